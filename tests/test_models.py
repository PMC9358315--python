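"""Mixed-model stage: table assembly, AICc, selection, LR tests,
Satterthwaite degrees of freedom and Tukey contrasts (with an
lmerTest/emmeans cross-check)."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from facetempo import models as fm
from facetempo.simulate import SimConfig, generate_all
from facetempo.types import ValidationError


# ---------------------------------------------------------------------------
# AICc


class TestAICc:
    def test_closed_form(self):
        assert fm.aicc(-100.0, 5, 30) == pytest.approx(212.5)

    def test_matches_formula_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ll = rng.normal(-200, 50)
            k = int(rng.integers(1, 12))
            n = int(rng.integers(k + 2, 500))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert fm.aicc(ll, k, n) == pytest.approx(expected, abs=1e-9)

    def test_reduces_to_aic_for_large_n(self):
        assert fm.aicc(-100.0, 5, 10**9) - 210.0 < 1e-6

    def test_zero_parameters(self):
        assert fm.aicc(-100.0, 0, 30) == 200.0

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            fm.aicc(-100.0, 5, 6)


# ---------------------------------------------------------------------------
# candidate enumeration


class TestCandidates:
    def test_no_interactions_gives_null_plus_main(self):
        specs = fm.enumerate_candidates("log_intensity", interactions=())
        assert len(specs) == 2
        assert specs[0].is_null
        assert set(specs[1].terms) == set(fm.MAIN_TERMS)

    def test_default_scheme_is_33(self):
        # 5 admissible two-way interactions -> 2**5 subsets + null
        specs = fm.enumerate_candidates("variability")
        assert len(specs) == 33
        assert len({s.formula for s in specs}) == 33

    def test_outcome_sex_interaction_forbidden(self):
        with pytest.raises(ValidationError):
            fm.enumerate_candidates(
                "log_intensity", interactions=("outcome:sex_combination",)
            )
        with pytest.raises(ValidationError):
            fm.ModelSpec("log_intensity", ("sex_combination:outcome",))

    def test_external_candidate_file(self, tmp_path):
        # an externally supplied 41-spec list is used verbatim
        rng = np.random.default_rng(1)
        specs = [fm.ModelSpec("log_intensity", ())]
        pool = fm.MAIN_TERMS + fm.DEFAULT_INTERACTIONS
        seen = {()}
        while len(specs) < 41:
            terms = tuple(
                t for t in pool if rng.random() < 0.6
            )
            if terms not in seen:
                seen.add(terms)
                specs.append(fm.ModelSpec("log_intensity", terms))
        path = tmp_path / "candidates.yaml"
        fm.save_candidates(specs, path)
        loaded = fm.load_candidates(path, "log_intensity")
        assert len(loaded) == 41
        assert loaded == specs


# ---------------------------------------------------------------------------
# analysis-table assembly


@pytest.fixture(scope="module")
def assembled(sim_analysis):
    metrics, dyads, sexes, _ = sim_analysis
    return metrics, dyads, sexes


class TestAssemble:
    def test_row_count_matches_non_excluded_bouts(self, assembled):
        metrics, dyads, sexes = assembled
        table = fm.assemble_analysis_table(metrics, dyads, sexes)
        assert len(table) == int((~metrics["excluded"]).sum())

    def test_log_transform_and_quadratic(self, assembled):
        metrics, dyads, sexes = assembled
        table = fm.assemble_analysis_table(metrics, dyads, sexes, eps=0.0)
        keep = metrics[~metrics["excluded"]].reset_index(drop=True)
        assert np.allclose(table["log_intensity"], np.log(keep["intensity"]))
        assert np.allclose(
            table["elo_difference_squared"], table["elo_difference"] ** 2
        )

    def test_unit_intensity_maps_to_zero(self):
        metrics = pd.DataFrame(
            {
                "bout_id": ["b1"],
                "signaller": ["A"],
                "receiver": ["B"],
                "group": ["G"],
                "outcome": ["aggression"],
                "intensity": [1.0],
                "var_total": [0.1],
                "excluded": [False],
            }
        )
        dyads = pd.DataFrame(
            {
                "signaller": ["A"],
                "receiver": ["B"],
                "group": ["G"],
                "elo_difference": [100.0],
                "csi": [1.0],
            }
        )
        table = fm.assemble_analysis_table(
            metrics, dyads, {"A": "F", "B": "F"}, eps=0.0
        )
        assert table.loc[0, "log_intensity"] == 0.0
        assert table.loc[0, "sex_combination"] == "FF"

    def test_unmatched_dyads_dropped(self, assembled, caplog):
        metrics, dyads, sexes = assembled
        smaller = dyads.iloc[: len(dyads) // 2]
        with caplog.at_level("INFO"):
            table = fm.assemble_analysis_table(metrics, smaller, sexes)
        assert len(table) < int((~metrics["excluded"]).sum())


# ---------------------------------------------------------------------------
# fitting, selection, LR


def _fake_fit(loglik, k, n=100, terms=("x",), dv="y"):
    return fm.FitResult(
        spec=fm.ModelSpec(dv, terms),
        loglik=loglik,
        n_obs=n,
        k_params=k,
        aicc=fm.aicc(loglik, k, n),
        converged=True,
    )


class TestSelection:
    def test_minimum_aicc_wins(self):
        fits = [_fake_fit(-100, 5, terms=("a",)), _fake_fit(-102, 5, terms=("b",))]
        assert fm.select_by_aicc(fits) is fits[0]

    def test_tie_broken_by_fewer_parameters(self):
        a = _fake_fit(-100, 6, terms=("a", "b"))
        b = fm.FitResult(  # same AICc, fewer parameters
            spec=fm.ModelSpec("y", ("c",)), loglik=0.0, n_obs=100, k_params=5,
            aicc=a.aicc, converged=True,
        )
        assert fm.select_by_aicc([a, b]) is b

    def test_argmin_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fits = [
                _fake_fit(rng.normal(-150, 20), int(rng.integers(3, 9)), terms=(f"t{i}",))
                for i in range(8)
            ]
            best = fm.select_by_aicc(fits)
            assert best.aicc == min(f.aicc for f in fits)

    def test_no_converged_fits_errors(self):
        bad = _fake_fit(-100, 5)
        bad.converged = False
        with pytest.raises(ValidationError):
            fm.select_by_aicc([bad])


class TestLRTest:
    def test_identical_models_give_zero(self):
        null = _fake_fit(-100, 2, terms=())
        best = _fake_fit(-100, 2, terms=())
        chi2, df, p = fm.lr_test_vs_null(best, null)
        assert chi2 == 0.0 and p == 1.0

    def test_statistic_is_twice_loglik_gap(self):
        null = _fake_fit(5.0, 2, terms=())
        best = _fake_fit(10.0, 5, terms=("a", "b", "c"))
        chi2, df, p = fm.lr_test_vs_null(best, null)
        assert chi2 == pytest.approx(10.0)
        assert df == 3

    def test_non_nested_rejected(self):
        a = _fake_fit(-100, 4, terms=("a",))
        b = _fake_fit(-100, 4, terms=("b",))
        with pytest.raises(ValidationError):
            fm.lr_test_vs_null(a, b)


def _balanced_table(rng, n_sig=10, per=8):
    sig = np.repeat([f"S{i}" for i in range(n_sig)], per)
    n = len(sig)
    return pd.DataFrame(
        {
            "signaller": sig,
            "outcome": pd.Categorical(
                np.tile(["affiliation", "aggression", "copulation", "submission"], n // 4),
                categories=["affiliation", "aggression", "copulation", "submission"],
            ),
            "csi": rng.gamma(2.0, 0.5, n),
        }
    )


class TestFitLMM:
    def test_null_generative_case(self):
        rng = np.random.default_rng(4)
        table = _balanced_table(rng)
        table["y"] = 3.0 + rng.normal(0, 1e-8, len(table))
        fit = fm.fit_lmm(fm.ModelSpec("y", ("outcome", "csi")), table)
        assert fit.params["Intercept"] == pytest.approx(3.0, abs=1e-4)
        assert np.allclose(fit.params.drop("Intercept"), 0.0, atol=1e-4)

    def test_single_signaller_rejected(self):
        table = pd.DataFrame(
            {"signaller": ["A"] * 10, "y": np.arange(10.0), "x": np.arange(10.0)}
        )
        with pytest.raises(ValidationError):
            fm.fit_lmm(fm.ModelSpec("y", ("x",)), table)

    def test_zero_column_does_not_change_loglik(self):
        # guard on the likelihood machinery itself: a null column cannot
        # move the profiled marginal likelihood
        rng = np.random.default_rng(6)
        table = _balanced_table(rng)
        table["y"] = (
            np.repeat(rng.normal(0, 0.5, 10), 8) + 0.3 * table["csi"] + rng.normal(0, 1, 80)
        )
        X = np.column_stack([np.ones(len(table)), table["csi"]])
        groups = table["signaller"].to_numpy()
        base = fm._RandomInterceptProfile(X, table["y"].to_numpy(), groups)
        padded = fm._RandomInterceptProfile(
            np.column_stack([X, np.zeros(len(table))]), table["y"].to_numpy(), groups
        )
        for s2, t2 in [(1.0, 0.3), (0.5, 0.01), (2.0, 1.0)]:
            assert padded.loglik(s2, t2) == pytest.approx(base.loglik(s2, t2), abs=1e-8)

    def test_recovers_planted_outcome_effect(self):
        """Planted -0.4 affiliation deficit on log intensity is estimated
        within 3 SE on one default-size simulated dataset."""
        from conftest import build_analysis

        config = SimConfig(
            context_weights={"affiliation": 0.5, "aggression": 0.5},
            context_intensity={
                "affiliation": 0.45 * math.exp(-0.4), "aggression": 0.45,
            },
            context_var_unpred={"affiliation": 0.5, "aggression": 0.5},
            rdad_prob={"affiliation": 0.3, "aggression": 0.3},
            elo2_coef=0.0,
        )
        data = generate_all(config, seed=21)
        *_, table = build_analysis(data, eps=0.0)
        fit = fm.fit_lmm(fm.ModelSpec("log_intensity", fm.MAIN_TERMS), table)
        est = fit.params["outcome[T.aggression]"]
        se = fit.bse["outcome[T.aggression]"]
        assert abs(est - 0.4) < 3 * se


@pytest.fixture(scope="module")
def fitted(sim_analysis):
    *_, table = sim_analysis
    return fm.fit_lmm(fm.ModelSpec("log_intensity", fm.MAIN_TERMS), table)


class TestContrasts:

    def test_contrast_counts(self, fitted):
        assert len(fm.pairwise_contrasts(fitted, "outcome")) == 10  # C(5,2)
        assert len(fm.pairwise_contrasts(fitted, "sex_combination")) == 6  # C(4,2)

    def test_absent_factor_errors(self, fitted):
        with pytest.raises(ValidationError):
            fm.pairwise_contrasts(fitted, "group")

    def test_balanced_one_way_equals_cell_mean_differences(self):
        rng = np.random.default_rng(8)
        table = _balanced_table(rng)
        table["y"] = rng.normal(0, 1, len(table)) + table["outcome"].cat.codes * 0.5
        fit = fm.fit_lmm(fm.ModelSpec("y", ("outcome",)), table)
        cell = table.groupby("outcome", observed=True)["y"].mean()
        out = fm.pairwise_contrasts(fit, "outcome")
        for row in out.itertuples():
            assert row.estimate == pytest.approx(
                cell[row.level_a] - cell[row.level_b], abs=1e-8
            )


# ---------------------------------------------------------------------------
# independent R oracle (lme4/lmerTest/emmeans)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_lmerTest_and_emmeans(tmp_path):
    """ML estimates, Satterthwaite df and Tukey contrasts agree with the
    reference R implementations on a small fixture."""
    rng = np.random.default_rng(42)
    n_g, per = 12, 10
    n = n_g * per
    df = pd.DataFrame(
        {
            "signaller": np.repeat([f"S{i:02d}" for i in range(n_g)], per),
            "outcome": pd.Categorical(
                rng.choice(["affiliation", "aggression", "copulation"], n),
                categories=["affiliation", "aggression", "copulation"],
            ),
            "csi": rng.gamma(2.0, 0.5, n),
        }
    )
    eff = {"affiliation": 0.0, "aggression": 0.5, "copulation": 0.3}
    df["y"] = (
        np.repeat(rng.normal(0, 0.4, n_g), per)
        + df["outcome"].map(eff).astype(float)
        + 0.2 * df["csi"]
        + rng.normal(0, 0.6, n)
    )
    csv = tmp_path / "fixture.csv"
    df.to_csv(csv, index=False)
    fit = fm.fit_lmm(fm.ModelSpec("y", ("outcome", "csi")), df)
    contrasts = fm.pairwise_contrasts(fit, "outcome")

    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages({library(lmerTest); library(emmeans)})\n"
        f"d <- read.csv('{csv}')\n"
        "d$outcome <- factor(d$outcome, levels=c('affiliation','aggression','copulation'))\n"
        "m <- lmer(y ~ outcome + csi + (1|signaller), data=d, REML=FALSE)\n"
        "cat('LOGLIK', sprintf('%.6f', as.numeric(logLik(m))), '\\n')\n"
        "s <- coef(summary(m))\n"
        "for (i in 1:nrow(s)) cat('COEF', rownames(s)[i], sprintf('%.6f', s[i,1]),"
        " sprintf('%.6f', s[i,2]), sprintf('%.3f', s[i,3]), '\\n')\n"
        "p <- as.data.frame(pairs(emmeans(m, ~outcome, lmer.df='satterthwaite')))\n"
        "for (i in 1:nrow(p)) cat('PAIR', gsub(' ', '', p$contrast[i]),"
        " sprintf('%.6f', p$estimate[i]), sprintf('%.6f', p$SE[i]),"
        " sprintf('%.3f', p$df[i]), sprintf('%.6f', p$p.value[i]), '\\n')\n"
    )
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    lines = proc.stdout.splitlines()
    ll = float(next(l.split()[1] for l in lines if l.startswith("LOGLIK")))
    assert fit.loglik == pytest.approx(ll, abs=1e-3)

    name_map = {
        "(Intercept)": "Intercept",
        "outcomeaggression": "outcome[T.aggression]",
        "outcomecopulation": "outcome[T.copulation]",
        "csi": "csi",
    }
    for line in lines:
        if line.startswith("COEF"):
            _, rname, est, se, dof = line.split()
            pname = name_map[rname]
            assert fit.params[pname] == pytest.approx(float(est), abs=1e-4)
            assert fit.bse[pname] == pytest.approx(float(se), abs=1e-4)
            assert fit.df[pname] == pytest.approx(float(dof), rel=0.02)
    pairs = {
        (r.level_a, r.level_b): r for r in contrasts.itertuples()
    }
    for line in lines:
        if line.startswith("PAIR"):
            _, contrast, est, se, dof, pval = line.split()
            a, b = contrast.split("-")
            row = pairs[(a, b)]
            assert row.estimate == pytest.approx(float(est), abs=1e-4)
            assert row.se == pytest.approx(float(se), abs=1e-4)
            assert row.df == pytest.approx(float(dof), rel=0.02)
            assert row.p_tukey == pytest.approx(float(pval), abs=2e-3)
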