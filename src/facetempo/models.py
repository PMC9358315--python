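"""Mixed-model stage: candidate enumeration, AICc selection, likelihood
ratio test against the null, and Tukey-adjusted pairwise contrasts.

Each dependent variable (log intensity; total variability) is modelled
with a Gaussian linear mixed model fitted by maximum likelihood, with a
random intercept per signaller.  Fixed effects are the interaction
outcome (5 levels), the signaller-first sex combination (4 levels), the
composite sociality index, and the Elo rating difference entered as both
linear and quadratic terms (the quadratic allows intensity to peak when
opponents are closely matched).  Candidate models differ in which
two-way interactions they add; interactions of outcome with sex
combination are never allowed because crossing the two factors produces
heavily unbalanced cells.

Model comparison uses AICc, ``-2*ll + 2k + 2k(k+1)/(n-k-1)``, counting
the residual and random-intercept variances in ``k``.  The selected
model is compared to the random-intercept-only null with a likelihood
ratio test.  t-statistics and contrasts use Satterthwaite-approximated
degrees of freedom, computed from the curvature of the profiled marginal
likelihood in the two variance parameters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
import patsy
import yaml
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .types import OUTCOMES, SEX_COMBINATIONS, ValidationError

log = logging.getLogger(__name__)

MAIN_TERMS = (
    "outcome",
    "sex_combination",
    "csi",
    "elo_difference",
    "elo_difference_squared",
)

#: Two-way interactions admitted by the default candidate scheme.  The
#: outcome x sex_combination interaction is structurally forbidden.
DEFAULT_INTERACTIONS = (
    "outcome:csi",
    "outcome:elo_difference",
    "sex_combination:csi",
    "sex_combination:elo_difference",
    "csi:elo_difference",
)

FORBIDDEN_PAIR = frozenset({"outcome", "sex_combination"})


# ---------------------------------------------------------------------------
# analysis table


def assemble_analysis_table(
    metrics: pd.DataFrame,
    dyads: pd.DataFrame,
    sexes: dict[str, str],
    eps: float | None = None,
    elo_scale: float = 1000.0,
) -> pd.DataFrame:
    """Join bout metrics with dyadic covariates into the model table.

    Parameters
    ----------
    metrics
        Per-bout metric table from :func:`facetempo.metrics.score_bouts`.
    dyads
        Ordered-dyad covariates (``elo_difference``, ``csi``) from
        :func:`facetempo.social.dyad_covariates`.
    eps
        Offset added before the log transform, because intensity can be
        exactly zero.  Defaults to half the smallest positive intensity
        in the data.
    elo_scale
        Elo differences are divided by this before entering the model
        (raw rating differences span hundreds of points; the quadratic
        term would otherwise be numerically tiny).

    Excluded bouts and bouts whose dyad has no covariates are dropped,
    with a log line per dropped bout.
    """
    keep = metrics[~metrics["excluded"]].copy()
    merged = keep.merge(dyads, on=["signaller", "receiver", "group"], how="left")
    unmatched = merged["elo_difference"].isna() | merged["csi"].isna()
    for bout_id in merged.loc[unmatched, "bout_id"]:
        log.info("bout %s dropped: no dyadic covariates", bout_id)
    merged = merged[~unmatched].copy()

    if eps is None:
        positive = merged.loc[merged["intensity"] > 0, "intensity"]
        eps = 0.5 * positive.min() if len(positive) else 0.0
    merged["log_intensity"] = np.log(merged["intensity"] + eps)
    merged["variability"] = merged["var_total"]
    merged["elo_difference"] = merged["elo_difference"] / elo_scale
    merged["elo_difference_squared"] = merged["elo_difference"] ** 2
    merged["sex_combination"] = [
        sexes[s] + sexes[r] for s, r in zip(merged["signaller"], merged["receiver"])
    ]
    merged["outcome"] = pd.Categorical(merged["outcome"], categories=OUTCOMES)
    merged["sex_combination"] = pd.Categorical(
        merged["sex_combination"], categories=SEX_COMBINATIONS
    )
    cols = [
        "bout_id",
        "signaller",
        "receiver",
        "group",
        "outcome",
        "sex_combination",
        "csi",
        "elo_difference",
        "elo_difference_squared",
        "log_intensity",
        "variability",
    ]
    return merged[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# candidate models


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effects structure for a dependent variable."""

    dv: str
    terms: tuple[str, ...]  # fixed-effect terms beyond the intercept

    def __post_init__(self):
        for term in self.terms:
            parts = set(term.split(":"))
            if FORBIDDEN_PAIR <= parts:
                raise ValidationError(
                    "interactions between outcome and sex_combination are not "
                    f"permitted (term {term!r})"
                )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.dv} ~ {rhs}"

    @property
    def is_null(self) -> bool:
        return not self.terms

    def nests(self, other: "ModelSpec") -> bool:
        """True when ``self``'s terms are a subset of ``other``'s."""
        return self.dv == other.dv and set(self.terms) <= set(other.terms)


def enumerate_candidates(
    dv: str,
    interactions: tuple[str, ...] | None = None,
    main_terms: tuple[str, ...] = MAIN_TERMS,
) -> list[ModelSpec]:
    """Null model, main-effects model, and every interaction subset.

    With the default five admissible two-way interactions this yields
    1 (null) + 2**5 = 33 candidates per dependent variable.
    """
    if interactions is None:
        interactions = DEFAULT_INTERACTIONS
    for term in interactions:
        if FORBIDDEN_PAIR <= set(term.split(":")):
            raise ValidationError(
                f"requested interaction {term!r} pairs outcome with sex_combination"
            )
    specs = [ModelSpec(dv, ())]
    for r in range(len(interactions) + 1):
        for subset in combinations(interactions, r):
            specs.append(ModelSpec(dv, main_terms + subset))
    return specs


def load_candidates(path, dv: str) -> list[ModelSpec]:
    """Read a candidate set from YAML: a list of term lists.

    An empty term list denotes the null model.  This lets an externally
    defined candidate set (for example a published 41-model list) replace
    the default scheme.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ModelSpec(dv, tuple(terms)) for terms in raw]


def save_candidates(specs: list[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([list(s.terms) for s in specs], fh)


# ---------------------------------------------------------------------------
# random-intercept marginal likelihood (for Satterthwaite df)


class _RandomInterceptProfile:
    """Profiled ML machinery for a Gaussian LMM with one random intercept.

    Exposes the marginal log-likelihood (fixed effects profiled out) and
    the fixed-effects covariance as functions of the two variance
    parameters (residual ``s2``, intercept ``t2``), from which
    Satterthwaite degrees of freedom are computed by finite differences.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        codes, _ = pd.factorize(groups)
        order = np.argsort(codes, kind="stable")
        self.X = self.X[order]
        self.y = self.y[order]
        codes = codes[order]
        self.slices = [
            slice(lo, hi)
            for lo, hi in zip(
                np.searchsorted(codes, np.unique(codes)),
                np.searchsorted(codes, np.unique(codes), side="right"),
            )
        ]
        self.n, self.p = self.X.shape

    def _whiten(self, s2: float, t2: float):
        """Return (XtViX, XtViy, ytViy, logdetV) summed over groups."""
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        logdet = 0.0
        for sl in self.slices:
            Xi, yi = self.X[sl], self.y[sl]
            ni = len(yi)
            w = t2 / (s2 + ni * t2)
            xs, ys = Xi.sum(axis=0), yi.sum()
            XtViX += (Xi.T @ Xi - w * np.outer(xs, xs)) / s2
            XtViy += (Xi.T @ yi - w * xs * ys) / s2
            ytViy += (yi @ yi - w * ys * ys) / s2
            logdet += (ni - 1) * math.log(s2) + math.log(s2 + ni * t2)
        return XtViX, XtViy, ytViy, logdet

    def loglik(self, s2: float, t2: float) -> float:
        """Marginal ML log-likelihood with beta at its GLS optimum."""
        XtViX, XtViy, ytViy, logdet = self._whiten(s2, t2)
        beta = np.linalg.pinv(XtViX) @ XtViy  # pinv: tolerate collinear columns
        quad = ytViy - beta @ XtViy
        return -0.5 * (self.n * math.log(2 * math.pi) + logdet + quad)

    def beta_cov(self, s2: float, t2: float) -> np.ndarray:
        XtViX, _, _, _ = self._whiten(s2, t2)
        return np.linalg.pinv(XtViX)

    def _varpar_cov(self, s2: float, t2: float) -> np.ndarray | None:
        """Asymptotic covariance of (s2, t2): inverse observed information."""
        h = np.array([max(s2, 1e-8) * 1e-4, max(t2, 1e-8) * 1e-4])

        def f(ds, dt):
            return self.loglik(max(s2 + ds, 1e-12), max(t2 + dt, 1e-12))

        H = np.empty((2, 2))
        H[0, 0] = (f(h[0], 0) - 2 * f(0, 0) + f(-h[0], 0)) / h[0] ** 2
        H[1, 1] = (f(0, h[1]) - 2 * f(0, 0) + f(0, -h[1])) / h[1] ** 2
        H[0, 1] = H[1, 0] = (
            f(h[0], h[1]) - f(h[0], -h[1]) - f(-h[0], h[1]) + f(-h[0], -h[1])
        ) / (4 * h[0] * h[1])
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or cov[0, 0] <= 0:
            return None
        return cov

    def satterthwaite_df(self, L: np.ndarray, s2: float, t2: float) -> np.ndarray:
        """Degrees of freedom for contrasts ``L @ beta`` (rows of L).

        df = 2 f^2 / (g' A g) where f(theta) = l' C(theta) l is the
        contrast variance, g its gradient in the variance parameters and
        A their asymptotic covariance.  Falls back to the residual df
        ``n - p`` when the information matrix is degenerate (e.g. the
        random-intercept variance sits on its zero boundary).
        """
        L = np.atleast_2d(L)
        fallback = float(self.n - self.p)
        A = self._varpar_cov(s2, t2)
        if A is None:
            return np.full(len(L), fallback)
        h = np.array([max(s2, 1e-8) * 1e-4, max(t2, 1e-8) * 1e-4])
        s2lo = max(s2 - h[0], 1e-12)
        t2lo = max(t2 - h[1], 1e-12)
        covs = {
            "0+": self.beta_cov(s2 + h[0], t2),
            "0-": self.beta_cov(s2lo, t2),
            "1+": self.beta_cov(s2, t2 + h[1]),
            "1-": self.beta_cov(s2, t2lo),
        }
        C0 = self.beta_cov(s2, t2)
        dfs = np.empty(len(L))
        for i, l in enumerate(L):
            f0 = l @ C0 @ l
            g = np.array(
                [
                    (l @ covs["0+"] @ l - l @ covs["0-"] @ l) / (s2 + h[0] - s2lo),
                    (l @ covs["1+"] @ l - l @ covs["1-"] @ l) / (t2 + h[1] - t2lo),
                ]
            )
            denom = g @ A @ g
            df = 2 * f0**2 / denom if denom > 0 else fallback
            dfs[i] = min(df, fallback) if df > 0 else fallback
        return dfs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """One fitted mixed model with everything selection and reporting need."""

    spec: ModelSpec
    loglik: float
    n_obs: int
    k_params: int  # fixed effects + 2 variance parameters
    aicc: float
    converged: bool
    params: pd.Series = field(repr=False, default=None)
    bse: pd.Series = field(repr=False, default=None)
    df: pd.Series = field(repr=False, default=None)  # Satterthwaite, per coefficient
    tvalues: pd.Series = field(repr=False, default=None)
    pvalues: pd.Series = field(repr=False, default=None)
    sigma2: float = np.nan
    tau2: float = np.nan
    design_info: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    _profile: object = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "df": self.df,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC: ``-2*ll + 2k + 2k(k+1)/(n-k-1)``."""
    if n_obs <= n_params + 1:
        raise ValueError(
            f"AICc undefined for n_obs={n_obs} <= n_params+1={n_params + 1}"
        )
    k = n_params
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def fit_lmm(spec: ModelSpec, table: pd.DataFrame, groups_col: str = "signaller") -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Requires at least two signallers.  Non-convergence is flagged rather
    than raised, so selection can drop the fit with a warning.
    """
    if table[groups_col].nunique() < 2:
        raise ValidationError("mixed model requires >= 2 signallers")
    table = table.copy()
    for col in table.columns:  # empty factor levels would make X singular
        if isinstance(table[col].dtype, pd.CategoricalDtype):
            table[col] = table[col].cat.remove_unused_categories()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            spec.formula, data=table, groups=table[groups_col], re_formula="1"
        )
        res = model.fit(reml=False)
    converged = bool(res.converged) and np.isfinite(res.llf)
    fe_names = list(model.exog_names)
    p = len(fe_names)
    k = p + 2
    n = model.nobs
    sigma2 = float(res.scale)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    profile = _RandomInterceptProfile(model.exog, model.endog, np.asarray(table[groups_col]))
    params = res.fe_params.copy()
    params.index = fe_names
    bse = pd.Series(np.sqrt(np.diag(profile.beta_cov(sigma2, tau2))), index=fe_names)
    dfs = pd.Series(profile.satterthwaite_df(np.eye(p), sigma2, tau2), index=fe_names)
    tvals = params / bse
    pvals = pd.Series(
        2 * stats.t.sf(np.abs(tvals.to_numpy()), dfs.to_numpy()), index=fe_names
    )
    return FitResult(
        spec=spec,
        loglik=float(res.llf),
        n_obs=int(n),
        k_params=k,
        aicc=aicc(float(res.llf), k, int(n)) if converged else np.inf,
        converged=converged,
        params=params,
        bse=bse,
        df=dfs,
        tvalues=tvals,
        pvalues=pvals,
        sigma2=sigma2,
        tau2=tau2,
        design_info=model.data.design_info,
        data=table,
        _profile=profile,
    )


def fit_candidates(
    specs: list[ModelSpec], table: pd.DataFrame, groups_col: str = "signaller"
) -> list[FitResult]:
    fits = []
    for spec in specs:
        try:
            fit = fit_lmm(spec, table, groups_col)
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("model %s failed to fit: %s", spec.formula, exc)
            continue
        if not fit.converged:
            log.warning("model %s did not converge; excluded from selection", spec.formula)
        fits.append(fit)
    return fits


def select_by_aicc(fits: list[FitResult]) -> FitResult:
    """Smallest AICc among converged fits.

    Ties break toward fewer parameters, then lexicographic formula order,
    so selection is deterministic.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValidationError("no converged fits to select from")
    return min(converged, key=lambda f: (f.aicc, f.k_params, f.spec.formula))


def lr_test_vs_null(best: FitResult, null: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of the selected model against a nested null.

    Returns ``(chi_square, df, p)`` with the statistic
    ``2 * (ll_best - ll_null)`` referred to a chi-square on the
    parameter-count difference.
    """
    if not null.spec.nests(best.spec):
        raise ValidationError(
            f"{null.spec.formula!r} is not nested in {best.spec.formula!r}"
        )
    chi2 = max(0.0, 2.0 * (best.loglik - null.loglik))
    df = best.k_params - null.k_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 <= 1e-8 else 0.0)
    return chi2, df, p


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey contrasts


def _reference_grid(fit: FitResult) -> tuple[pd.DataFrame, dict[str, list]]:
    """Balanced grid over the model's categorical factors; covariates at
    their observed means."""
    di = fit.design_info
    cat_levels: dict[str, list] = {}
    num_means: dict[str, float] = {}
    for factor, info in di.factor_infos.items():
        name = factor.name()
        if info.type == "categorical":
            cat_levels[name] = list(info.categories)
        else:
            num_means[name] = float(np.mean(fit.data.eval(name)))
    if not cat_levels:
        raise ValidationError("model contains no categorical factor")
    names = list(cat_levels)
    rows = [
        {**dict(zip(names, combo)), **num_means}
        for combo in product(*(cat_levels[n] for n in names))
    ]
    return pd.DataFrame(rows), cat_levels


def estimated_marginal_means(fit: FitResult, factor: str) -> pd.DataFrame:
    """EMMs for one factor: level means over a balanced reference grid."""
    grid, cat_levels = _reference_grid(fit)
    if factor not in cat_levels:
        raise ValidationError(f"factor {factor!r} not in model")
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    rows = []
    for level in cat_levels[factor]:
        mask = (grid[factor] == level).to_numpy()
        l = X[mask].mean(axis=0)
        est = float(l @ fit.params.to_numpy())
        prof = fit._profile
        se = float(np.sqrt(l @ prof.beta_cov(fit.sigma2, fit.tau2) @ l))
        rows.append({"level": level, "emmean": est, "se": se, "lvec": l})
    return pd.DataFrame(rows)


def pairwise_contrasts(fit: FitResult, factor: str) -> pd.DataFrame:
    """All level-pair EMM differences with Tukey-adjusted p-values.

    For an L-level factor this yields C(L, 2) contrasts.  The adjustment
    refers ``|t| * sqrt(2)`` to the studentized range distribution with L
    groups and the contrast's Satterthwaite degrees of freedom.
    """
    emms = estimated_marginal_means(fit, factor)
    levels = list(emms["level"])
    k = len(levels)
    prof = fit._profile
    beta = fit.params.to_numpy()
    rows = []
    for (ia, a), (ib, b) in combinations(enumerate(levels), 2):
        l = emms["lvec"][ia] - emms["lvec"][ib]
        est = float(l @ beta)
        se = float(np.sqrt(l @ prof.beta_cov(fit.sigma2, fit.tau2) @ l))
        df = float(prof.satterthwaite_df(l, fit.sigma2, fit.tau2)[0])
        t = est / se
        p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        rows.append(
            {
                "factor": factor,
                "level_a": a,
                "level_b": b,
                "estimate": est,
                "se": se,
                "df": df,
                "t": t,
                "p_tukey": min(max(p, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)
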