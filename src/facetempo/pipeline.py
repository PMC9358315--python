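"""End-to-end orchestration: ingest -> score -> social -> fit.

One call produces a reproducible run directory holding the per-bout
metric table, the dyadic covariate table, the joined analysis table,
one fit report per dependent variable, and a manifest recording the
configuration, input checksums and row counts at every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ftio
from . import metrics as ftmetrics
from . import models as ftmodels
from . import social as ftsocial
from .types import ValidationError

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending rows."""


@dataclass
class RunConfig:
    bouts: str = "bouts.csv"
    dominance: str = "dominance.csv"
    affiliation: str = "affiliation.csv"
    scans: str = "scans.csv"
    effort: str = "effort.csv"
    out_dir: str = "run"
    fps: float = 25.0
    eps: float | None = None  # log-transform offset; None -> data-driven
    elo_initial: float = 1000.0
    elo_k: float = 50.0
    elo_same_sex_only: bool = True
    elo_expectation: str = "logistic"
    elo_scale: float = 1000.0
    count_neutral_transitions: bool = False
    candidates_file: str | None = None
    dependent_variables: tuple[str, ...] = ("log_intensity", "variability")
    contrast_factors: tuple[str, ...] = ("outcome", "sex_combination")
    seed: int = 0


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fit_report(fits, best, null, lr, contrasts) -> dict:
    return {
        "selected_formula": best.spec.formula,
        "n_obs": best.n_obs,
        "loglik": best.loglik,
        "aicc": best.aicc,
        "sigma2": best.sigma2,
        "tau2": best.tau2,
        "estimates": {
            name: {
                "estimate": float(best.params[name]),
                "se": float(best.bse[name]),
                "df": float(best.df[name]),
                "t": float(best.tvalues[name]),
                "p": float(best.pvalues[name]),
            }
            for name in best.params.index
        },
        "aicc_table": sorted(
            (
                {"formula": f.spec.formula, "aicc": float(f.aicc), "k": int(f.k_params),
                 "converged": bool(f.converged)}
                for f in fits
            ),
            key=lambda d: d["aicc"],
        ),
        "lr_test_vs_null": {"chi2": lr[0], "df": lr[1], "p": lr[2]},
        "contrasts": {
            factor: tab.drop(columns=["factor"]).to_dict(orient="records")
            for factor, tab in contrasts.items()
        },
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artefacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    ioconf = ftio.IOConfig(default_fps=config.fps)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValidationError, ValueError, KeyError) as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    bouts = stage("ingest", ftio.read_bouts, config.bouts, ioconf)
    if not bouts:
        raise PipelineError("stage 'ingest' failed: bout file is empty")
    interactions = stage("ingest", ftio.read_dominance, config.dominance, ioconf)
    affil, scans, effort = stage(
        "ingest", ftio.read_affiliation, config.affiliation, config.scans,
        config.effort, ioconf,
    )
    counts["bouts_ingested"] = len(bouts)
    counts["dominance_interactions"] = len(interactions)
    counts["affiliation_records"] = len(affil)
    counts["proximity_scans"] = len(scans)

    metrics = stage(
        "score", ftmetrics.score_bouts, bouts,
        count_neutral_transitions=config.count_neutral_transitions,
    )
    counts["bouts_scored"] = int((~metrics["excluded"]).sum())
    counts["bouts_excluded_by_gaze"] = int(metrics["excluded"].sum())
    ftio.write_metrics(metrics, out / "metrics.csv")

    elo = stage(
        "social", ftsocial.compute_elo, interactions, effort,
        initial=config.elo_initial, k=config.elo_k,
        same_sex_only=config.elo_same_sex_only,
        expectation=config.elo_expectation,
    )
    elo = stage("social", ftsocial.recalibrate_female_elo, elo)
    effort_hours = dict(zip(effort["id"], effort["hours"]))
    csi_tables = []
    for group, sub in effort.groupby("group"):
        csi_tables.append(
            stage(
                "social", ftsocial.compute_csi,
                [r for r in affil if r.dyad[0] in set(sub["id"])],
                [s for s in scans if s.dyad[0] in set(sub["id"])],
                effort_hours, list(sub["id"]), group=group,
            )
        )
    dyads = stage("social", ftsocial.dyad_covariates, elo, csi_tables)
    counts["dyads"] = len(dyads)
    ftio.write_metrics(
        elo.reset_index(names="id"), out / "elo.csv"
    )
    ftio.write_metrics(dyads, out / "dyads.csv")

    sexes = dict(zip(effort["id"], effort["sex"]))
    table = stage(
        "assemble", ftmodels.assemble_analysis_table, metrics, dyads, sexes,
        eps=config.eps, elo_scale=config.elo_scale,
    )
    counts["analysis_rows"] = len(table)
    counts["signallers"] = int(table["signaller"].nunique())
    ftio.write_metrics(table, out / "analysis.csv")

    reports = {}
    for dv in config.dependent_variables:
        if config.candidates_file:
            specs = ftmodels.load_candidates(config.candidates_file, dv)
        else:
            specs = ftmodels.enumerate_candidates(dv)
        fits = stage("fit", ftmodels.fit_candidates, specs, table)
        best = stage("fit", ftmodels.select_by_aicc, fits)
        null = next(f for f in fits if f.spec.is_null)
        lr = ftmodels.lr_test_vs_null(best, null)
        contrasts = {}
        for factor in config.contrast_factors:
            if any(factor in t.split(":") for t in best.spec.terms):
                contrasts[factor] = ftmodels.pairwise_contrasts(best, factor)
        report = _fit_report(fits, best, null, lr, contrasts)
        reports[dv] = report
        name = "fit_intensity.json" if dv == "log_intensity" else f"fit_{dv}.json"
        with open(out / name, "w") as fh:
            json.dump(report, fh, indent=1)
        log.info(
            "%s: selected %s, LR vs null chi2=%.2f df=%d p=%.3g",
            dv, report["selected_formula"], *lr,
        )

    manifest = {
        "config": asdict(config),
        "counts": counts,
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("bouts", "dominance", "affiliation", "scans", "effort")
        },
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _versions() -> dict:
    import statsmodels

    from . import __version__

    return {
        "facetempo": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
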