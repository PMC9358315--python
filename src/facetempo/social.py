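"""Dyadic social covariates: Elo dominance ratings and the composite
sociality index (CSI).

Elo ratings are updated sequentially through the dominance-interaction
record: the winner gains ``k * (1 - p_win)`` points and the loser loses
the same amount, where ``p_win`` is the winner's expected probability of
winning given the pre-interaction ratings.  Ratings start at 1000 with
k = 50 and, by default, only same-sex interactions update ratings —
inter-sexual conflicts are uninformative in a species where every such
conflict is won by the male.  Female ratings are then recalibrated so the
top-ranked female sits just below the lowest-ranked male of her group:

    E_new = E_old * (M_min - 1) / F_max

The CSI for a dyad (a, b) is the mean of four effort-corrected
affiliation measures — grooming frequency G, grooming duration D,
proximity within 1 m P, affiliative-contact frequency A — each expressed
relative to its group-wide average:

    CSI = (G_ab/G_x + D_ab/D_x + P_ab/P_x + A_ab/A_x) / 4

so CSI = 1 describes an averagely bonded dyad and the group mean CSI is
exactly 1 whenever all four group denominators are positive.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .types import (
    AffiliationRecord,
    DominanceInteraction,
    ProximityScan,
    ValidationError,
    canonical_dyad,
)

log = logging.getLogger(__name__)

CSI_COMPONENTS = ("groom_freq", "groom_dur", "proximity", "contact_freq")


def logistic_expectation(rating_a: float, rating_b: float) -> float:
    """Standard Elo expected score for A against B."""
    return 1.0 / (1.0 + 10.0 ** ((rating_b - rating_a) / 400.0))


def normal_expectation(rating_a: float, rating_b: float) -> float:
    """Normal-CDF expected score (Elo's original formulation)."""
    from scipy.stats import norm

    return float(norm.cdf((rating_a - rating_b) / (2000.0 / 7.0)))

EXPECTATION_FUNCTIONS = {
    "logistic": logistic_expectation,
    "normal": normal_expectation,
}


def compute_elo(
    interactions: list[DominanceInteraction],
    individuals: pd.DataFrame,
    initial: float = 1000.0,
    k: float = 50.0,
    same_sex_only: bool = True,
    expectation: str = "logistic",
) -> pd.DataFrame:
    """Sequential Elo ratings over the full observation window.

    Parameters
    ----------
    interactions
        Decided dominance interactions; processed in date order
        (same-date interactions keep their input order).
    individuals
        One row per individual with columns ``id``, ``sex`` ('M'/'F') and
        ``group``.  Individuals without interactions keep the initial
        rating.

    Returns
    -------
    DataFrame indexed by individual id with columns ``sex``, ``group``,
    ``rating_raw`` and ``rating`` (recalibration fills the latter; here
    both equal the raw rating).
    """
    expect = EXPECTATION_FUNCTIONS[expectation]
    table = individuals.set_index("id") if "id" in individuals.columns else individuals
    sexes = table["sex"].to_dict()
    ratings = {ind: float(initial) for ind in table.index}

    for it in interactions:
        it.validate()
        if it.date is None:
            raise ValidationError(f"undated interaction {it.winner} vs {it.loser}")
        for ind in (it.winner, it.loser):
            if ind not in sexes:
                raise ValidationError(f"individual {ind!r} has no sex/group record")

    for it in sorted(interactions, key=lambda x: x.date):  # stable within a date
        if same_sex_only and sexes[it.winner] != sexes[it.loser]:
            continue
        p_win = expect(ratings[it.winner], ratings[it.loser])
        delta = k * (1.0 - p_win)
        ratings[it.winner] += delta
        ratings[it.loser] -= delta

    out = table.copy()
    out["rating_raw"] = pd.Series(ratings)
    out["rating"] = out["rating_raw"]
    return out


def recalibrate_female_elo(table: pd.DataFrame) -> pd.DataFrame:
    """Scale female ratings so the top female sits below every male.

    Within each group, every female's raw rating is multiplied by
    ``(M_min - 1) / F_max``; male ratings are untouched.  Groups lacking
    either sex are skipped with a warning.
    """
    out = table.copy()
    out["rating_raw"] = out["rating_raw"].astype(float)
    out["rating"] = out["rating_raw"]
    for group, sub in out.groupby("group"):
        males = sub[sub["sex"] == "M"]
        females = sub[sub["sex"] == "F"]
        if males.empty or females.empty:
            log.warning(
                "group %s: recalibration skipped (needs both sexes)", group
            )
            continue
        m_min = males["rating_raw"].min()
        f_max = females["rating_raw"].max()
        if f_max <= 0:
            raise ValidationError(
                f"group {group}: cannot recalibrate, top female rating "
                f"{f_max} is not positive"
            )
        scale = (m_min - 1.0) / f_max
        out.loc[females.index, "rating"] = females["rating_raw"] * scale
    return out


def elo_difference(table: pd.DataFrame, signaller: str, receiver: str) -> float:
    """Signed rating difference, signaller minus receiver.

    Positive when the signaller outranks the receiver.  Uses recalibrated
    ratings.
    """
    if signaller == receiver:
        raise ValidationError("self-dyad has no rating difference")
    for ind in (signaller, receiver):
        if ind not in table.index:
            raise ValidationError(f"individual {ind!r} not in Elo table")
    return float(table.loc[signaller, "rating"] - table.loc[receiver, "rating"])


# ---------------------------------------------------------------------------
# composite sociality index


def compute_csi(
    affiliation: list[AffiliationRecord],
    scans: list[ProximityScan],
    effort_hours: dict[str, float],
    members: list[str],
    group: str = "",
    proximity_by_scan_count: bool = False,
    scan_counts: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Composite sociality index for every dyad among ``members``.

    Each dyadic term (groom count, groom seconds, within-1 m scan count,
    contact count) is corrected for sampling effort by dividing by the
    dyad's combined focal hours, then divided by the group-wide mean of
    the corrected term over all dyads.  The CSI is the mean of the four
    ratios.  A component whose group mean is zero is dropped from the
    mean for every dyad, with a warning.

    ``proximity_by_scan_count`` switches the proximity correction to the
    number of scans sampled for the dyad (``scan_counts``) instead of
    focal hours.
    """
    for rec in affiliation:
        rec.validate()
    missing = sorted(
        {i for rec in affiliation for i in rec.dyad if i not in effort_hours}
        | {i for sc in scans for i in sc.dyad if i not in effort_hours}
    )
    if missing:
        raise ValidationError(
            f"individuals without observation effort: {', '.join(missing)}"
        )
    for ind in members:
        if effort_hours.get(ind, 0.0) <= 0:
            raise ValidationError(f"individual {ind!r} has no positive effort hours")

    dyads = [canonical_dyad(a, b) for a, b in combinations(sorted(members), 2)]
    raw = pd.DataFrame(0.0, index=pd.MultiIndex.from_tuples(dyads), columns=CSI_COMPONENTS)
    for rec in affiliation:
        d = canonical_dyad(*rec.dyad)
        if d not in raw.index:
            continue
        if rec.kind == "groom":
            raw.loc[d, "groom_freq"] += 1.0
            raw.loc[d, "groom_dur"] += rec.duration
        else:
            raw.loc[d, "contact_freq"] += 1.0
    for sc in scans:
        d = canonical_dyad(*sc.dyad)
        if sc.within_1m and d in raw.index:
            raw.loc[d, "proximity"] += 1.0

    combined_hours = pd.Series(
        {d: effort_hours[d[0]] + effort_hours[d[1]] for d in dyads}
    )
    corrected = raw.div(combined_hours, axis=0)
    if proximity_by_scan_count:
        if scan_counts is None:
            raise ValidationError("proximity_by_scan_count requires scan_counts")
        n_scans = pd.Series({d: scan_counts.get(d, 0) for d in dyads})
        corrected["proximity"] = raw["proximity"].where(n_scans > 0, 0.0) / n_scans.replace(0, np.nan)
        corrected["proximity"] = corrected["proximity"].fillna(0.0)

    group_means = corrected.mean(axis=0)
    usable = [c for c in CSI_COMPONENTS if group_means[c] > 0]
    for c in CSI_COMPONENTS:
        if c not in usable:
            log.warning(
                "group %s: CSI component %s has zero group mean; dropped", group, c
            )
    if not usable:
        raise ValidationError(f"group {group}: no usable CSI component")

    ratios = corrected[usable].div(group_means[usable], axis=1)
    out = pd.DataFrame(
        {
            "id_a": [d[0] for d in dyads],
            "id_b": [d[1] for d in dyads],
            "group": group,
            "csi": ratios.mean(axis=1).to_numpy(),
        }
    )
    for c in usable:
        out[f"ratio_{c}"] = ratios[c].to_numpy()
    for c in CSI_COMPONENTS:
        out[f"corrected_{c}"] = corrected[c].to_numpy()
    return out


def dyad_covariates(
    elo_table: pd.DataFrame, csi_tables: list[pd.DataFrame]
) -> pd.DataFrame:
    """Ordered-dyad covariate table: Elo difference and CSI.

    One row per ordered (signaller, receiver) pair within each group;
    ``elo_difference`` is antisymmetric and ``csi`` symmetric in the dyad.
    """
    csi_lookup: dict[tuple[str, str], float] = {}
    for tab in csi_tables:
        for row in tab.itertuples():
            csi_lookup[(row.id_a, row.id_b)] = row.csi
    rows = []
    for group, sub in elo_table.groupby("group"):
        for s in sub.index:
            for r in sub.index:
                if s == r:
                    continue
                rows.append(
                    {
                        "signaller": s,
                        "receiver": r,
                        "group": group,
                        "elo_difference": elo_difference(elo_table, s, r),
                        "csi": csi_lookup.get(canonical_dyad(s, r), np.nan),
                    }
                )
    return pd.DataFrame(rows)
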