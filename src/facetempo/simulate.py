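"""Synthetic behavioural event streams with known ground truth.

The generator emulates the three observational input streams the
pipeline consumes — FACS-coded communicative bouts, decided dominance
interactions, and affiliation/proximity/effort records — for a
population of macaque-like individuals living in multi-male multi-female
groups.  Every latent quantity (per-individual dominance, per-dyad bond
strength, per-bout target intensity and variability, planted regression
effects) is returned alongside the data so parameter recovery can be
scored exactly.

Bout realisation inverts the metric definitions: the high-intensity
fraction of graded-AU time is set equal to the latent intensity, change
points are laid down so the change count matches the latent
unpredictable variability, and an RDAD episode covers the fraction of
movement frames implied by the latent predictable variability.  All
event boundaries are aligned to the frame grid, so with noise switched
off the metrics recover the planted values up to frame discretisation.
Realised (post-discretisation) per-bout values are part of the ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from .types import AffiliationRecord, AUEvent, Bout, DominanceInteraction, GazeSegment, ProximityScan, canonical_dyad

CONTEXTS = ("affiliation", "aggression", "copulation", "submission", "unknown")

#: RDAD code preference by context: lipsmack is affiliative, teeth
#: chatter submissive, tongue chatter common around copulation.
_CONTEXT_RDAD = {
    "affiliation": "AD181",
    "submission": "AD182",
    "copulation": "AD183",
    "aggression": "AD184",
    "unknown": "AD181",
}

_WINDOW_START = Date(2018, 4, 1)
_WINDOW_DAYS = 365


@dataclass
class SimConfig:
    """Study conditions for the simulated population and event streams.

    Context means mirror the qualitative structure the analysis is
    designed to detect: affiliative bouts are the least intense
    (mean 0.25 on the [0, 1] intensity scale versus 0.45-0.55 for
    aggression, submission and copulation) and the most variable
    (+0.2 changes/s), and intensity falls off quadratically with the
    squared dominance-rating difference (coefficient -1.4 on the
    log-intensity scale per squared standardized difference).
    """

    n_groups: int = 2
    n_males: int = 5  # per group
    n_females: int = 10  # per group
    n_bouts: int = 400
    fps: float = 25.0
    context_weights: dict = field(
        default_factory=lambda: {
            "affiliation": 0.35,
            "aggression": 0.20,
            "copulation": 0.10,
            "submission": 0.15,
            "unknown": 0.20,
        }
    )
    context_intensity: dict = field(
        default_factory=lambda: {
            "affiliation": 0.25,
            "aggression": 0.50,
            "copulation": 0.45,
            "submission": 0.55,
            "unknown": 0.35,
        }
    )
    context_var_unpred: dict = field(
        default_factory=lambda: {  # changes/s; affiliation elevated by +0.2
            "affiliation": 0.65,
            "aggression": 0.45,
            "copulation": 0.45,
            "submission": 0.45,
            "unknown": 0.45,
        }
    )
    rdad_prob: dict = field(
        default_factory=lambda: {
            "affiliation": 0.50,
            "aggression": 0.05,
            "copulation": 0.30,
            "submission": 0.40,
            "unknown": 0.20,
        }
    )
    elo2_coef: float = -1.4  # log-intensity per squared standardized Elo diff
    signaller_sd: float = 0.15  # random-intercept sd, log-intensity scale
    intensity_noise_sd: float = 0.10
    var_noise_sd: float = 0.15  # changes/s
    au27_prob: float = 0.15
    gaze_noise: float = 0.3  # prob. of a non-qualifying pad with a decoy event
    mean_duration_s: float = 8.0
    duration_sigma: float = 0.4  # lognormal sigma of clip durations
    dominance_steepness: float = 4.0
    dominance_spacing: float = 0.5  # latent-score gap between adjacent ranks
    interactions_per_dyad: float = 12.0
    cross_sex_interactions_per_dyad: float = 1.0
    bond_shape: float = 1.5
    bond_scale: float = 1.0
    groom_rate: float = 0.06  # events per bond unit per combined focal hour
    contact_rate: float = 0.05
    scan_rate: float = 0.08
    effort_hours_low: float = 20.0
    effort_hours_high: float = 80.0


@dataclass
class GroundTruth:
    dominance: dict  # individual -> latent score
    bonds: dict  # canonical dyad -> bond strength
    signaller_intercepts: dict
    context_intensity: dict
    context_var_unpred: dict
    elo2_coef: float
    bout_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------


def generate_population(config: SimConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Individuals with sex, group and latent dominance; dyadic bonds.

    Within each group every male's latent score sits strictly above every
    female's (inter-sexual conflicts in this species are won by males
    without exception), and scores are strictly ordered within sex.  Bond
    strengths are gamma-distributed (right-skewed: most dyads weak, few
    strong).
    """
    rng = np.random.default_rng(seed)
    rows = []
    dominance = {}
    gap = config.dominance_spacing
    for g in range(config.n_groups):
        gname = f"G{g + 1}"
        if config.n_males == 0:
            import logging

            logging.getLogger(__name__).warning(
                "group %s has no males; recalibration will be skipped", gname
            )
        for i in range(config.n_males):
            ind = f"{gname}M{i + 1:02d}"
            dominance[ind] = 1.0 + gap * (config.n_males - i)
            rows.append({"id": ind, "sex": "M", "group": gname})
        for i in range(config.n_females):
            ind = f"{gname}F{i + 1:02d}"
            dominance[ind] = -gap * i  # top female at 0, below every male
            rows.append({"id": ind, "sex": "F", "group": gname})
    individuals = pd.DataFrame(rows)
    bonds = {}
    for g, sub in individuals.groupby("group"):
        ids = sorted(sub["id"])
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                bonds[canonical_dyad(a, b)] = float(
                    rng.gamma(config.bond_shape, config.bond_scale)
                )
    intercepts = {
        ind: float(rng.normal(0.0, config.signaller_sd)) for ind in individuals["id"]
    }
    truth = GroundTruth(
        dominance=dominance,
        bonds=bonds,
        signaller_intercepts=intercepts,
        context_intensity=dict(config.context_intensity),
        context_var_unpred=dict(config.context_var_unpred),
        elo2_coef=config.elo2_coef,
    )
    return individuals, truth


def _random_date(rng) -> Date:
    return _WINDOW_START + timedelta(days=int(rng.integers(0, _WINDOW_DAYS)))


def generate_dominance_interactions(
    individuals: pd.DataFrame, truth: GroundTruth, config: SimConfig, seed: int
) -> list[DominanceInteraction]:
    """Dyadic decided interactions driven by latent dominance.

    Within sex, the higher-scoring individual wins with logistic
    probability in the score difference times the steepness.  Cross-sex
    interactions are always won by the male.
    """
    rng = np.random.default_rng(seed)
    itypes = ("displacement", "aggression", "submission")
    out = []
    for g, sub in individuals.groupby("group"):
        ids = list(sub["id"])
        sexes = dict(zip(sub["id"], sub["sex"]))
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                same_sex = sexes[a] == sexes[b]
                rate = (
                    config.interactions_per_dyad
                    if same_sex
                    else config.cross_sex_interactions_per_dyad
                )
                for _ in range(rng.poisson(rate)):
                    if same_sex:
                        d = truth.dominance[a] - truth.dominance[b]
                        p_a = 1.0 / (1.0 + math.exp(-config.dominance_steepness * d))
                        winner, loser = (a, b) if rng.random() < p_a else (b, a)
                    else:
                        winner, loser = (a, b) if sexes[a] == "M" else (b, a)
                    out.append(
                        DominanceInteraction(
                            _random_date(rng), winner, loser, itypes[rng.integers(3)]
                        )
                    )
    out.sort(key=lambda it: it.date)
    return out


def generate_affiliation_and_scans(
    individuals: pd.DataFrame, truth: GroundTruth, config: SimConfig, seed: int
) -> tuple[list[AffiliationRecord], list[ProximityScan], pd.DataFrame]:
    """Grooming, contact and proximity records proportional to bond strength.

    Observation effort is heterogeneous across individuals so the
    effort correction in the sociality index is actually exercised.
    """
    rng = np.random.default_rng(seed)
    effort = {
        ind: float(rng.uniform(config.effort_hours_low, config.effort_hours_high))
        for ind in individuals["id"]
    }
    records: list[AffiliationRecord] = []
    scans: list[ProximityScan] = []
    scan_no = 0
    for dyad, bond in truth.bonds.items():
        h = effort[dyad[0]] + effort[dyad[1]]
        for _ in range(rng.poisson(config.groom_rate * bond * h)):
            records.append(
                AffiliationRecord(
                    dyad, "groom", _random_date(rng), float(rng.lognormal(4.0, 0.6))
                )
            )
        for _ in range(rng.poisson(config.contact_rate * bond * h)):
            records.append(AffiliationRecord(dyad, "contact", _random_date(rng)))
        for _ in range(rng.poisson(config.scan_rate * bond * h)):
            scan_no += 1
            scans.append(ProximityScan(f"scan{scan_no:06d}", dyad, True))
    effort_df = individuals.copy()
    effort_df["hours"] = effort_df["id"].map(effort)
    return records, scans, effort_df


# ---------------------------------------------------------------------------
# bout realisation


def _alternating_runs(n_frames: int, high_frames: int, n_changes: int) -> list[tuple[int, str]]:
    """Split ``n_frames`` into alternating high/low runs with exactly
    ``n_changes`` level switches (fewer if frame counts cannot support
    them).  Returns (run_length_frames, level) pairs."""
    low_frames = n_frames - high_frames
    if high_frames == 0 or low_frames == 0:
        return [(n_frames, "high" if high_frames else "low")]
    n_runs = n_changes + 1
    # alternating runs need ceil(n/2) of the starting level, floor of the other
    while n_runs > 1:
        n_a, n_b = (n_runs + 1) // 2, n_runs // 2
        first_high = high_frames >= low_frames
        n_h, n_l = (n_a, n_b) if first_high else (n_b, n_a)
        if n_h <= high_frames and n_l <= low_frames:
            break
        n_runs -= 1
    else:
        n_runs = 1
    if n_runs == 1:  # cannot alternate: keep a single split (one change)
        return [(high_frames, "high"), (low_frames, "low")]
    first_high = high_frames >= low_frames
    n_h = (n_runs + 1) // 2 if first_high else n_runs // 2
    n_l = n_runs - n_h

    def split(total, parts):
        base, extra = divmod(total, parts)
        return [base + (1 if i < extra else 0) for i in range(parts)]

    highs = split(high_frames, n_h)
    lows = split(low_frames, n_l)
    runs = []
    hi_iter, lo_iter = iter(highs), iter(lows)
    level_high = first_high
    for _ in range(n_runs):
        runs.append((next(hi_iter) if level_high else next(lo_iter), "high" if level_high else "low"))
        level_high = not level_high
    return runs


def _realise_bout(
    bout_id: str,
    signaller: str,
    receiver: str,
    group: str,
    outcome: str,
    target_intensity: float,
    target_var_unpred: float,
    target_var_pred: float,
    config: SimConfig,
    rng,
) -> tuple[Bout, dict]:
    """Construct events whose metrics equal the targets up to frame
    rounding.  Returns the bout and the realised per-bout truth."""
    fps = config.fps
    n_frames = max(
        8, int(round(rng.lognormal(math.log(config.mean_duration_s), config.duration_sigma) * fps))
    )
    t_move = n_frames / fps

    pad_pre = 0.0
    decoy = None
    if rng.random() < config.gaze_noise:
        pad_frames = int(rng.integers(int(0.5 * fps), int(2 * fps)))
        pad_pre = pad_frames / fps
        # decoy movement while looking away: dropped by the gaze filter
        decoy = AUEvent("AU12", 0.0, pad_pre, "low")
    duration = pad_pre + t_move

    aus = ["AU26"]
    if rng.random() < 0.5:
        aus.append(str(rng.choice(["AU12", "AU10", "EAU3"])))
    n_au = len(aus)

    # AU27 spanning the whole window adds T27 to numerator and denominator;
    # inject only when the graded-AU high fraction can compensate, keeping
    # the realised intensity at its target up to frame rounding.
    with_au27 = False
    high_frames = int(round(target_intensity * n_frames))
    if rng.random() < config.au27_prob:
        h = int(round((target_intensity * (n_au + 1) * n_frames - n_frames) / n_au))
        if 0 <= h <= n_frames:
            with_au27 = True
            high_frames = h

    n_changes = int(round(target_var_unpred * duration))
    if n_changes == 0 and 0 < high_frames < n_frames:
        n_changes = 1  # a static face cannot carry a fractional intensity
    runs = _alternating_runs(n_frames, high_frames, n_changes)

    events: list[AUEvent] = []
    t = pad_pre
    for run_frames, level in runs:
        if run_frames == 0:
            continue
        end = t + run_frames / fps
        for au in aus:
            events.append(AUEvent(au, t, end, level))
        t = end
    if with_au27:
        events.append(AUEvent("AU27", pad_pre, pad_pre + t_move))

    rdad_frames = 0
    if target_var_pred > 0:
        rdad_frames = min(n_frames, max(1, int(round(0.5 * target_var_pred * n_frames))))
        code = _CONTEXT_RDAD[outcome]
        events.append(AUEvent(code, pad_pre, pad_pre + rdad_frames / fps))

    gaze = []
    if pad_pre > 0:
        gaze.append(GazeSegment(0.0, pad_pre, False, False, True))
        events.append(decoy)
    gaze.append(GazeSegment(pad_pre, duration, True))

    bout = Bout(
        bout_id=bout_id,
        signaller=signaller,
        receiver=receiver,
        group=group,
        outcome=outcome,
        fps=fps,
        duration=duration,
        events=sorted(events, key=lambda e: (e.onset, e.au_code)),
        gaze=gaze,
    )
    # realised values after discretisation
    t27 = n_frames if with_au27 else 0
    high_total = sum(
        rf for rf, lv in runs if lv == "high"
    ) * n_au + t27
    total = n_au * n_frames + t27
    realised = {
        "bout_id": bout_id,
        "target_intensity": target_intensity,
        "realised_intensity": high_total / total,
        "target_var_unpredictable": target_var_unpred,
        "realised_var_unpredictable": (len([r for r in runs if r[0] > 0]) - 1) / duration,
        "target_var_predictable": target_var_pred,
        "realised_var_predictable": 2.0 * rdad_frames / n_frames,
    }
    return bout, realised


def generate_bouts(
    individuals: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    seed: int,
) -> list[Bout]:
    """Communicative bouts with planted context and dominance effects.

    Latent log intensity is the log context mean plus the quadratic
    dominance-difference term plus a signaller random intercept plus
    noise; unpredictable variability is the context rate plus noise;
    predictable variability arises from context-dependent RDAD episodes.
    Appends the per-bout realised truth to ``truth.bout_truth``.
    """
    rng = np.random.default_rng(seed)
    contexts = list(config.context_weights)
    weights = np.array([config.context_weights[c] for c in contexts], float)
    weights /= weights.sum()
    dom = truth.dominance
    spread = max(dom.values()) - min(dom.values())
    by_group = {g: list(sub["id"]) for g, sub in individuals.groupby("group")}
    groups = sorted(by_group)
    bouts = []
    rows = []
    for i in range(config.n_bouts):
        g = groups[int(rng.integers(len(groups)))]
        ids = by_group[g]
        s, r = (str(x) for x in rng.choice(ids, size=2, replace=False))
        ctx = contexts[int(rng.choice(len(contexts), p=weights))]
        z = (dom[s] - dom[r]) / spread  # standardized dominance difference
        log_i = (
            math.log(config.context_intensity[ctx])
            + config.elo2_coef * z * z
            + truth.signaller_intercepts[s]
            + rng.normal(0.0, config.intensity_noise_sd)
        )
        target_i = min(max(math.exp(log_i), 0.02), 0.98)
        target_vu = max(0.0, config.context_var_unpred[ctx] + rng.normal(0.0, config.var_noise_sd))
        target_vp = 0.0
        if rng.random() < config.rdad_prob[ctx]:
            target_vp = 2.0 * rng.beta(2.0, 2.0)
        bout, realised = _realise_bout(
            f"bout{i + 1:05d}", s, r, g, ctx, target_i, target_vu, target_vp, config, rng
        )
        realised.update({"signaller": s, "receiver": r, "outcome": ctx, "z_dominance": z})
        bouts.append(bout)
        rows.append(realised)
    truth.bout_truth = pd.DataFrame(rows)
    return bouts


def generate_all(config: SimConfig, seed: int):
    """Generate every input stream from one master seed.

    Sub-seeds are derived deterministically, so any stream can be
    regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    individuals, truth = generate_population(config, subseeds[0])
    interactions = generate_dominance_interactions(individuals, truth, config, subseeds[1])
    affil, scans, effort = generate_affiliation_and_scans(individuals, truth, config, subseeds[2])
    bouts = generate_bouts(individuals, truth, config, subseeds[3])
    return {
        "individuals": individuals,
        "truth": truth,
        "dominance": interactions,
        "affiliation": affil,
        "scans": scans,
        "effort": effort,
        "bouts": bouts,
    }
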