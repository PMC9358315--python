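"""Per-bout facial-movement metrics: intensity and variability.

Three quantities are computed for every analysable bout, after applying
the gaze-inclusion rule:

* **intensity** — the fraction of graded-AU time produced at high
  intensity, with AU27 counted as high-grade AU26 throughout::

      intensity = (H10 + H12 + H26 + H_EAU3 + T27)
                  / (T10 + T12 + T26 + T_EAU3 + T27)

  where ``Hn`` is the time AU *n* was at high intensity and ``Tn`` its
  total active time.  Always in [0, 1] for a valid bout.

* **unpredictable variability** — the number of changes in AU
  combination plus the number of changes in intensity grade of the four
  graded AUs, divided by the clip length in seconds (changes/s).

* **predictable variability** — the fraction of movement frames during
  which at least one RDAD (lipsmack, teeth chatter, tongue chatter, jaw
  wobble) was active, multiplied by 2 because these oscillatory displays
  run at roughly 2 Hz.  Bounded in [0, 2].

Total variability is the sum of the two components.  Note the deliberate
denominator asymmetry: the unpredictable component is normalised by clip
length in seconds while the predictable component is normalised by
movement duration in frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AUEvent,
    Bout,
    CODEABLE_AUS,
    CORE_AUS,
    RDAD_CODES,
)

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class FaceState:
    """A maximal interval over which the facial configuration is constant.

    ``active_aus`` excludes RDADs: oscillatory displays feed the
    predictable component only and do not define configurations.
    """

    start: float
    end: float
    active_aus: frozenset[str]
    intensities: tuple[tuple[str, str], ...]  # sorted (au, level) pairs, graded AUs only

    @property
    def duration(self) -> float:
        return self.end - self.start

    def intensity_map(self) -> dict[str, str]:
        return dict(self.intensities)


@dataclass
class BoutMetrics:
    bout_id: str
    intensity: float
    var_unpredictable: float  # changes / s
    var_predictable: float  # dimensionless, [0, 2]
    movement_duration_frames: int
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def var_total(self) -> float:
        return self.var_unpredictable + self.var_predictable


# ---------------------------------------------------------------------------
# gaze filter


def qualifying_intervals(bout: Bout) -> list[tuple[float, float]]:
    """Union of gaze segments during which movements are analysed.

    A segment qualifies when the signaller looks at the target, or is in
    body contact with the target and not looking at a second individual.
    Time with no gaze annotation is conservatively non-qualifying.
    """
    ivs = [
        (seg.start, seg.end)
        for seg in sorted(bout.gaze, key=lambda s: s.start)
        if seg.qualifies()
    ]
    merged: list[tuple[float, float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + _EPS:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def filter_gaze(bout: Bout) -> Bout:
    """Clip the bout's events to qualifying gaze time.

    Events wholly outside qualifying time are dropped; events straddling a
    boundary are truncated (and split if they span a non-qualifying gap).
    A bout left with no graded-AU/AU27 time is flagged ``excluded`` and
    carried forward so the pipeline can report it.
    """
    windows = qualifying_intervals(bout)
    clipped: list[AUEvent] = []
    n_truncated = 0
    for ev in bout.events:
        for ws, we in windows:
            s = max(ev.onset, ws)
            e = min(ev.offset, we)
            if e - s > _EPS:
                if s > ev.onset + _EPS or e < ev.offset - _EPS:
                    n_truncated += 1
                clipped.append(
                    AUEvent(ev.au_code, s, e, ev.intensity)
                    if (s != ev.onset or e != ev.offset)
                    else ev
                )
    if n_truncated:
        log.debug("bout %s: %d event(s) truncated by gaze rule", bout.bout_id, n_truncated)
    if not any(ev.au_code in CORE_AUS for ev in clipped):
        log.info("bout %s: excluded, no qualifying facial movement", bout.bout_id)
        return bout.with_events(
            clipped, excluded=True, exclusion_reason="no qualifying gaze time"
        )
    return bout.with_events(clipped)


# ---------------------------------------------------------------------------
# face-state segmentation


def segment_face_states(bout: Bout) -> list[FaceState]:
    """Partition movement time into maximal constant-configuration states.

    A state is the set of active non-RDAD AUs together with the intensity
    grades of the active graded AUs.  Neutral time (no non-RDAD AU active)
    separates states and belongs to no state.  If the same graded AU is
    active twice simultaneously at different grades, ``high`` wins.
    """
    events = [ev for ev in bout.events if not ev.is_rdad()]
    if not events:
        return []
    bounds = sorted({t for ev in events for t in (ev.onset, ev.offset)})
    states: list[FaceState] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo <= _EPS:
            continue
        mid = 0.5 * (lo + hi)
        active: set[str] = set()
        grades: dict[str, str] = {}
        for ev in events:
            if ev.onset <= mid < ev.offset:
                active.add(ev.au_code)
                if ev.au_code in CODEABLE_AUS:
                    prev = grades.get(ev.au_code)
                    grades[ev.au_code] = (
                        "high" if ("high" in (prev, ev.intensity)) else ev.intensity
                    )
        if not active:
            continue
        sig = (frozenset(active), tuple(sorted(grades.items())))
        if (
            states
            and abs(states[-1].end - lo) <= _EPS
            and (states[-1].active_aus, states[-1].intensities) == sig
        ):
            states[-1] = FaceState(states[-1].start, hi, *sig)
        else:
            states.append(FaceState(lo, hi, *sig))
    return states


def count_state_changes(
    states: list[FaceState], count_neutral_transitions: bool = False
) -> tuple[int, int]:
    """Count (combination changes, intensity changes) between adjacent states.

    Only transitions between temporally contiguous states are counted: the
    moves from neutral into the first configuration, back to neutral at the
    end, and across neutral gaps are not changes *between* coded
    configurations.  Set ``count_neutral_transitions`` to also count each
    entry into / exit from neutral as a combination change.  A transition
    differing in both combination and grade counts once, as a combination
    change.
    """
    n_comb = 0
    n_int = 0
    for prev, cur in zip(states[:-1], states[1:]):
        contiguous = abs(cur.start - prev.end) <= _EPS
        if not contiguous:
            if count_neutral_transitions:
                n_comb += 2  # prev -> neutral, neutral -> cur
            continue
        if prev.active_aus != cur.active_aus:
            n_comb += 1
        elif prev.intensities != cur.intensities:
            n_int += 1
    return n_comb, n_int


# ---------------------------------------------------------------------------
# metric computations


def compute_intensity(bout: Bout) -> float:
    """High-grade fraction of graded-AU time, AU27 counted as high AU26."""
    high = 0.0
    total = 0.0
    for ev in bout.events:
        if ev.au_code in CODEABLE_AUS:
            total += ev.duration
            if ev.intensity == "high":
                high += ev.duration
        elif ev.au_code == "AU27":
            total += ev.duration
            high += ev.duration
    if total <= _EPS:
        raise ValueError(
            f"bout {bout.bout_id}: intensity undefined (no graded-AU time)"
        )
    return high / total


def _frame_activity(bout: Bout, codes: tuple[str, ...] | None = None) -> np.ndarray:
    """Boolean per-frame activity raster.

    Frame ``i`` spans ``[i/fps, (i+1)/fps)``; it is active when any
    selected event covers the frame midpoint.
    """
    n_frames = max(1, round(bout.duration * bout.fps))
    mids = (np.arange(n_frames) + 0.5) / bout.fps
    active = np.zeros(n_frames, dtype=bool)
    for ev in bout.events:
        if codes is None or ev.au_code in codes:
            active |= (mids >= ev.onset) & (mids < ev.offset)
    return active


def compute_unpredictable_variability(
    bout: Bout, count_neutral_transitions: bool = False
) -> float:
    """Configuration plus grade changes per second of clip."""
    if bout.duration <= 0:
        raise ValueError(f"bout {bout.bout_id}: zero duration")
    states = segment_face_states(bout)
    n_comb, n_int = count_state_changes(states, count_neutral_transitions)
    return (n_comb + n_int) / bout.duration


def compute_predictable_variability(bout: Bout) -> tuple[float, int]:
    """RDAD-active movement-frame fraction times two.

    Returns ``(value, movement_duration_frames)``.  Overlapping RDADs are
    unioned (no double counting).  Raises if no movement frames exist.
    """
    movement = _frame_activity(bout)  # any facial movement, RDADs included
    n_movement = int(movement.sum())
    if n_movement == 0:
        raise ValueError(f"bout {bout.bout_id}: no movement frames")
    rdad = _frame_activity(bout, RDAD_CODES) & movement
    return 2.0 * int(rdad.sum()) / n_movement, n_movement


def compute_bout_metrics(
    bout: Bout, count_neutral_transitions: bool = False
) -> BoutMetrics:
    """Assemble intensity and the variability components for one bout.

    The bout must already have passed :func:`filter_gaze`; excluded bouts
    come back as excluded metric rows with NaN values.
    """
    if bout.excluded:
        return BoutMetrics(
            bout.bout_id,
            math.nan,
            math.nan,
            math.nan,
            0,
            excluded=True,
            exclusion_reason=bout.exclusion_reason,
        )
    intensity = compute_intensity(bout)
    var_unpred = compute_unpredictable_variability(bout, count_neutral_transitions)
    var_pred, n_frames = compute_predictable_variability(bout)
    return BoutMetrics(bout.bout_id, intensity, var_unpred, var_pred, n_frames)


def score_bouts(
    bouts: list[Bout],
    apply_gaze_filter: bool = True,
    count_neutral_transitions: bool = False,
) -> pd.DataFrame:
    """Gaze-filter and score a list of bouts into a tidy metrics table."""
    rows = []
    n_excluded = 0
    for bout in bouts:
        b = filter_gaze(bout) if apply_gaze_filter else bout
        m = compute_bout_metrics(b, count_neutral_transitions)
        n_excluded += m.excluded
        rows.append(
            {
                "bout_id": m.bout_id,
                "signaller": b.signaller,
                "receiver": b.receiver,
                "group": b.group,
                "outcome": b.outcome,
                "intensity": m.intensity,
                "var_unpredictable": m.var_unpredictable,
                "var_predictable": m.var_predictable,
                "var_total": m.var_total,
                "movement_duration_frames": m.movement_duration_frames,
                "excluded": m.excluded,
            }
        )
    if n_excluded:
        log.info("%d/%d bouts excluded by the gaze rule", n_excluded, len(bouts))
    return pd.DataFrame(rows)
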