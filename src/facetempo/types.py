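"""Core domain types for FACS-coded communicative bouts.

A *bout* is one continuous communicative interaction by a signaller toward
a receiver, captured as a trimmed video clip and coded as a stream of
action-unit (AU) activation intervals plus gaze annotation segments.

Four AUs are conspicuous enough to carry a two-level intensity grade
(low/high): AU10 (upper lip raiser), AU12 (lip corner puller), AU26
(jaw drop) and EAU3 (ear flattener).  AU27 (jaw stretch) is treated as an
exaggerated AU26 and carries no grade of its own.  Repetitive dynamic
action descriptors (RDADs) are ritualized oscillatory displays coded as
units: AD181 lipsmack, AD182 teeth chatter, AD183 tongue chatter, AD184
jaw wobble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date

#: AUs for which a low/high intensity grade is coded.
CODEABLE_AUS = ("AU10", "AU12", "AU26", "EAU3")

#: Repetitive dynamic action descriptors (oscillatory displays, ~2 Hz).
RDAD_CODES = ("AD181", "AD182", "AD183", "AD184")

#: AUs entering the intensity ratio (codeable AUs plus AU27).
CORE_AUS = CODEABLE_AUS + ("AU27",)

#: Interaction-outcome categories, in factor-level order.
OUTCOMES = ("affiliation", "aggression", "copulation", "submission", "unknown")

#: Signaller-first sex combinations, in factor-level order.
SEX_COMBINATIONS = ("FF", "FM", "MF", "MM")

INTENSITY_LEVELS = ("low", "high")


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


class SchemaError(ValueError):
    """Raised when an input file lacks a required column."""


@dataclass(frozen=True)
class AUEvent:
    """One activation interval of a single AU within a bout.

    Times are seconds from bout start.  ``intensity`` is ``"low"`` or
    ``"high"`` for the four codeable AUs and ``"uncoded"`` otherwise.
    """

    au_code: str
    onset: float
    offset: float
    intensity: str = "uncoded"

    def validate(self, bout_id: str = "?") -> None:
        if not self.offset > self.onset >= 0:
            raise ValidationError(
                f"bout {bout_id}: event {self.au_code} requires offset > onset >= 0 "
                f"(got onset={self.onset}, offset={self.offset})"
            )
        if self.au_code in CODEABLE_AUS:
            if self.intensity not in INTENSITY_LEVELS:
                raise ValidationError(
                    f"bout {bout_id}: {self.au_code} must carry intensity low/high, "
                    f"got {self.intensity!r}"
                )
        elif self.intensity != "uncoded":
            raise ValidationError(
                f"bout {bout_id}: {self.au_code} cannot carry an intensity grade "
                f"(got {self.intensity!r}); only {'/'.join(CODEABLE_AUS)} are graded"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def is_rdad(self) -> bool:
        return self.au_code in RDAD_CODES


@dataclass(frozen=True)
class GazeSegment:
    """Gaze/contact annotation over ``[start, end)`` seconds of a bout."""

    start: float
    end: float
    looking_at_target: bool
    in_body_contact: bool = False
    looking_at_second_individual: bool = False

    def validate(self, bout_id: str = "?") -> None:
        if not self.end > self.start >= 0:
            raise ValidationError(
                f"bout {bout_id}: gaze segment requires end > start >= 0 "
                f"(got {self.start}..{self.end})"
            )

    def qualifies(self) -> bool:
        """Movement during this segment counts toward the analysis.

        Qualifying time is where the signaller is looking at the target, or
        is in body contact with the target while not looking at a second
        individual.
        """
        if self.looking_at_target:
            return True
        return self.in_body_contact and not self.looking_at_second_individual


@dataclass
class Bout:
    """One communicative interaction with its timed AU events and gaze."""

    bout_id: str
    signaller: str
    receiver: str
    group: str
    outcome: str
    fps: float
    duration: float
    events: list[AUEvent] = field(default_factory=list)
    gaze: list[GazeSegment] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""

    def validate(self) -> None:
        if self.signaller == self.receiver:
            raise ValidationError(f"bout {self.bout_id}: signaller == receiver")
        if self.outcome not in OUTCOMES:
            raise ValidationError(
                f"bout {self.bout_id}: unknown outcome {self.outcome!r}"
            )
        if self.duration <= 0 or self.fps <= 0:
            raise ValidationError(
                f"bout {self.bout_id}: duration and fps must be positive"
            )
        for ev in self.events:
            ev.validate(self.bout_id)
            if ev.offset > self.duration + 1e-9:
                raise ValidationError(
                    f"bout {self.bout_id}: event {ev.au_code} ends at {ev.offset}s, "
                    f"beyond clip duration {self.duration}s"
                )
        last_end = 0.0
        for seg in sorted(self.gaze, key=lambda s: s.start):
            seg.validate(self.bout_id)
            if seg.start < last_end - 1e-9:
                raise ValidationError(
                    f"bout {self.bout_id}: overlapping gaze segments"
                )
            last_end = seg.end
        if not any(ev.au_code in CORE_AUS for ev in self.events):
            raise ValidationError(
                f"bout {self.bout_id}: no codeable AU "
                f"({', '.join(CORE_AUS)}) present"
            )

    def with_events(self, events: list[AUEvent], **changes) -> "Bout":
        return replace(self, events=events, **changes)


@dataclass(frozen=True)
class DominanceInteraction:
    """One decided dominance interaction (displacement, unidirectional
    aggression or submission) with a winner and a loser."""

    date: Date
    winner: str
    loser: str
    itype: str  # displacement | aggression | submission

    def validate(self) -> None:
        if self.winner == self.loser:
            raise ValidationError(
                f"dominance interaction on {self.date}: winner == loser "
                f"({self.winner})"
            )
        if self.itype not in ("displacement", "aggression", "submission"):
            raise ValidationError(f"unknown interaction type {self.itype!r}")


@dataclass(frozen=True)
class AffiliationRecord:
    """A grooming or affiliative-contact event between an unordered dyad."""

    dyad: tuple[str, str]  # canonical: lexicographically sorted
    kind: str  # groom | contact
    date: Date
    duration: float = 0.0  # seconds; grooms only

    def validate(self) -> None:
        if self.kind not in ("groom", "contact"):
            raise ValidationError(f"unknown affiliation kind {self.kind!r}")
        if self.kind == "groom" and self.duration <= 0:
            raise ValidationError("groom record requires duration > 0")


@dataclass(frozen=True)
class ProximityScan:
    """One scan record: was the dyad within 1 m at the scan instant?"""

    timestamp: str
    dyad: tuple[str, str]
    within_1m: bool


def canonical_dyad(a: str, b: str) -> tuple[str, str]:
    """Unordered dyads are canonicalised as the sorted ID pair."""
    if a == b:
        raise ValidationError(f"self-dyad {a!r}")
    return (a, b) if a < b else (b, a)
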