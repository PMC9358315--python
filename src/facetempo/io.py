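"""Reading, validating and writing the tabular input/output streams.

All files are delimited text (comma or tab, auto-detected from the
header line), decimal point ``.``, dates ISO-8601.  The bout stream is a
long-format event log modelled on behavioural-observation-software
exports: one row per AU activation or gaze segment, grouped by
``bout_id``.  The roster/effort file carries each individual's sex,
group and focal observation hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .types import (
    AffiliationRecord,
    AUEvent,
    Bout,
    DominanceInteraction,
    GazeSegment,
    ProximityScan,
    SchemaError,
    ValidationError,
    canonical_dyad,
)

log = logging.getLogger(__name__)

BOUT_COLUMNS = [
    "bout_id",
    "signaller",
    "receiver",
    "group",
    "outcome",
    "fps",
    "duration",
    "record",
    "code",
    "onset",
    "offset",
    "intensity",
    "looking_at_target",
    "in_body_contact",
    "looking_at_second",
]
DOMINANCE_COLUMNS = ["date", "winner", "loser", "itype"]
AFFILIATION_COLUMNS = ["id_a", "id_b", "kind", "date", "duration"]
SCAN_COLUMNS = ["timestamp", "id_a", "id_b", "within_1m"]
EFFORT_COLUMNS = ["id", "sex", "group", "hours"]


@dataclass
class IOConfig:
    delimiter: str | None = None  # None -> auto-detect from the header line
    default_fps: float = 25.0


def _detect_delimiter(path, config: IOConfig | None) -> str:
    if config and config.delimiter:
        return config.delimiter
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path, required: list[str], config: IOConfig | None = None) -> pd.DataFrame:
    sep = _detect_delimiter(path, config)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _parse_bool(token: str) -> bool:
    return str(token).strip().lower() in ("1", "true", "t", "yes")


# ---------------------------------------------------------------------------
# bouts


def read_bouts(path, config: IOConfig | None = None) -> list[Bout]:
    """Parse and validate a long-format bout event log."""
    df = _read_table(path, BOUT_COLUMNS, config)
    bouts: list[Bout] = []
    for bout_id, sub in df.groupby("bout_id", sort=False):
        head = sub.iloc[0]
        events: list[AUEvent] = []
        gaze: list[GazeSegment] = []
        for _, row in sub.iterrows():
            try:
                onset, offset = float(row["onset"]), float(row["offset"])
            except ValueError as exc:
                raise ValidationError(
                    f"bout {bout_id}: unparseable time {row['onset']!r}/{row['offset']!r}"
                ) from exc
            if row["record"] == "au":
                intensity = row["intensity"].strip() or "uncoded"
                events.append(AUEvent(row["code"], onset, offset, intensity))
            elif row["record"] == "gaze":
                gaze.append(
                    GazeSegment(
                        onset,
                        offset,
                        _parse_bool(row["looking_at_target"]),
                        _parse_bool(row["in_body_contact"]),
                        _parse_bool(row["looking_at_second"]),
                    )
                )
            else:
                raise ValidationError(
                    f"bout {bout_id}: unknown record type {row['record']!r}"
                )
        fps = float(head["fps"]) if head["fps"] else (config.default_fps if config else 25.0)
        bout = Bout(
            bout_id=str(bout_id),
            signaller=head["signaller"],
            receiver=head["receiver"],
            group=head["group"],
            outcome=head["outcome"],
            fps=fps,
            duration=float(head["duration"]),
            events=events,
            gaze=gaze,
        )
        bout.validate()
        bouts.append(bout)
    if not bouts:
        log.warning("%s: no bouts found", path)
    return bouts


def write_bouts(bouts: list[Bout], path, sep: str = ",") -> None:
    rows = []
    for b in bouts:
        base = {
            "bout_id": b.bout_id,
            "signaller": b.signaller,
            "receiver": b.receiver,
            "group": b.group,
            "outcome": b.outcome,
            "fps": b.fps,
            "duration": b.duration,
        }
        for ev in b.events:
            rows.append(
                {
                    **base,
                    "record": "au",
                    "code": ev.au_code,
                    "onset": ev.onset,
                    "offset": ev.offset,
                    "intensity": "" if ev.intensity == "uncoded" else ev.intensity,
                    "looking_at_target": "",
                    "in_body_contact": "",
                    "looking_at_second": "",
                }
            )
        for seg in b.gaze:
            rows.append(
                {
                    **base,
                    "record": "gaze",
                    "code": "",
                    "onset": seg.start,
                    "offset": seg.end,
                    "intensity": "",
                    "looking_at_target": str(seg.looking_at_target).lower(),
                    "in_body_contact": str(seg.in_body_contact).lower(),
                    "looking_at_second": str(seg.looking_at_second_individual).lower(),
                }
            )
    pd.DataFrame(rows, columns=BOUT_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# dominance


def read_dominance(path, config: IOConfig | None = None) -> list[DominanceInteraction]:
    df = _read_table(path, DOMINANCE_COLUMNS, config)
    if df.empty:
        log.warning("%s: no dominance interactions", path)
        return []
    out = []
    for _, row in df.iterrows():
        it = DominanceInteraction(
            Date.fromisoformat(row["date"]), row["winner"], row["loser"], row["itype"]
        )
        it.validate()
        out.append(it)
    return out


def write_dominance(interactions: list[DominanceInteraction], path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {"date": it.date.isoformat(), "winner": it.winner, "loser": it.loser, "itype": it.itype}
            for it in interactions
        ],
        columns=DOMINANCE_COLUMNS,
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# affiliation / scans / effort


def read_effort(path, config: IOConfig | None = None) -> pd.DataFrame:
    """Roster-plus-effort table: id, sex (M/F), group, focal hours."""
    df = _read_table(path, EFFORT_COLUMNS, config)
    df["hours"] = df["hours"].astype(float)
    if (df["hours"] <= 0).any():
        bad = df.loc[df["hours"] <= 0, "id"].tolist()
        raise ValidationError(f"non-positive effort hours for: {', '.join(bad)}")
    if not df["sex"].isin(["M", "F"]).all():
        raise ValidationError(f"{path}: sex must be M or F")
    return df.reset_index(drop=True)


def read_affiliation(
    affil_path, scans_path, effort_path, config: IOConfig | None = None
) -> tuple[list[AffiliationRecord], list[ProximityScan], pd.DataFrame]:
    """Read affiliation events, proximity scans and the effort table.

    Any individual referenced by a record but absent from the effort
    table is an error (effort correction would be undefined).
    """
    effort = read_effort(effort_path, config)
    known = set(effort["id"])

    adf = _read_table(affil_path, AFFILIATION_COLUMNS, config)
    if adf.empty:
        log.warning("%s: no affiliation records", affil_path)
    records = []
    for _, row in adf.iterrows():
        rec = AffiliationRecord(
            canonical_dyad(row["id_a"], row["id_b"]),
            row["kind"],
            Date.fromisoformat(row["date"]) if row["date"] else None,
            float(row["duration"]) if row["duration"] else 0.0,
        )
        rec.validate()
        records.append(rec)

    sdf = _read_table(scans_path, SCAN_COLUMNS, config)
    scans = [
        ProximityScan(
            row["timestamp"],
            canonical_dyad(row["id_a"], row["id_b"]),
            _parse_bool(row["within_1m"]),
        )
        for _, row in sdf.iterrows()
    ]

    unknown = sorted(
        {i for rec in records for i in rec.dyad if i not in known}
        | {i for sc in scans for i in sc.dyad if i not in known}
    )
    if unknown:
        raise ValidationError(
            f"individuals not present in effort table: {', '.join(unknown)}"
        )
    return records, scans, effort


def write_affiliation(records: list[AffiliationRecord], path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {
                "id_a": r.dyad[0],
                "id_b": r.dyad[1],
                "kind": r.kind,
                "date": r.date.isoformat() if r.date else "",
                "duration": r.duration if r.kind == "groom" else "",
            }
            for r in records
        ],
        columns=AFFILIATION_COLUMNS,
    ).to_csv(path, sep=sep, index=False)


def write_scans(scans: list[ProximityScan], path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {
                "timestamp": s.timestamp,
                "id_a": s.dyad[0],
                "id_b": s.dyad[1],
                "within_1m": str(s.within_1m).lower(),
            }
            for s in scans
        ],
        columns=SCAN_COLUMNS,
    ).to_csv(path, sep=sep, index=False)


def write_effort(effort: pd.DataFrame, path, sep: str = ",") -> None:
    effort[EFFORT_COLUMNS].to_csv(path, sep=sep, index=False)


def write_metrics(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a derived metric table with a stable column order."""
    table.to_csv(path, sep=sep, index=False)
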