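"""Readers and writers for lickometer event streams and experiment metadata.

Two on-disk layouts are supported for lick timestamps:

* plain long-format CSV — one row per lick with subject / day / concentration
  columns, the format the rest of the pipeline writes; and
* MED-PC text data files — the session files produced by Med Associates
  acquisition software: a block of ``Key: value`` header lines (``Start Date``,
  ``Subject``, ``Box``, ...) followed by named numeric arrays printed five
  elements per line behind a leading element-index field (``     0:``).

Timestamps are stored in seconds as floats; the 0.01 s device resolution of a
contact lickometer is *validated*, never enforced by an integer type, so
synthetic and real data travel the same path.  Two licks registered in the
same 0.01 s tick are kept as two licks: a contact sensor reports discrete
contacts and merging them would bias cluster sizes downward.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: device resolution of the contact lickometer, in seconds
TICK_RESOLUTION = 0.01

HANDLING_LEVELS = ("tail", "tunnel")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LickTrain:
    """One subject-session's ordered lick timestamps plus session metadata.

    Parameters
    ----------
    subject_id : str
        Animal identifier.
    session_day : int
        Study day on which the session ran.
    concentration : float
        Sucrose concentration, percent w/w (e.g. 4 or 16).
    timestamps : tuple of float
        Lick times in seconds from session start, non-decreasing, each an
        integer multiple of the 0.01 s lickometer resolution.
    session_duration : float
        Session length in seconds (default 900 = 15 min).
    """

    subject_id: str
    session_day: int
    concentration: float
    timestamps: tuple[float, ...]
    session_duration: float = 900.0

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", tuple(ts.tolist()))
        if ts.size:
            if np.any(np.diff(ts) < 0):
                raise ValidationError(
                    f"{self.subject_id} day {self.session_day}: timestamps not sorted"
                )
            if ts[0] < 0 or ts[-1] > self.session_duration + 1e-9:
                raise ValidationError(
                    f"{self.subject_id} day {self.session_day}: timestamps outside "
                    f"[0, {self.session_duration}]"
                )
            # each timestamp must sit on the 0.01 s grid up to float noise
            ticks = ts / TICK_RESOLUTION
            if np.max(np.abs(ticks - np.round(ticks))) > 1e-6:
                raise ValidationError(
                    f"{self.subject_id} day {self.session_day}: timestamps not on "
                    f"the {TICK_RESOLUTION} s resolution grid"
                )

    @property
    def n_licks(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SubjectRecord:
    """Experiment metadata for one animal."""

    subject_id: str
    cage_id: str
    handling: str                  # "tail" | "tunnel"
    body_weight: float | None = None   # grams; None when not recorded
    testing_group: int | None = None   # 1-4 counterbalancing group

    def __post_init__(self):
        if self.handling not in HANDLING_LEVELS:
            raise ValidationError(
                f"subject {self.subject_id}: handling must be one of "
                f"{HANDLING_LEVELS}, got {self.handling!r}"
            )
        if self.body_weight is not None and not (
            math.isfinite(self.body_weight) and self.body_weight > 0
        ):
            raise ValidationError(
                f"subject {self.subject_id}: body weight must be finite and > 0"
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    """Mass of sucrose solution consumed in one session."""

    subject_id: str
    session_day: int
    concentration: float
    mass_consumed: float  # grams

    def __post_init__(self):
        if not math.isfinite(self.mass_consumed) or self.mass_consumed < 0:
            raise ValidationError(
                f"subject {self.subject_id} day {self.session_day}: mass_consumed "
                f"must be finite and >= 0, got {self.mass_consumed}"
            )


# ---------------------------------------------------------------------------
# CSV lick events
# ---------------------------------------------------------------------------

DEFAULT_LICK_COLUMNS = {
    "subject": "subject_id",
    "day": "session_day",
    "concentration": "concentration",
    "timestamp": "timestamp",
}


def read_lick_csv(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    session_duration: float = 900.0,
    metadata: pd.DataFrame | None = None,
) -> list[LickTrain]:
    """Read long-format lick events, one :class:`LickTrain` per (subject, day).

    Parameters
    ----------
    path : path
        CSV with one row per lick.
    columns : mapping, optional
        Maps the logical names ``subject``, ``day``, ``concentration``,
        ``timestamp`` to the file's column names.  Defaults to the names this
        package writes.
    session_duration : float
        Session length in seconds assigned to every train.
    metadata : DataFrame, optional
        If given, (subject, day, concentration) rows present here but absent
        from the lick file yield empty trains (a session in which the animal
        never licked is data, not a parse failure).

    Raises
    ------
    SchemaError
        A required column is missing (named in the message).
    ValidationError
        A negative timestamp, with its row number.
    """
    colmap = dict(DEFAULT_LICK_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    for logical, name in colmap.items():
        if name not in df.columns:
            raise SchemaError(f"{path}: missing required column {name!r} ({logical})")

    ts_col = colmap["timestamp"]
    neg = df.index[df[ts_col] < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative timestamp at row {int(neg[0]) + 2}"  # 1-based + header
        )

    trains: list[LickTrain] = []
    keys = [colmap["subject"], colmap["day"], colmap["concentration"]]
    for (subj, day, conc), grp in df.groupby(keys, sort=True):
        ts = np.sort(grp[ts_col].to_numpy(dtype=float))
        if not np.array_equal(ts, grp[ts_col].to_numpy(dtype=float)):
            logger.warning(
                "lick timestamps out of order for subject %s day %s; sorted", subj, day
            )
        trains.append(
            LickTrain(
                subject_id=str(subj),
                session_day=int(day),
                concentration=float(conc),
                timestamps=tuple(np.round(ts, 2)),
                session_duration=session_duration,
            )
        )

    if metadata is not None:
        seen = {(t.subject_id, t.session_day) for t in trains}
        for _, row in metadata.iterrows():
            key = (str(row["subject_id"]), int(row["session_day"]))
            if key not in seen:
                trains.append(
                    LickTrain(
                        subject_id=key[0],
                        session_day=key[1],
                        concentration=float(row["concentration"]),
                        timestamps=(),
                        session_duration=session_duration,
                    )
                )
        trains.sort(key=lambda t: (t.subject_id, t.session_day))
    return trains


def write_lick_csv(trains: Iterable[LickTrain], path: str | Path) -> None:
    """Write lick trains as long-format CSV (UTF-8, header row, '.' decimals)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "session_day", "concentration", "timestamp"])
        for t in trains:
            for ts in t.timestamps:
                w.writerow([t.subject_id, t.session_day, t.concentration, f"{ts:.2f}"])


# ---------------------------------------------------------------------------
# MED-PC text data files
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "Start Date", "End Date", "Subject", "Experiment", "Group", "Box",
    "Start Time", "End Time", "MSN",
}
_ARRAY_RE = re.compile(r"^([A-Z]):\s*$")
_ROW_RE = re.compile(r"^\s+(\d+):((?:\s+-?[\d.]+)*)\s*$")
_SCALAR_RE = re.compile(r"^([A-Z]):\s+(-?[\d.]+)\s*$")


def read_medpc_file(
    path: str | Path,
    array: str | None = None,
    tick: float = TICK_RESOLUTION,
    session_duration: float = 900.0,
    session_day: int = 0,
    concentration: float = float("nan"),
) -> list[LickTrain]:
    """Parse a MED-PC text data file into lick trains.

    One train per session block; multi-session files concatenated by the
    acquisition software are split on repeated ``Start Date:`` headers.

    Parameters
    ----------
    array : str, optional
        Letter of the array holding lick times.  MED-PC configurations differ
        in which array logs licks, so this is configurable; default is the
        first array in the file.
    tick : float
        Seconds per array unit (default 0.01 s/tick).
    """
    text = Path(path).read_text(encoding="utf-8")
    blocks: list[dict] = []
    current: dict | None = None
    current_array: str | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("Start Date:"):
            current = {"headers": {}, "arrays": {}, "order": []}
            blocks.append(current)
            current_array = None
        if current is None:
            raise ParseError(f"content before first 'Start Date:' header", lineno)

        m = _ARRAY_RE.match(line)
        if m:
            current_array = m.group(1)
            current["arrays"][current_array] = []
            current["order"].append(current_array)
            continue
        m = _ROW_RE.match(line)
        if m and current_array is not None:
            values = m.group(2).split()
            try:
                current["arrays"][current_array].extend(float(v) for v in values)
            except ValueError:
                raise ParseError(f"non-numeric array element in {line!r}", lineno)
            continue
        m = _SCALAR_RE.match(line)
        if m:  # single-value variable, e.g. "T: 900.000"
            current["arrays"][m.group(1)] = [float(m.group(2))]
            current["order"].append(m.group(1))
            current_array = None
            continue
        if ":" in line:
            key, _, value = line.partition(":")
            if key.strip() in _HEADER_KEYS:
                current["headers"][key.strip()] = value.strip()
                current_array = None
                continue
            raise ParseError(f"unrecognized header {key.strip()!r}", lineno)
        raise ParseError(f"unparseable line {line!r}", lineno)

    trains: list[LickTrain] = []
    for block in blocks:
        if array is not None:
            if array not in block["arrays"]:
                raise ParseError(f"array {array!r} not present in {path}")
            letter = array
        elif block["order"]:
            letter = block["order"][0]
        else:
            letter = None
        ticks = np.asarray(block["arrays"].get(letter, []), dtype=float)
        ts = np.round(np.sort(ticks) * tick, 2)
        trains.append(
            LickTrain(
                subject_id=block["headers"].get("Subject", "unknown"),
                session_day=session_day,
                concentration=concentration,
                timestamps=tuple(ts),
                session_duration=session_duration,
            )
        )
    return trains


def write_medpc_file(
    trains: Sequence[LickTrain],
    path: str | Path,
    array: str = "A",
    tick: float = TICK_RESOLUTION,
) -> None:
    """Write trains in the MED-PC single-session text layout (5 values/line).

    Mainly for parser round-trip testing and for producing synthetic files in
    the acquisition format.
    """
    lines: list[str] = []
    for t in trains:
        lines += [
            "Start Date: 01/01/70",
            "End Date: 01/01/70",
            f"Subject: {t.subject_id}",
            "Experiment: SUCROSE",
            "Group: NA",
            "Box: 1",
            "Start Time: 00:00:00",
            "End Time: 00:15:00",
            "MSN: LICK",
            f"{array}:",
        ]
        ticks = [ts / tick for ts in t.timestamps]
        for i in range(0, len(ticks), 5):
            chunk = ticks[i:i + 5]
            vals = "".join(f"{v:13.3f}" for v in chunk)
            lines.append(f"{i:6d}:{vals}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# metadata and consumption tables
# ---------------------------------------------------------------------------

def read_metadata_table(path: str | Path) -> list[SubjectRecord]:
    """Read subject metadata (subject, cage, handling, weight, testing group).

    Validates the cage-sharing invariant: both mice of a cage must share the
    handling assignment (handling was randomized at the cage level).  A
    missing weight column yields records with weight absent; weight-adjusted
    analyses will refuse those subjects later.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "cage_id", "handling"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated subject_id {dup!r}")

    has_weight = "body_weight" in df.columns
    has_group = "testing_group" in df.columns
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                cage_id=str(row["cage_id"]),
                handling=str(row["handling"]),
                body_weight=float(row["body_weight"]) if has_weight and pd.notna(row["body_weight"]) else None,
                testing_group=int(row["testing_group"]) if has_group and pd.notna(row["testing_group"]) else None,
            )
        )
    by_cage: dict[str, set[str]] = {}
    for r in records:
        by_cage.setdefault(r.cage_id, set()).add(r.handling)
    for cage, levels in by_cage.items():
        if len(levels) > 1:
            raise ValidationError(
                f"{path}: cage {cage!r} mixes handling labels {sorted(levels)}"
            )
    return records


def write_metadata_table(records: Iterable[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "cage_id": r.cage_id,
                "handling": r.handling,
                "body_weight": r.body_weight,
                "testing_group": r.testing_group,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_consumption_table(path: str | Path) -> list[ConsumptionRecord]:
    """Read per-session consumed masses; (subject, day) must be unique."""
    df = pd.read_csv(path)
    for col in ("subject_id", "session_day", "concentration", "mass_consumed"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.duplicated(subset=["subject_id", "session_day"]).any():
        raise ValidationError(f"{path}: duplicate (subject, day) consumption rows")
    return [
        ConsumptionRecord(
            subject_id=str(r.subject_id),
            session_day=int(r.session_day),
            concentration=float(r.concentration),
            mass_consumed=float(r.mass_consumed),
        )
        for r in df.itertuples()
    ]


def write_consumption_table(records: Iterable[ConsumptionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "session_day": r.session_day,
                "concentration": r.concentration,
                "mass_consumed": r.mass_consumed,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
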