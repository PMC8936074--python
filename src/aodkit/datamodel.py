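"""Domain types and CSV/JSON readers-writers.

A :class:`Measurement` is one steady-state (or near-steady-state) O2-uptake
observation with its protocol context; a :class:`Subject` bundles measurements
with body mass and maximal O2 uptake; a :class:`Cohort` is the unit every
analysis consumes.  Subjects missing data required by a given analysis are
excluded subject-wise from that analysis, never imputed.

CSV dialect: UTF-8, comma-separated, one measurement per row, header columns
exactly the Measurement fields (``subject_id,protocol,frequency,power,
window_start,window_end,vo2,hr,lactate``); missing optional values are empty
strings.  Lines starting with ``#`` are metadata comments and are skipped.
Subject-level attributes (sex, body mass, VO2max) travel in a companion
``cohort.json``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import FormatError, RowValidationError

#: Recognised exercise protocols.
#: bout10    -- 10-min constant-power bout (windows at 3-4 and 8-10 min)
#: bout4_rest -- 4-min bout preceded by rest
#: step4     -- 4-min stepwise increasing power, no rest between steps
#: loadless  -- pedaling against zero braking force
#: rest      -- seated rest on the ergometer
PROTOCOLS = ("bout10", "bout4_rest", "step4", "loadless", "rest")

MEASUREMENT_COLUMNS = (
    "subject_id", "protocol", "frequency", "power",
    "window_start", "window_end", "vo2", "hr", "lactate",
)

#: Default sanity bound: no single VO2 may exceed this multiple of the
#: subject's VO2max (measurement noise can push values slightly past 1).
VO2MAX_SANITY_FACTOR = 1.15


@dataclass
class Measurement:
    """One O2-uptake observation with protocol/power/frequency/window context.

    Units: frequency Hz, power W, window times s within the bout,
    vo2 mmol s^-1, hr beats min^-1, lactate mmol L^-1.
    """

    subject_id: str
    protocol: str
    frequency: float
    power: float
    window_start: float
    window_end: float
    vo2: float
    hr: Optional[float] = None
    lactate: Optional[float] = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.vo2 < 0:
            raise ValueError(f"vo2 must be >= 0, got {self.vo2}")
        if self.power < 0:
            raise ValueError(f"power must be >= 0, got {self.power}")
        if self.protocol in ("loadless", "rest") and self.power != 0:
            raise ValueError(f"{self.protocol} requires power 0, got {self.power}")
        if not (self.window_end > self.window_start >= 0):
            raise ValueError(
                f"need window_end > window_start >= 0, got "
                f"({self.window_start}, {self.window_end})")
        if self.protocol == "rest":
            if self.frequency not in (0, 0.0):
                raise ValueError("rest requires frequency 0")
        elif not (0 < self.frequency <= 3.0):
            raise ValueError(f"frequency must be in (0, 3] Hz, got {self.frequency}")

    @property
    def is_late_window(self) -> bool:
        """True for the 8-10-min (steady-state) window, False for 3-4 min."""
        return self.window_start >= 450.0


@dataclass
class Subject:
    """A study participant: anthropometrics plus all their measurements."""

    subject_id: str
    sex: Optional[str] = None
    body_mass: Optional[float] = None          # kg
    vo2max: Optional[float] = None             # mmol s^-1
    measurements: list = field(default_factory=list)

    def __post_init__(self):
        if self.body_mass is not None and not self.body_mass > 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if self.vo2max is not None and not self.vo2max > 0:
            raise ValueError(f"vo2max must be > 0, got {self.vo2max}")

    def check_vo2_sanity(self, factor: float = VO2MAX_SANITY_FACTOR) -> list:
        """Return measurements whose VO2 exceeds ``factor * vo2max``."""
        if self.vo2max is None:
            return []
        return [m for m in self.measurements if m.vo2 > factor * self.vo2max]

    def select(self, protocol=None, frequency=None, late_window=None) -> list:
        """Filter measurements by protocol (str or set), frequency, window."""
        out = []
        for m in self.measurements:
            if protocol is not None:
                wanted = (protocol,) if isinstance(protocol, str) else tuple(protocol)
                if m.protocol not in wanted:
                    continue
            if frequency is not None and not math.isclose(m.frequency, frequency):
                continue
            if late_window is not None and m.is_late_window != late_window:
                continue
            out.append(m)
        return out


@dataclass
class Cohort:
    """Collection of subjects; derived means are arithmetic over members."""

    subjects: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)

    def get(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def mean_body_mass(self) -> float:
        masses = [s.body_mass for s in self.subjects if s.body_mass is not None]
        if not masses:
            raise ValueError("no subject has a body mass")
        return sum(masses) / len(masses)

    @property
    def mean_vo2max(self) -> float:
        v = [s.vo2max for s in self.subjects if s.vo2max is not None]
        if not v:
            raise ValueError("no subject has a VO2max")
        return sum(v) / len(v)


def cohort_mean_mass(cohort: Cohort) -> float:
    """Arithmetic mean body mass of the cohort, kg."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return cohort.mean_body_mass


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_measurements(path, cohort_json=None, strict: bool = False) -> Cohort:
    """Read a measurements CSV (and optional cohort.json) into a Cohort.

    Rows violating field invariants are rejected with row-addressed
    diagnostics: warnings by default, :class:`RowValidationError` if
    ``strict=True``.  Row numbers refer to data rows (1-based, header and
    comment lines excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: no data section; returning empty cohort")
        return Cohort([])
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df.columns) != len(set(df.columns)):
        raise FormatError(f"{path}: duplicate columns")
    if df.empty:
        warnings.warn(f"{path}: no data rows; returning empty cohort")
        return Cohort([])

    meta = {}
    if cohort_json is not None:
        with open(cohort_json) as fh:
            payload = json.load(fh)
        for rec in payload.get("subjects", []):
            meta[str(rec["subject_id"])] = rec

    subjects: dict[str, Subject] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            for col in ("vo2", "power"):
                val = getattr(row, col)
                if pd.isna(val):
                    raise RowValidationError(i, col, "missing value")
            m = Measurement(
                subject_id=str(row.subject_id),
                protocol=str(row.protocol),
                frequency=float(row.frequency) if not pd.isna(row.frequency) else 0.0,
                power=float(row.power),
                window_start=float(row.window_start),
                window_end=float(row.window_end),
                vo2=float(row.vo2),
                hr=_opt(row.hr),
                lactate=_opt(row.lactate),
            )
        except RowValidationError as err:
            if strict:
                raise
            warnings.warn(str(err))
            continue
        except (ValueError, TypeError) as exc:
            err = RowValidationError(i, _guess_field(str(exc)), str(exc))
            if strict:
                raise err from exc
            warnings.warn(str(err))
            continue
        sid = m.subject_id
        if sid not in subjects:
            rec = meta.get(sid, {})
            subjects[sid] = Subject(
                subject_id=sid,
                sex=rec.get("sex"),
                body_mass=rec.get("body_mass"),
                vo2max=rec.get("vo2max"),
            )
        subjects[sid].measurements.append(m)

    cohort = Cohort(list(subjects.values()))
    for s in cohort:
        bad = s.check_vo2_sanity()
        if bad:
            warnings.warn(
                f"subject {s.subject_id}: {len(bad)} measurement(s) exceed "
                f"{VO2MAX_SANITY_FACTOR} x VO2max")
    return cohort


def _guess_field(msg: str) -> str:
    for col in MEASUREMENT_COLUMNS:
        if col in msg:
            return col
    return "?"


def measurements_frame(cohort: Cohort) -> pd.DataFrame:
    """All measurements of a cohort as a tidy DataFrame (dialect columns)."""
    rows = []
    for s in cohort:
        for m in s.measurements:
            rows.append({
                "subject_id": m.subject_id, "protocol": m.protocol,
                "frequency": m.frequency, "power": m.power,
                "window_start": m.window_start, "window_end": m.window_end,
                "vo2": m.vo2,
                "hr": "" if m.hr is None else m.hr,
                "lactate": "" if m.lactate is None else m.lactate,
            })
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_measurements(cohort: Cohort, path, header_comment: str | None = None) -> None:
    """Write the cohort's measurements in the documented CSV dialect."""
    df = measurements_frame(cohort)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_cohort_json(cohort: Cohort, path) -> None:
    """Write subject-level attributes plus derived cohort means to JSON."""
    payload = {
        "subjects": [
            {"subject_id": s.subject_id, "sex": s.sex,
             "body_mass": s.body_mass, "vo2max": s.vo2max,
             "n_measurements": len(s.measurements)}
            for s in cohort
        ],
    }
    try:
        payload["mean_body_mass"] = cohort.mean_body_mass
        payload["mean_vo2max"] = cohort.mean_vo2max
    except ValueError:
        pass
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
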