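"""Domain types and delimited-text I/O for foot-level injury datasets.

One observational unit is a single foot: the sit-to-stand navicular drop
(SSNDT, mm) is foot-specific, while training load and experience are
participant attributes shared by both feet.  Feet are clustered within
participants, which every downstream model accounts for with a
participant-level random intercept.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "FootSide",
    "FootRecord",
    "Dataset",
    "ValidationReport",
    "read_dataset",
    "write_table",
    "DEFAULT_PLAUSIBILITY_MM",
]

#: Plausibility window for SSNDT values (mm).  Values outside are rejected
#: with a reason, never silently dropped.
DEFAULT_PLAUSIBILITY_MM = (0.0, 25.0)

_COLUMNS = [
    "participant_id",
    "foot_side",
    "ssndt_mm",
    "injured",
    "load_h_per_week",
    "experience_years",
    "cohort_year",
]


class FootSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class FootRecord:
    """A single foot with its exposure, covariates, cluster id and outcome."""

    participant_id: str
    foot_side: FootSide
    ssndt_mm: float
    injured: int
    load_h_per_week: float
    experience_years: float
    cohort_year: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.foot_side, FootSide):
            object.__setattr__(self, "foot_side", FootSide(self.foot_side))
        if self.injured not in (0, 1):
            raise ValidationError(
                f"injured must be 0 or 1, got {self.injured!r}"
            )
        if not np.isfinite(self.ssndt_mm):
            raise ValidationError("ssndt_mm must be finite")


@dataclass(frozen=True)
class RejectedRow:
    index: int
    reason: str


@dataclass
class ValidationReport:
    """What was rejected during ingestion, and why."""

    rejected: list[RejectedRow] = field(default_factory=list)
    n_missing_covariates: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def add(self, index: int, reason: str) -> None:
        self.rejected.append(RejectedRow(index, reason))

    def summary(self) -> str:
        lines = [f"{self.n_rejected} row(s) rejected"]
        if self.n_missing_covariates:
            lines.append(
                f"{self.n_missing_covariates} row(s) dropped for missing "
                "load/experience covariates (listwise deletion)"
            )
        lines += [f"  row {r.index}: {r.reason}" for r in self.rejected]
        return "\n".join(lines)


class Dataset:
    """An ordered, validated collection of :class:`FootRecord`.

    Invariants: (participant_id, foot_side) unique; each participant
    contributes at most two feet.
    """

    def __init__(
        self,
        records: Iterable[FootRecord],
        validation: ValidationReport | None = None,
    ) -> None:
        self.records: list[FootRecord] = list(records)
        self.validation = validation or ValidationReport()
        self._check()

    def _check(self) -> None:
        seen: set[tuple[str, FootSide]] = set()
        per_participant: dict[str, int] = {}
        for rec in self.records:
            key = (rec.participant_id, rec.foot_side)
            if key in seen:
                raise ValidationError(
                    f"duplicate (participant, side): {key[0]!r}/{key[1].value}"
                )
            seen.add(key)
            per_participant[rec.participant_id] = (
                per_participant.get(rec.participant_id, 0) + 1
            )
        for pid, count in per_participant.items():
            if count > 2:
                raise ValidationError(
                    f"participant {pid!r} contributes {count} feet (max 2)"
                )

    @property
    def n_feet(self) -> int:
        return len(self.records)

    @property
    def n_participants(self) -> int:
        return len({r.participant_id for r in self.records})

    @property
    def n_injured(self) -> int:
        return sum(r.injured for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "foot_side": [r.foot_side.value for r in self.records],
                "ssndt_mm": [r.ssndt_mm for r in self.records],
                "injured": [r.injured for r in self.records],
                "load_h_per_week": [r.load_h_per_week for r in self.records],
                "experience_years": [r.experience_years for r in self.records],
                "cohort_year": [r.cohort_year for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        records = [
            FootRecord(
                participant_id=str(row.participant_id),
                foot_side=FootSide(row.foot_side),
                ssndt_mm=float(row.ssndt_mm),
                injured=int(row.injured),
                load_h_per_week=float(row.load_h_per_week),
                experience_years=float(row.experience_years),
                cohort_year=(
                    int(row.cohort_year)
                    if row.cohort_year is not None
                    and not pd.isna(row.cohort_year)
                    else None
                ),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    def subset_participants(self, participant_ids: Sequence[str]) -> "Dataset":
        """Participant-level resample: each occurrence of an id becomes a
        fresh cluster (both feet enter together, duplicates get new ids)."""
        by_pid: dict[str, list[FootRecord]] = {}
        for r in self.records:
            by_pid.setdefault(r.participant_id, []).append(r)
        out: list[FootRecord] = []
        for k, pid in enumerate(participant_ids):
            for r in by_pid[pid]:
                out.append(
                    FootRecord(
                        participant_id=f"{pid}#{k}",
                        foot_side=r.foot_side,
                        ssndt_mm=r.ssndt_mm,
                        injured=r.injured,
                        load_h_per_week=r.load_h_per_week,
                        experience_years=r.experience_years,
                        cohort_year=r.cohort_year,
                    )
                )
        return Dataset(out)

    def __len__(self) -> int:
        return self.n_feet

    def __repr__(self) -> str:
        return (
            f"Dataset(n_feet={self.n_feet}, "
            f"n_participants={self.n_participants}, "
            f"n_injured={self.n_injured})"
        )


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_dataset(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
    outcome_map: Mapping[str, int] | None = None,
    plausibility_mm: tuple[float, float] = DEFAULT_PLAUSIBILITY_MM,
    delimiter: str | None = None,
) -> Dataset:
    """Read a foot-level CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        Delimited text file, dot-decimal only.  The delimiter is sniffed
        unless given explicitly.
    schema_map
        Mapping from canonical column names (``participant_id``,
        ``foot_side``, ``ssndt_mm``, ``injured``, ``load_h_per_week``,
        ``experience_years``, ``cohort_year``) to the file's column names.
    outcome_map
        Optional explicit mapping of raw outcome codes to 0/1 (for
        "yes"/"no"-coded files).  Without it, only 0/1 are accepted.
    plausibility_mm
        Inclusive window of acceptable SSNDT values; out-of-window rows are
        rejected and reported.

    Rows with missing load or experience are dropped (listwise deletion,
    counted in the validation report) because all adjusted models require
    both covariates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"empty file: {path}")
    delim = delimiter or _sniff_delimiter(text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str)
    mapping = {k: (schema_map or {}).get(k, k) for k in _COLUMNS}
    required = [c for c in _COLUMNS if c != "cohort_year"]
    missing = [mapping[c] for c in required if mapping[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    report = ValidationReport()
    lo, hi = plausibility_mm
    records: list[FootRecord] = []
    has_year = mapping["cohort_year"] in df.columns
    for idx, row in df.iterrows():
        raw_ssndt = str(row[mapping["ssndt_mm"]]).strip()
        if "," in raw_ssndt:
            raise SchemaError(
                f"row {idx}: comma-decimal value {raw_ssndt!r}; this reader "
                "accepts dot-decimal CSV only"
            )
        try:
            ssndt = float(raw_ssndt)
        except ValueError:
            report.add(int(idx), f"unparseable ssndt {raw_ssndt!r}")
            continue
        raw_y = str(row[mapping["injured"]]).strip()
        if outcome_map is not None and raw_y in outcome_map:
            y = outcome_map[raw_y]
        else:
            try:
                y = int(float(raw_y))
            except ValueError:
                raise ValidationError(
                    f"row {idx}: non-binary outcome {raw_y!r} and no "
                    "outcome_map entry"
                )
        if y not in (0, 1):
            raise ValidationError(f"row {idx}: outcome {y!r} not in {{0,1}}")
        if not np.isfinite(ssndt) or not (lo <= ssndt <= hi):
            report.add(
                int(idx),
                f"ssndt {ssndt} outside plausibility window [{lo}, {hi}]",
            )
            continue
        covs = {}
        ok = True
        for name in ("load_h_per_week", "experience_years"):
            raw = row[mapping[name]]
            if pd.isna(raw) or str(raw).strip() == "":
                ok = False
                break
            covs[name] = float(str(raw).strip())
        if not ok:
            report.n_missing_covariates += 1
            report.add(int(idx), "missing load/experience covariate")
            continue
        side_raw = str(row[mapping["foot_side"]]).strip().lower()
        try:
            side = FootSide(side_raw)
        except ValueError:
            report.add(int(idx), f"unknown foot side {side_raw!r}")
            continue
        year = None
        if has_year and not pd.isna(row[mapping["cohort_year"]]):
            year = int(float(row[mapping["cohort_year"]]))
        records.append(
            FootRecord(
                participant_id=str(row[mapping["participant_id"]]),
                foot_side=side,
                ssndt_mm=ssndt,
                injured=y,
                load_h_per_week=covs["load_h_per_week"],
                experience_years=covs["experience_years"],
                cohort_year=year,
            )
        )
    return Dataset(records, validation=report)


def write_table(rows, path: str | Path) -> None:
    """Write a result table to CSV so that re-reading reproduces it.

    Accepts a DataFrame, a :class:`Dataset`, or any object exposing
    ``to_frame()``.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif hasattr(rows, "to_frame"):
        df = rows.to_frame()
    else:
        raise TypeError(f"cannot tabulate {type(rows).__name__}")
    df.to_csv(path, index=False)
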