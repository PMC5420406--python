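"""Data model and CSV round-trip for per-animal behavioral cohorts.

A cohort is an ordered collection of :class:`BehavioralRecord`, one per
animal, carrying the two behavioral readouts this package operates on:

* ``spt_rate`` — sucrose preference rate from the sucrose preference test,
  the proportion (in [0, 1]) of sucrose solution consumed out of total
  fluid intake; low values indicate anhedonia-like behavior.
* ``fst_immobility_s`` — immobility time in seconds from the forced
  swimming test; high values indicate despair-like behavior.

Optional fields record the treatment arm and post-treatment readouts for
recovery analysis.  CSV interchange is comma-separated UTF-8 with a
mandatory header and '.' decimal separator; missing optional values are
empty cells, never sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "GROUPS",
    "ARMS",
    "COLUMNS",
    "BehavioralRecord",
    "CohortTable",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

#: Stress-model group labels: unstressed controls, maternal deprivation,
#: chronic unpredictable stress, and the combination.
GROUPS = ("NOR", "MD", "CUS", "MD+CUS")

#: Treatment arms.  ``none`` means the animal was never randomized.
ARMS = ("escitalopram", "saline", "none")

#: Canonical CSV column order.
COLUMNS = (
    "animal_id",
    "group",
    "spt_rate",
    "fst_immobility_s",
    "arm",
    "post_spt_rate",
    "post_fst_immobility_s",
)

INDEX_NAMES = ("spt_rate", "fst_immobility_s")


class CohortSchemaError(ValueError):
    """A required column is missing or an unknown field was requested."""


class CohortValidationError(ValueError):
    """One or more rows violate field invariants.

    ``rows`` carries the offending (1-based data) row numbers with
    human-readable messages.
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems)
        super().__init__(f"cohort validation failed: {lines}")


def _check_proportion(name: str, value: float) -> Optional[str]:
    if not math.isfinite(value):
        return f"{name} is not finite ({value!r})"
    if not 0.0 <= value <= 1.0:
        return f"{name}={value!r} outside [0, 1]"
    return None


def _check_nonneg(name: str, value: float) -> Optional[str]:
    if not math.isfinite(value):
        return f"{name} is not finite ({value!r})"
    if value < 0.0:
        return f"{name}={value!r} is negative"
    return None


@dataclass
class BehavioralRecord:
    """One animal's group membership, readouts and treatment information."""

    animal_id: str
    group: str
    spt_rate: float
    fst_immobility_s: float
    arm: Optional[str] = None
    post_spt_rate: Optional[float] = None
    post_fst_immobility_s: Optional[float] = None

    def problems(self) -> list[str]:
        """Return all invariant violations for this record (empty if valid)."""
        out: list[str] = []
        if not self.animal_id:
            out.append("empty animal_id")
        if self.group not in GROUPS:
            out.append(f"unknown group {self.group!r}")
        for msg in (
            _check_proportion("spt_rate", self.spt_rate),
            _check_nonneg("fst_immobility_s", self.fst_immobility_s),
        ):
            if msg:
                out.append(msg)
        if self.arm is not None and self.arm not in ARMS:
            out.append(f"unknown arm {self.arm!r}")
        if self.post_spt_rate is not None:
            msg = _check_proportion("post_spt_rate", self.post_spt_rate)
            if msg:
                out.append(msg)
        if self.post_fst_immobility_s is not None:
            msg = _check_nonneg("post_fst_immobility_s", self.post_fst_immobility_s)
            if msg:
                out.append(msg)
        return out


@dataclass
class CohortTable:
    """Ordered collection of records plus free-form provenance metadata."""

    records: list[BehavioralRecord]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BehavioralRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> BehavioralRecord:
        return self.records[i]

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` listing every invalid row."""
        problems: list[tuple[int, str]] = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records, start=1):
            for msg in rec.problems():
                problems.append((i, msg))
            if rec.animal_id in seen:
                problems.append((i, f"duplicate animal_id {rec.animal_id!r}"))
            seen.add(rec.animal_id)
        if problems:
            raise CohortValidationError(problems)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.group] = counts.get(rec.group, 0) + 1
        return counts

    def values(self, index: str) -> list[float]:
        """Readout column as a list; ``index`` is one of ``INDEX_NAMES``."""
        if index not in INDEX_NAMES:
            raise CohortSchemaError(f"unknown index {index!r}")
        return [getattr(rec, index) for rec in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "group": rec.group,
                    "spt_rate": rec.spt_rate,
                    "fst_immobility_s": rec.fst_immobility_s,
                    "arm": rec.arm,
                    "post_spt_rate": rec.post_spt_rate,
                    "post_fst_immobility_s": rec.post_fst_immobility_s,
                }
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))

    def with_records(self, records: Iterable[BehavioralRecord]) -> "CohortTable":
        return CohortTable(records=list(records), meta=dict(self.meta))

    def copy(self) -> "CohortTable":
        return CohortTable(
            records=[replace(r) for r in self.records], meta=dict(self.meta)
        )


def _parse_optional_float(raw: object) -> Optional[float]:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    s = str(raw).strip()
    if not s:
        return None
    return float(s)


def read_cohort(
    path,
    *,
    spt_as_percentage: bool = False,
    validate: bool = True,
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file with the columns in :data:`COLUMNS` (optional columns may
        be absent entirely).
    spt_as_percentage
        If True, sucrose preference enters as a percentage in [0, 100] and
        is stored as a proportion.  Both conventions occur in the
        behavioral literature; the flag makes the choice explicit.
    validate
        Check all field invariants and uniqueness of ``animal_id``.

    Raises
    ------
    CohortSchemaError
        A required column is missing.
    CohortValidationError
        Rows with non-numeric or out-of-range readouts, listed by row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("animal_id", "group", "spt_rate", "fst_immobility_s")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[BehavioralRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            spt = float(row_d["spt_rate"])
            if spt_as_percentage:
                spt /= 100.0
            fst = float(row_d["fst_immobility_s"])
            arm = str(row_d.get("arm", "") or "").strip() or None
            rec = BehavioralRecord(
                animal_id=str(row_d["animal_id"]).strip(),
                group=str(row_d["group"]).strip(),
                spt_rate=spt,
                fst_immobility_s=fst,
                arm=arm,
                post_spt_rate=_parse_optional_float(row_d.get("post_spt_rate")),
                post_fst_immobility_s=_parse_optional_float(
                    row_d.get("post_fst_immobility_s")
                ),
            )
            if rec.post_spt_rate is not None and spt_as_percentage:
                rec.post_spt_rate /= 100.0
        except (TypeError, ValueError) as exc:
            problems.append((i, f"unparseable row: {exc}"))
            continue
        records.append(rec)

    cohort = CohortTable(records=records, meta={"source": str(path)})
    if validate:
        if problems:
            raise CohortValidationError(problems)
        cohort.validate()
    return cohort


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    # repr round-trips IEEE doubles losslessly
    return repr(float(x))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV that round-trips bit-identically through
    :func:`read_cohort`.  The cohort must be non-empty."""
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for rec in cohort:
            fh.write(
                ",".join(
                    [
                        rec.animal_id,
                        rec.group,
                        _fmt_float(rec.spt_rate),
                        _fmt_float(rec.fst_immobility_s),
                        rec.arm or "",
                        _fmt_float(rec.post_spt_rate),
                        _fmt_float(rec.post_fst_immobility_s),
                    ]
                )
                + "\n"
            )
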