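"""Percentile cutoffs and three-level phenotype classification.

The operational criterion: take a large naive reference cohort, compute
percentile reference limits of each behavioral readout, and call each
stressed animal *affected*, *sub* (subthreshold) or *resilient* per index.

For a low-is-pathological index (sucrose preference) the severe cutoff is
the 5th percentile and the mild cutoff the 10th; for a high-is-pathological
index (immobility time) they are the 95th and 85th.  Values strictly beyond
the severe cutoff are affected, values strictly on the healthy side of the
mild cutoff are resilient, and the closed interval between the cutoffs is
the subthreshold band (a value exactly at a cutoff goes to the less severe
adjacent category, following the strict-inequality wording of the outer
definitions).

After treatment, an animal that was affected or subthreshold on an index
counts as *recovered* on that index iff its post-treatment value is
strictly on the resilient side of the mild cutoff; otherwise it is
*treatment-resilient*.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort_io import CohortTable, CohortSchemaError
from . import defaults

__all__ = [
    "LOW_IS_PATHOLOGICAL",
    "HIGH_IS_PATHOLOGICAL",
    "CATEGORIES",
    "CutoffEntry",
    "CutoffTable",
    "PhenotypeCall",
    "ClassifiedCohort",
    "percentile",
    "build_cutoffs",
    "classify_index",
    "classify_cohort",
    "classify_recovery",
    "reference_cutoffs",
]

logger = logging.getLogger(__name__)

LOW_IS_PATHOLOGICAL = "low_is_pathological"
HIGH_IS_PATHOLOGICAL = "high_is_pathological"
CATEGORIES = ("affected", "sub", "resilient")

#: Default direction map for the two behavioral indices.
DEFAULT_DIRECTIONS = {
    "spt_rate": LOW_IS_PATHOLOGICAL,
    "fst_immobility_s": HIGH_IS_PATHOLOGICAL,
}

#: Default percentile levels: (severe, mild) tail probabilities.
DEFAULT_LEVELS = (0.05, 0.10)


def percentile(values: Sequence[float], level: float, method: str = "weibull") -> float:
    """Sample percentile at probability ``level``.

    The default ``weibull`` method is the (n+1)-based weighted-average
    rule: h = (n+1)*level, interpolating linearly between the floor(h)-th
    and ceil(h)-th order statistics and clamping to the data extremes when
    h falls outside [1, n].  This is the convention of the mainstream
    statistics packages used for reference-limit work.  Any numpy quantile
    method name may be passed for sensitivity analysis.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty sequence")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return float(np.quantile(arr, level, method=method))


@dataclass
class CutoffEntry:
    """Operational cutoffs for one behavioral index."""

    index: str
    direction: str
    severe_cutoff: float
    mild_cutoff: float
    reference_n: int
    percentile_method: str = "weibull"

    def __post_init__(self) -> None:
        if self.direction not in (LOW_IS_PATHOLOGICAL, HIGH_IS_PATHOLOGICAL):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == LOW_IS_PATHOLOGICAL:
            if self.severe_cutoff > self.mild_cutoff:
                raise ValueError(
                    "low-direction cutoffs must satisfy severe <= mild"
                )
        elif self.mild_cutoff > self.severe_cutoff:
            raise ValueError("high-direction cutoffs must satisfy mild <= severe")

    def category_interval(self, category: str) -> tuple[float, float]:
        """Open/closed aside, the numeric interval occupied by ``category``.

        Returned as (low, high) with infinities where unbounded; boundary
        membership follows :func:`classify_index`.
        """
        lo, hi = -np.inf, np.inf
        if self.direction == LOW_IS_PATHOLOGICAL:
            if category == "affected":
                hi = self.severe_cutoff
            elif category == "sub":
                lo, hi = self.severe_cutoff, self.mild_cutoff
            elif category == "resilient":
                lo = self.mild_cutoff
            else:
                raise ValueError(f"unknown category {category!r}")
        else:
            if category == "affected":
                lo = self.severe_cutoff
            elif category == "sub":
                lo, hi = self.mild_cutoff, self.severe_cutoff
            elif category == "resilient":
                hi = self.mild_cutoff
            else:
                raise ValueError(f"unknown category {category!r}")
        return float(lo), float(hi)


@dataclass
class CutoffTable:
    """Per-index cutoff entries with provenance."""

    entries: dict[str, CutoffEntry]

    def __getitem__(self, index: str) -> CutoffEntry:
        try:
            return self.entries[index]
        except KeyError:
            raise CohortSchemaError(f"no cutoffs for index {index!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {name: vars(e) for name, e in self.entries.items()}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "CutoffTable":
        raw = json.loads(text)
        return cls(entries={name: CutoffEntry(**e) for name, e in raw.items()})


def reference_cutoffs() -> CutoffTable:
    """The published operational cutoffs of the n=309 naive reference cohort
    (sucrose preference P5/P10 = 0.28/0.41; immobility P95/P85 =
    187.95/149.40 s)."""
    return CutoffTable(
        entries={
            "spt_rate": CutoffEntry(
                index="spt_rate",
                direction=LOW_IS_PATHOLOGICAL,
                severe_cutoff=defaults.SPT_SEVERE_CUTOFF,
                mild_cutoff=defaults.SPT_MILD_CUTOFF,
                reference_n=defaults.NAIVE_N,
            ),
            "fst_immobility_s": CutoffEntry(
                index="fst_immobility_s",
                direction=HIGH_IS_PATHOLOGICAL,
                severe_cutoff=defaults.FST_SEVERE_CUTOFF,
                mild_cutoff=defaults.FST_MILD_CUTOFF,
                reference_n=defaults.NAIVE_N,
            ),
        }
    )


def build_cutoffs(
    reference: CohortTable,
    directions: Optional[dict[str, str]] = None,
    method: str = "weibull",
    levels: tuple[float, float] = DEFAULT_LEVELS,
) -> CutoffTable:
    """Construct operational cutoffs from a naive reference cohort.

    ``levels`` are the (severe, mild) tail probabilities; a
    low-is-pathological index gets the (P5, P10) pair directly, a
    high-is-pathological index the mirrored (P95, P85).
    """
    if len(reference) == 0:
        raise ValueError("reference cohort is empty")
    if len(reference) < 100:
        warnings.warn(
            f"reference n={len(reference)} < 100: tail percentiles are "
            "unreliable at this size",
            stacklevel=2,
        )
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    severe_level, mild_level = levels
    if not 0 < severe_level < mild_level < 0.5:
        raise ValueError("levels must satisfy 0 < severe < mild < 0.5")

    entries: dict[str, CutoffEntry] = {}
    for index, direction in directions.items():
        values = reference.values(index)  # raises CohortSchemaError if unknown
        if direction == LOW_IS_PATHOLOGICAL:
            severe = percentile(values, severe_level, method)
            mild = percentile(values, mild_level, method)
        elif direction == HIGH_IS_PATHOLOGICAL:
            severe = percentile(values, 1.0 - severe_level, method)
            mild = percentile(values, 1.0 - mild_level, method)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        entries[index] = CutoffEntry(
            index=index,
            direction=direction,
            severe_cutoff=severe,
            mild_cutoff=mild,
            reference_n=len(reference),
            percentile_method=method,
        )
    return CutoffTable(entries=entries)


def classify_index(value: float, entry: CutoffEntry) -> str:
    """Three-level call for one readout value against one cutoff entry.

    Low direction: value < severe -> affected; severe <= value <= mild ->
    sub; value > mild -> resilient.  High direction mirrored.
    """
    if entry.direction == LOW_IS_PATHOLOGICAL:
        if value < entry.severe_cutoff:
            return "affected"
        if value <= entry.mild_cutoff:
            return "sub"
        return "resilient"
    if value > entry.severe_cutoff:
        return "affected"
    if value >= entry.mild_cutoff:
        return "sub"
    return "resilient"


@dataclass
class PhenotypeCall:
    """Per-animal three-level call on each index plus joint resilience."""

    animal_id: str
    group: str
    categories: dict[str, str]
    joint_stress_resilient: bool
    recovery: dict[str, str] = field(default_factory=dict)


@dataclass
class ClassifiedCohort:
    """Calls for every classifiable animal plus an exclusion report."""

    calls: list[PhenotypeCall]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def category_counts(self, index: str) -> dict[str, dict[str, int]]:
        """group -> {category -> count} for one index."""
        out: dict[str, dict[str, int]] = {}
        for call in self.calls:
            g = out.setdefault(call.group, {c: 0 for c in CATEGORIES})
            g[call.categories[index]] += 1
        return out


def classify_cohort(cohort: CohortTable, cutoffs: CutoffTable) -> ClassifiedCohort:
    """Call every animal on every index in the cutoff table.

    Animals missing a readout are excluded with a logged warning and listed
    in the exclusion report; the joint stress-resilient flag is the AND of
    per-index resilience.
    """
    calls: list[PhenotypeCall] = []
    excluded: list[tuple[str, str]] = []
    for rec in cohort:
        cats: dict[str, str] = {}
        missing = None
        for index in cutoffs.entries:
            value = getattr(rec, index, None)
            if value is None or not np.isfinite(value):
                missing = index
                break
            cats[index] = classify_index(float(value), cutoffs[index])
        if missing is not None:
            logger.warning(
                "animal %s excluded: missing readout %s", rec.animal_id, missing
            )
            excluded.append((rec.animal_id, f"missing {missing}"))
            continue
        calls.append(
            PhenotypeCall(
                animal_id=rec.animal_id,
                group=rec.group,
                categories=cats,
                joint_stress_resilient=all(c == "resilient" for c in cats.values()),
            )
        )
    return ClassifiedCohort(calls=calls, excluded=excluded)


def classify_recovery(
    pre_call: PhenotypeCall,
    post_spt: Optional[float],
    post_fst: Optional[float],
    cutoffs: CutoffTable,
) -> dict[str, str]:
    """Score recovery per index for an animal non-resilient pre-treatment.

    Only indices where the animal was affected or subthreshold are scored;
    recovery requires the post value strictly past the mild cutoff on the
    resilient side (sucrose preference > mild cutoff; immobility < mild
    cutoff).  A scored index without its post readout raises; an animal
    resilient on both indices yields an empty result.
    """
    post_values = {"spt_rate": post_spt, "fst_immobility_s": post_fst}
    out: dict[str, str] = {}
    for index, category in pre_call.categories.items():
        if category == "resilient":
            continue
        value = post_values.get(index)
        if value is None:
            raise ValueError(
                f"animal {pre_call.animal_id}: post-treatment {index} required "
                f"to score recovery"
            )
        out[index] = (
            "recovered"
            if classify_index(float(value), cutoffs[index]) == "resilient"
            else "treatment_resilient"
        )
    return out
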