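"""Seeded generators emulating the naive and stressed rat cohorts.

Raw per-animal data for the study design this package models were never
deposited, so every downstream stage is exercised on synthetic cohorts
whose *summary structure* matches the published one:

* a naive reference population whose sucrose preference is Beta(2.53,
  1.08) and whose immobility time is Gamma(shape 2.29, rate 0.0264);
* a four-class latent profile of the same population (class weights
  44/100/153/12 out of 309, bivariate diagonal Gaussians);
* stressed groups in which each animal draws a phenotype category per
  index from the published incidence and then a readout from a normal
  law with the published category-conditional moments, truncated to the
  category's cutoff interval (so re-classification reproduces the
  sampled category exactly);
* treatment response in which each treated animal recovers with its
  category's published recovery probability.

Generation is purely distributional — no mechanistic stress modelling —
and deterministic given (parameters, seed).  The two indices are drawn
independently within category; the joint "stress-resilience" rate is an
emergent quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from . import defaults
from .classifier import (
    CATEGORIES,
    CutoffTable,
    PhenotypeCall,
    classify_index,
    reference_cutoffs,
)
from .cohort_io import CohortTable, BehavioralRecord

__all__ = [
    "MixtureSpec",
    "CategoryModel",
    "StressScenario",
    "simulate_naive_marginal",
    "simulate_naive_mixture",
    "simulate_stressed_cohort",
    "simulate_treatment_response",
    "naive_mixture_spec",
    "stress_scenario",
    "all_stress_scenarios",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

#: Rejection-sampling redraw cap for truncated draws.
REDRAW_CAP = 10**6

_INDEX_SUPPORT = {"spt_rate": (0.0, 1.0), "fst_immobility_s": (0.0, np.inf)}


@dataclass
class MixtureSpec:
    """K-class bivariate Gaussian mixture (diagonal covariance) on
    (sucrose preference, immobility)."""

    weights: Sequence[float]
    means: Sequence[tuple[float, float]]  # K pairs (spt, fst)
    variances: Sequence[float] | Sequence[tuple[float, float]]
    # (spt_var, fst_var) shared across classes, or K pairs when class-varying

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if w.ndim != 1 or m.shape != (w.size, 2):
            raise ValueError("means must be K pairs matching K weights")
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any():
            raise ValueError("weights must be non-negative and sum to 1")
        if v.shape not in ((2,), (w.size, 2)):
            raise ValueError("variances must be a pair or K pairs")
        if (v <= 0).any():
            raise ValueError("variances must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    def class_variances(self) -> np.ndarray:
        """Variances broadcast to shape (K, 2)."""
        v = np.asarray(self.variances, dtype=float)
        if v.shape == (2,):
            return np.broadcast_to(v, (self.K, 2)).copy()
        return v


@dataclass
class CategoryModel:
    """One phenotype category of one index within a stressed group."""

    prob: float
    mean: float
    sd: float
    recovery_prob: float = 0.0


@dataclass
class StressScenario:
    """Generative description of one stressed group.

    ``anhedonia`` and ``despair`` map category name -> CategoryModel for
    the sucrose-preference and immobility index respectively.  Category
    probabilities must each sum to 1 and every conditional mean must lie
    inside its category's cutoff interval (checked at construction).
    """

    group: str
    n: int
    anhedonia: dict[str, CategoryModel]
    despair: dict[str, CategoryModel]
    cutoffs: CutoffTable = field(default_factory=reference_cutoffs)

    def __post_init__(self) -> None:
        for index, models in (("spt_rate", self.anhedonia),
                              ("fst_immobility_s", self.despair)):
            if set(models) != set(CATEGORIES):
                raise ValueError(f"{index}: categories must be exactly {CATEGORIES}")
            total = sum(m.prob for m in models.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{index}: category probabilities sum to {total}")
            entry = self.cutoffs[index]
            for cat, m in models.items():
                if m.sd <= 0:
                    raise ValueError(f"{index}/{cat}: sd must be positive")
                if not 0 <= m.prob <= 1 or not 0 <= m.recovery_prob <= 1:
                    raise ValueError(f"{index}/{cat}: probabilities must be in [0,1]")
                if classify_index(m.mean, entry) != cat:
                    raise ValueError(
                        f"{index}/{cat}: conditional mean {m.mean} lies outside "
                        f"the category's cutoff interval"
                    )

    def models(self, index: str) -> dict[str, CategoryModel]:
        return self.anhedonia if index == "spt_rate" else self.despair


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_naive_marginal(
    n: int,
    beta_params: tuple[float, float] = defaults.NAIVE_BETA_PARAMS,
    gamma_params: tuple[float, float] = defaults.NAIVE_GAMMA_PARAMS,
    seed: Optional[int] = None,
) -> CohortTable:
    """Naive (NOR) cohort with independent Beta / Gamma marginals.

    ``gamma_params`` is (shape, rate); draws use scale = 1/rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = beta_params
    shape, rate = gamma_params
    if min(a, b, shape, rate) <= 0:
        raise ValueError("distribution parameters must be strictly positive")
    rng = _rng(seed)
    spt = rng.beta(a, b, size=n)
    fst = rng.gamma(shape, 1.0 / rate, size=n)
    records = [
        BehavioralRecord(
            animal_id=f"NAIVE{i + 1:04d}", group="NOR",
            spt_rate=float(spt[i]), fst_immobility_s=float(fst[i]),
        )
        for i in range(n)
    ]
    return CohortTable(
        records=records,
        meta={"generator": "naive_marginal", "seed": seed,
              "beta_params": list(beta_params), "gamma_params": list(gamma_params)},
    )


def naive_mixture_spec() -> MixtureSpec:
    """The published four-class profile of the naive cohort as a
    class-varying-variance mixture spec (weights 44/100/153/12 of 309)."""
    counts = np.asarray(defaults.NAIVE_CLASS_COUNTS, dtype=float)
    means = [
        (defaults.NAIVE_CLASS_SPT[k][0], defaults.NAIVE_CLASS_FST[k][0])
        for k in range(4)
    ]
    variances = [
        (defaults.NAIVE_CLASS_SPT[k][1] ** 2, defaults.NAIVE_CLASS_FST[k][1] ** 2)
        for k in range(4)
    ]
    return MixtureSpec(weights=counts / counts.sum(), means=means, variances=variances)


def simulate_naive_mixture(
    n: int, spec: MixtureSpec, seed: Optional[int] = None
) -> tuple[CohortTable, np.ndarray]:
    """Draw a naive cohort from a Gaussian mixture; returns true labels too.

    Class labels are drawn from the weights, then each readout from the
    class's Gaussian; sucrose preference is truncated to [0, 1] and
    immobility to [0, inf) by redraw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    labels = rng.choice(spec.K, size=n, p=np.asarray(spec.weights, dtype=float))
    variances = spec.class_variances()
    means = np.asarray(spec.means, dtype=float)
    records = []
    for i in range(n):
        k = labels[i]
        spt = _truncated_normal_draw(
            rng, means[k, 0], float(np.sqrt(variances[k, 0])), 0.0, 1.0
        )
        fst = _truncated_normal_draw(
            rng, means[k, 1], float(np.sqrt(variances[k, 1])), 0.0, np.inf
        )
        records.append(
            BehavioralRecord(
                animal_id=f"NAIVE{i + 1:04d}", group="NOR",
                spt_rate=spt, fst_immobility_s=fst,
            )
        )
    cohort = CohortTable(
        records=records, meta={"generator": "naive_mixture", "seed": seed}
    )
    return cohort, labels


def _truncated_normal_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    accept=None,
) -> float:
    """One truncated-normal draw by rejection with an explicit cap.

    ``accept`` optionally adds a predicate beyond the [low, high] support
    bounds (used to respect strict/closed category boundaries exactly).
    """
    for _ in range(REDRAW_CAP):
        x = rng.normal(mean, sd)
        if low <= x <= high and (accept is None or accept(x)):
            return float(x)
    raise RuntimeError(
        f"rejection sampling failed after {REDRAW_CAP} draws "
        f"(mean={mean}, sd={sd}, interval=[{low}, {high}])"
    )


def _draw_category_value(
    rng: np.random.Generator,
    scenario: StressScenario,
    index: str,
    category: str,
) -> float:
    entry = scenario.cutoffs[index]
    model = scenario.models(index)[category]
    lo, hi = entry.category_interval(category)
    support_lo, support_hi = _INDEX_SUPPORT[index]
    lo, hi = max(lo, support_lo), min(hi, support_hi)
    # the accept predicate enforces the exact (strict vs closed) boundary
    return _truncated_normal_draw(
        rng, model.mean, model.sd, lo, hi,
        accept=lambda x: classify_index(x, entry) == category,
    )


def simulate_stressed_cohort(
    scenario: StressScenario, seed: Optional[int] = None
) -> CohortTable:
    """Draw one stressed group.

    For each animal: sample the anhedonia and despair categories
    independently from the scenario's incidence probabilities, then draw
    each readout from a normal law with the category's conditional moments
    truncated to the category's cutoff interval.  By construction,
    re-classifying with the same cutoffs reproduces the sampled categories
    exactly.
    """
    rng = _rng(seed)
    records = []
    probs = {
        index: np.array([scenario.models(index)[c].prob for c in CATEGORIES])
        for index in ("spt_rate", "fst_immobility_s")
    }
    for i in range(scenario.n):
        values = {}
        for index in ("spt_rate", "fst_immobility_s"):
            cat = CATEGORIES[rng.choice(3, p=probs[index])]
            values[index] = _draw_category_value(rng, scenario, index, cat)
        records.append(
            BehavioralRecord(
                animal_id=f"{scenario.group}{i + 1:04d}",
                group=scenario.group,
                spt_rate=values["spt_rate"],
                fst_immobility_s=values["fst_immobility_s"],
            )
        )
    return CohortTable(
        records=records,
        meta={"generator": "stressed_cohort", "group": scenario.group, "seed": seed},
    )


def simulate_treatment_response(
    cohort: CohortTable,
    calls: Sequence[PhenotypeCall],
    scenario: StressScenario,
    seed: Optional[int] = None,
) -> CohortTable:
    """Post-treatment readouts for every non-resilient animal.

    Animals affected or subthreshold on at least one index receive the
    antidepressant arm; on each scored index they recover with the
    category's recovery probability.  A recovered index draws its post
    readout beyond the mild cutoff on the resilient side (from the
    resilient category's conditional law); a non-recovered index redraws
    inside its pre-treatment category interval.  Indices already resilient
    keep a resilient-law draw and are not scored.
    """
    by_id = {c.animal_id: c for c in calls}
    rng = _rng(seed)
    out_records = []
    for rec in cohort:
        call = by_id.get(rec.animal_id)
        if call is None:
            raise ValueError(f"no phenotype call for animal {rec.animal_id}")
        if call.joint_stress_resilient:
            out_records.append(replace(rec, arm="none"))
            continue
        post = {}
        for index in ("spt_rate", "fst_immobility_s"):
            cat = call.categories[index]
            if cat == "resilient":
                post[index] = _draw_category_value(rng, scenario, index, "resilient")
                continue
            recov_p = scenario.models(index)[cat].recovery_prob
            if rng.random() < recov_p:
                post[index] = _draw_category_value(rng, scenario, index, "resilient")
            else:
                post[index] = _draw_category_value(rng, scenario, index, cat)
        out_records.append(
            replace(
                rec,
                arm="escitalopram",
                post_spt_rate=post["spt_rate"],
                post_fst_immobility_s=post["fst_immobility_s"],
            )
        )
    return CohortTable(
        records=out_records,
        meta={**cohort.meta, "generator": "treatment_response", "treatment_seed": seed},
    )


def stress_scenario(
    group: str,
    n: Optional[int] = None,
    cutoffs: Optional[CutoffTable] = None,
) -> StressScenario:
    """Published scenario for one group (NOR, MD, CUS or MD+CUS):
    incidence, conditional moments and recovery probabilities all taken
    from the study's summary tables."""
    if group not in defaults.GROUP_SIZES:
        raise ValueError(f"unknown group {group!r}")
    n = defaults.GROUP_SIZES[group] if n is None else n
    size = defaults.GROUP_SIZES[group]

    def axis(counts, moments, axis_name) -> dict[str, CategoryModel]:
        out = {}
        for j, cat in enumerate(CATEGORIES):
            kind = f"{axis_name}_{cat}" if cat != "resilient" else None
            recov = defaults.recovery_probability(kind, group) if kind else 0.0
            out[cat] = CategoryModel(
                prob=counts[j] / size,
                mean=moments[j][0],
                sd=moments[j][1],
                recovery_prob=recov,
            )
        return out

    return StressScenario(
        group=group,
        n=n,
        anhedonia=axis(
            defaults.ANHEDONIA_COUNTS[group], defaults.ANHEDONIA_MOMENTS[group],
            "anhedonia",
        ),
        despair=axis(
            defaults.DESPAIR_COUNTS[group], defaults.DESPAIR_MOMENTS[group],
            "despair",
        ),
        cutoffs=cutoffs or reference_cutoffs(),
    )


def all_stress_scenarios(cutoffs: Optional[CutoffTable] = None) -> dict[str, StressScenario]:
    return {g: stress_scenario(g, cutoffs=cutoffs) for g in defaults.GROUP_SIZES}


# ---------------------------------------------------------------------------
# YAML round-trip for scenarios
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: StressScenario) -> str:
    def axis(models):
        return {
            cat: {"prob": m.prob, "mean": m.mean, "sd": m.sd,
                  "recovery_prob": m.recovery_prob}
            for cat, m in models.items()
        }

    doc = {
        "group": scenario.group,
        "n": scenario.n,
        "anhedonia": axis(scenario.anhedonia),
        "despair": axis(scenario.despair),
        "cutoffs": {
            name: vars(e) for name, e in scenario.cutoffs.entries.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> StressScenario:
    doc = yaml.safe_load(text)

    def axis(raw):
        return {cat: CategoryModel(**m) for cat, m in raw.items()}

    from .classifier import CutoffEntry

    cutoffs = CutoffTable(
        entries={name: CutoffEntry(**e) for name, e in doc["cutoffs"].items()}
    )
    return StressScenario(
        group=doc["group"], n=int(doc["n"]),
        anhedonia=axis(doc["anhedonia"]), despair=axis(doc["despair"]),
        cutoffs=cutoffs,
    )
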