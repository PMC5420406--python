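"""Incidence tables, chi-square tests and one-way ANOVA for phenotype calls.

Every published incidence comparison in the modelled study is a Pearson
chi-square on a *category-vs-rest* dichotomy: for one phenotype category
(say anhedonia-like), each stress group contributes a (in-category,
not-in-category) pair, giving a groups x 2 table.  This construction —
without continuity correction — reproduces every published statistic from
the published counts, and is therefore the default here.  Expected counts
below 5 trigger a recorded warning, never a silent switch of test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CATEGORIES, ClassifiedCohort

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "incidence_table",
    "recovery_table",
    "chi_square",
    "pairwise_chi_square",
    "anova_from_summary",
    "anova_raw",
    "tukey_posthoc",
]


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    correction: str = "none"
    warnings: list[str] = field(default_factory=list)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_summaries: pd.DataFrame  # columns n, mean, sd


def incidence_table(
    classified: ClassifiedCohort, index: str, category: str
) -> pd.DataFrame:
    """Category-vs-rest count table by group for one index.

    Rows are groups (in first-appearance order), columns the in-category
    and not-in-category counts.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counts = classified.category_counts(index)
    if not counts:
        raise ValueError("no phenotype calls to tabulate")
    rows = {}
    for group, by_cat in counts.items():
        n_in = by_cat[category]
        rows[group] = (n_in, sum(by_cat.values()) - n_in)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[category, "rest"]
    )


def recovery_table(
    classified: ClassifiedCohort, index: str, category: str
) -> pd.DataFrame:
    """Recovered-vs-not count table by group among animals that were in
    ``category`` on ``index`` pre-treatment and carry a recovery call."""
    rows: dict[str, list[int]] = {}
    for call in classified.calls:
        if call.categories.get(index) != category or index not in call.recovery:
            continue
        rec = rows.setdefault(call.group, [0, 0])
        rec[0 if call.recovery[index] == "recovered" else 1] += 1
    if not rows:
        raise ValueError("no recovery-scored animals in this category")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["recovered", "treatment_resilient"]
    )


def _as_count_frame(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("counts must be finite and non-negative")
    return df


def chi_square(table, correction: str = "none") -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction='yates'`` applies the continuity correction (2 x 2 only
    in practice); the default matches the modelled study (none).  A zero
    row/column margin is an error; expected counts below 5 are recorded
    as warnings.
    """
    df_obs = _as_count_frame(table)
    obs = df_obs.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    chi2, p, dof, expected = stats.chi2_contingency(
        obs, correction=(correction == "yates")
    )
    warns = []
    n_small = int((expected < 5).sum())
    if n_small:
        warns.append(
            f"{n_small} cell(s) with expected count < 5; chi-square "
            "approximation may be inaccurate"
        )
    return ContingencyResult(
        observed=df_obs,
        expected=expected,
        chi2=float(chi2),
        df=int(dof),
        p=float(p),
        correction=correction,
        warnings=warns,
    )


def pairwise_chi_square(
    table,
    correction: str = "none",
    adjust: str = "bonferroni",
) -> dict[tuple, ContingencyResult]:
    """All pairwise 2 x 2 (well, 2 x c) chi-square tests between group rows.

    ``adjust`` is the multiple-testing adjustment of the p-values:
    ``bonferroni`` (default) or ``none`` (mirrors the modelled study's
    unadjusted reporting).  Each pair's statistic equals the overall
    routine applied to the 2-row subtable.
    """
    df = _as_count_frame(table)
    if df.shape[0] < 3:
        raise ValueError("pairwise comparison needs at least 3 groups")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairs = list(itertools.combinations(df.index, 2))
    out: dict[tuple, ContingencyResult] = {}
    for g1, g2 in pairs:
        res = chi_square(df.loc[[g1, g2]], correction=correction)
        if adjust == "bonferroni":
            res.p = min(1.0, res.p * len(pairs))
        out[(g1, g2)] = res
    return out


def anova_from_summary(
    ns: Sequence[int],
    means: Sequence[float],
    sds: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    Between-group sum of squares from the group means about the grand
    mean; within-group sum of squares from the (n_g - 1) * sd_g^2 terms.
    Equivalent to :func:`anova_raw` when the summaries come from the raw
    values.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape) or ns.size < 2:
        raise ValueError("need matching n/mean/sd for at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1.0) * sds**2).sum())
    df_b = ns.size - 1
    df_w = int(n_total) - ns.size
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w if ms_w > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w))
    summaries = pd.DataFrame(
        {"n": ns.astype(int), "mean": means, "sd": sds},
        index=list(labels) if labels is not None else range(ns.size),
    )
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p,
                       group_summaries=summaries)


def anova_raw(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw per-group values."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    return anova_from_summary(
        [a.size for a in arrays],
        [a.mean() for a in arrays],
        [a.std(ddof=1) for a in arrays],
        labels=labels,
    )


def tukey_posthoc(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD pairwise mean comparisons with family-wise adjusted p.

    Returns one row per ordered pair with the mean difference, adjusted
    p-value and 95% family-wise confidence interval.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(0.95)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            }
        )
    return pd.DataFrame(rows)
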