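"""Reference values the synthetic cohorts emulate and the fixture tables.

All constants here were transcribed from the published summary tables of a
behavioral-phenotyping study of stress-induced depression in rats (a naive
reference cohort of n = 309 plus four stress-model groups).  Raw per-animal
data were never deposited, so these printed marginals, class profiles,
category-conditional moments, incidences and recovery rates are the
generative targets for :mod:`phenocut.synthetic_cohorts` and the count
fixtures for :mod:`phenocut.contingency_stats`.

Conventions
-----------
* Sucrose preference rate (``spt``) is a proportion in [0, 1];
  immobility time (``fst``) is in seconds.
* The Gamma law is parameterized by (shape, rate).  The published scale
  value 0.03 is a rounded rate: shape 2.29 equals the method-of-moments
  value (mean/SD)^2 of the printed moments, and mean/SD^2 = 0.0264, whose
  product with the shape recovers the printed mean 86.76 s (2.29 x 0.03
  as a scipy-style scale would give ~0.07 s).
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Naive reference population (n = 309): marginal fits and moments
# --------------------------------------------------------------------------

NAIVE_N = 309

#: Beta(shape1, shape2) fitted to the sucrose preference rate.
NAIVE_BETA_PARAMS = (2.53, 1.08)

#: Gamma(shape, rate) fitted to immobility time, rate back-derived from the
#: printed moments (see module docstring).
NAIVE_GAMMA_PARAMS = (2.29, 0.0264)

#: Printed descriptive moments of the naive cohort: (mean, sd).
NAIVE_SPT_MOMENTS = (0.70, 0.21)
NAIVE_FST_MOMENTS = (86.76, 57.28)

# --------------------------------------------------------------------------
# Operational percentile cutoffs from the naive cohort
# --------------------------------------------------------------------------

#: Empirical percentile cutoffs of the naive reference cohort:
#: sucrose preference P5/P10 and immobility P95/P85.
SPT_SEVERE_CUTOFF = 0.28   # 5th percentile; below = anhedonia-like
SPT_MILD_CUTOFF = 0.41     # 10th percentile; (0.28, 0.41] = sub anhedonia-like
FST_SEVERE_CUTOFF = 187.95  # 95th percentile; above = despair-like
FST_MILD_CUTOFF = 149.40    # 85th percentile; [149.40, 187.95] = sub despair-like

# --------------------------------------------------------------------------
# Four-class latent profile of the naive cohort
# --------------------------------------------------------------------------

#: Modal class sizes of the adopted 4-class solution (sum 309).  The
#: published percentage for class 4 (14.24%) duplicates class 1's and is a
#: typo; 12/309 = 3.88% is used.
NAIVE_CLASS_COUNTS = (44, 100, 153, 12)

#: Class-conditional (mean, sd) per class for each indicator.
NAIVE_CLASS_SPT = ((0.39, 0.12), (0.74, 0.18), (0.78, 0.14), (0.54, 0.13))
NAIVE_CLASS_FST = ((52.18, 29.86), (136.67, 26.61), (52.71, 23.51), (227.77, 28.99))

#: Published model-selection table for K = 1..5 classes (AIC, BIC, aBIC,
#: entropy, LMR-adjusted statistic, LMR p).  Used as a fixture for the
#: selection rule; entropy/LMR are None for K = 1.
SELECTION_TABLE_FIXTURE = (
    {"K": 1, "AIC": 3306.220, "BIC": 3321.154, "aBIC": 3308.467,
     "entropy": None, "lmr_stat": None, "lmr_p": None},
    {"K": 2, "AIC": 3279.370, "BIC": 3305.504, "aBIC": 3283.303,
     "entropy": 0.698, "lmr_stat": 31.045, "lmr_p": 0.057},
    {"K": 3, "AIC": 3258.680, "BIC": 3296.013, "aBIC": 3264.297,
     "entropy": 0.733, "lmr_stat": 25.224, "lmr_p": 0.086},
    {"K": 4, "AIC": 3240.962, "BIC": 3289.495, "aBIC": 3248.265,
     "entropy": 0.754, "lmr_stat": 22.414, "lmr_p": 0.019},
    {"K": 5, "AIC": 3225.607, "BIC": 3285.340, "aBIC": 3234.595,
     "entropy": 0.736, "lmr_stat": 20.182, "lmr_p": 0.277},
)

# --------------------------------------------------------------------------
# Stressed cohorts: group sizes, category incidences, conditional moments
# --------------------------------------------------------------------------

GROUP_SIZES = {"NOR": 120, "MD": 111, "CUS": 122, "MD+CUS": 99}

#: Category counts per group (affected, sub, resilient) for the anhedonia
#: axis (sucrose preference) and the despair axis (immobility).
ANHEDONIA_COUNTS = {
    "NOR": (5, 6, 109),
    "MD": (19, 13, 79),
    "CUS": (50, 23, 49),
    "MD+CUS": (75, 7, 17),
}
DESPAIR_COUNTS = {
    "NOR": (4, 14, 102),
    "MD": (15, 14, 82),
    "CUS": (48, 19, 55),
    "MD+CUS": (43, 10, 46),
}

#: Category-conditional (mean, sd) of the readout, per group, in order
#: (affected, sub, resilient).
ANHEDONIA_MOMENTS = {
    "NOR": ((0.18, 0.05), (0.35, 0.05), (0.71, 0.16)),
    "MD": ((0.20, 0.06), (0.34, 0.06), (0.71, 0.17)),
    "CUS": ((0.21, 0.05), (0.35, 0.06), (0.69, 0.18)),
    "MD+CUS": ((0.19, 0.05), (0.31, 0.06), (0.70, 0.16)),
}
DESPAIR_MOMENTS = {
    "NOR": ((245.26, 30.78), (176.68, 31.28), (87.66, 37.94)),
    "MD": ((248.91, 30.51), (172.68, 10.07), (86.99, 39.74)),
    "CUS": ((242.30, 33.55), (173.54, 10.41), (87.51, 39.14)),
    "MD+CUS": ((248.82, 35.30), (176.01, 12.58), (88.58, 36.40)),
}

# --------------------------------------------------------------------------
# Recovery after a 4-week escitalopram course
# --------------------------------------------------------------------------

#: Recovered counts per group per pre-treatment category.  Denominators are
#: those implied by the published percentages (they equal the incidence
#: counts above except NOR sub-despair, where the percentage implies 7).
RECOVERY_COUNTS = {
    "anhedonia_affected": {"NOR": (1, 5), "MD": (4, 19), "CUS": (21, 50), "MD+CUS": (9, 75)},
    "anhedonia_sub": {"NOR": (2, 6), "MD": (4, 13), "CUS": (12, 23), "MD+CUS": (2, 7)},
    "despair_affected": {"NOR": (3, 4), "MD": (11, 15), "CUS": (35, 48), "MD+CUS": (30, 43)},
    "despair_sub": {"NOR": (5, 7), "MD": (11, 14), "CUS": (16, 19), "MD+CUS": (7, 10)},
}


def recovery_probability(kind: str, group: str) -> float:
    """Recovery probability for a (category kind, group) pair."""
    k, n = RECOVERY_COUNTS[kind][group]
    return k / n


# --------------------------------------------------------------------------
# Published chi-square statistics (category-vs-rest 4x2 construction)
# --------------------------------------------------------------------------

#: The ten published Pearson chi-square statistics, keyed by the table they
#: summarize.  Each is reproduced by ``chi_square`` on the corresponding
#: category-vs-rest table built from the counts above.
PUBLISHED_CHI2 = {
    "anhedonia_affected": 143.24,
    "anhedonia_sub": 13.88,
    "anhedonia_resilient": 142.58,
    "despair_affected": 70.34,
    "despair_sub": 1.64,
    "despair_resilient": 59.00,
    "recovery_anhedonia_affected": 15.14,
    "recovery_anhedonia_sub": 2.35,
    "recovery_despair_affected": 0.16,
    "recovery_despair_sub": 0.98,
}
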