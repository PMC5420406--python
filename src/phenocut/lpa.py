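"""Latent profile analysis on the two behavioral indicators.

A latent profile model here is a K-class mixture of bivariate Gaussians
with diagonal covariance on (sucrose preference rate, immobility time),
fitted by EM on the raw indicator scales.  By default the two variances
are shared across classes (class-invariant), giving p = 3K + 1 free
parameters (2K means, 2 variances, K - 1 weights); class-varying
variances (p = 5K - 1) are available behind an option.

Class enumeration uses the usual toolkit: information criteria
(AIC / BIC / sample-size-adjusted BIC, lower is better), standardized
entropy (1 = perfectly crisp assignment), the Lo–Mendell–Rubin adjusted
likelihood-ratio test comparing K - 1 vs K classes, and a parametric
bootstrap LRT.  The LMR adjustment divides 2*ΔlogL by
1 + 1/(d * ln n) with d the parameter-count difference; its p-value is
approximated by a chi-square with d degrees of freedom, a crude reference
for which the bootstrap test is the preferred alternative (mixture LRTs
violate standard regularity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "LPAFit",
    "SelectionTable",
    "ConvergenceError",
    "fit_lpa",
    "information_criteria",
    "entropy",
    "assignment_probability_matrix",
    "lmr_alrt",
    "bootstrap_lrt",
    "selection_rows",
    "select_model",
]

#: Variance floor guarding against degenerate (collapsing) classes.
VARIANCE_FLOOR = 1e-8


class ConvergenceError(RuntimeError):
    """No EM start produced a usable fit; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message + "; starts: " + "; ".join(diagnostics))
        self.diagnostics = diagnostics


@dataclass
class LPAFit:
    """A fitted K-class profile model."""

    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, 2)
    variances: np.ndarray        # (2,) shared or (K, 2) class-varying
    variance_structure: str      # 'shared' | 'varying'
    logL: float
    n_params: int
    n: int
    posteriors: np.ndarray       # (n, K)
    assignments: np.ndarray      # (n,) modal class indices
    converged: bool
    n_restarts_used: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def class_variances(self) -> np.ndarray:
        if self.variances.shape == (2,):
            return np.broadcast_to(self.variances, (self.K, 2)).copy()
        return self.variances

    def information_criteria(self) -> dict[str, float]:
        return information_criteria(self.logL, self.n_params, self.n)


def n_free_parameters(K: int, variance_structure: str) -> int:
    """2K means + (K-1) weights + 2 shared or 2K class-varying variances."""
    if variance_structure == "shared":
        return 3 * K + 1
    if variance_structure == "varying":
        return 5 * K - 1
    raise ValueError(f"unknown variance_structure {variance_structure!r}")


def _log_densities(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log N(x_i | mu_k, diag(sigma_k^2)); variances shape (K, 2)."""
    diff = X[:, None, :] - means[None, :, :]            # (n, K, 2)
    return -0.5 * np.sum(
        np.log(2.0 * np.pi * variances)[None, :, :] + diff**2 / variances[None, :, :],
        axis=2,
    )


def _em_single_start(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    variance_structure: str,
) -> tuple[dict, str]:
    """One EM run from a random-exemplar start.

    K distinct observations are drawn as initial class means with the
    data's column variances and uniform weights; the first E-step turns
    them into responsibilities.  (Random soft-responsibility starts place
    every initial mean near the grand mean and routinely lose small,
    distant classes.)  Returns (result dict, status) where status is
    'converged', 'max_iter' or an abort reason ('empty class').
    """
    n = X.shape[0]
    means0 = X[rng.choice(n, size=K, replace=False)]
    var0 = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    logdens0 = _log_densities(X, means0, np.broadcast_to(var0, (K, 2))) - np.log(K)
    resp = np.exp(logdens0 - logsumexp(logdens0, axis=1)[:, None])
    loglik_path: list[float] = []
    logL = -np.inf
    means = variances = weights = None
    status = "max_iter"
    for _ in range(max_iter):
        # ---- M-step from current responsibilities
        nk = resp.sum(axis=0)                           # (K,)
        if (nk / n < 1.0 / (10.0 * n)).any():  # weight below 1/(10n)
            return {}, "empty class"
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]              # (K, 2)
        sq = (X[:, None, :] - means[None, :, :]) ** 2   # (n, K, 2)
        if variance_structure == "shared":
            shared = np.einsum("nk,nkj->j", resp, sq) / n
            variances = np.maximum(shared, VARIANCE_FLOOR)
            var_k = np.broadcast_to(variances, (K, 2))
        else:
            var_k = np.einsum("nk,nkj->kj", resp, sq) / nk[:, None]
            var_k = np.maximum(var_k, VARIANCE_FLOOR)
            variances = var_k
        # ---- E-step
        logdens = _log_densities(X, means, np.asarray(var_k)) + np.log(weights)[None, :]
        row_logsum = logsumexp(logdens, axis=1)
        new_logL = float(row_logsum.sum())
        resp = np.exp(logdens - row_logsum[:, None])
        loglik_path.append(new_logL)
        if np.isfinite(logL):
            rel = abs(new_logL - logL) / (abs(logL) + 1.0)
            if rel < tol:
                logL = new_logL
                status = "converged"
                break
        logL = new_logL
    result = {
        "weights": weights,
        "means": means,
        "variances": np.asarray(variances),
        "logL": logL,
        "posteriors": resp,
        "loglik_path": np.asarray(loglik_path),
    }
    return result, status


def fit_lpa(
    data: np.ndarray,
    K: int,
    *,
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-8,
    variance_structure: str = "shared",
    seed: Optional[int] = None,
) -> LPAFit:
    """Fit a K-class profile model by EM with seeded random restarts.

    Each restart initializes from a random responsibility matrix
    (Dirichlet rows) followed by an M-step; the start attaining the best
    log-likelihood wins (ties broken toward the lowest start index).  A
    class whose expected size falls below 1/(10n) of the sample aborts the
    start rather than continuing silently.  Raises
    :class:`ConvergenceError` when every start aborts.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("data must be an n x 2 matrix")
    if not np.isfinite(X).all():
        raise ValueError("data must be finite")
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        raise ValueError(f"need n > K, got n={n}, K={K}")
    n_free_parameters(K, variance_structure)  # validates structure name

    rng = np.random.default_rng(seed)
    best: Optional[dict] = None
    best_status = ""
    diagnostics: list[str] = []
    any_converged = False
    for start in range(restarts):
        result, status = _em_single_start(X, K, rng, max_iter, tol, variance_structure)
        diagnostics.append(f"start {start}: {status}")
        if not result:
            continue
        if status == "converged":
            any_converged = True
        # strict > keeps the lowest start index among equal-logL starts
        if best is None or result["logL"] > best["logL"] + 0.0:
            best, best_status = result, status
    if best is None:
        raise ConvergenceError(f"all {restarts} EM starts aborted", diagnostics)
    if not any_converged:
        warnings.warn(
            f"no EM start converged within {max_iter} iterations; "
            "returning the best available fit",
            stacklevel=2,
        )

    posteriors = best["posteriors"]
    return LPAFit(
        K=K,
        weights=np.asarray(best["weights"]),
        means=np.asarray(best["means"]),
        variances=np.asarray(best["variances"]),
        variance_structure=variance_structure,
        logL=best["logL"],
        n_params=n_free_parameters(K, variance_structure),
        n=n,
        posteriors=posteriors,
        assignments=np.argmax(posteriors, axis=1),
        converged=best_status == "converged",
        n_restarts_used=restarts,
        loglik_path=best["loglik_path"],
    )


def information_criteria(logL: float, p: int, n: int) -> dict[str, float]:
    """AIC = -2logL + 2p; BIC = -2logL + p ln n;
    aBIC = -2logL + p ln((n+2)/24) (sample-size-adjusted BIC)."""
    if p < 1 or n < 1:
        raise ValueError("need p >= 1 and n >= 1")
    neg2 = -2.0 * logL
    return {
        "AIC": neg2 + 2.0 * p,
        "BIC": neg2 + p * np.log(n),
        "aBIC": neg2 + p * np.log((n + 2.0) / 24.0),
    }


def entropy(posteriors: np.ndarray) -> float:
    """Standardized entropy E = 1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K).

    1 means perfectly crisp assignment, 0 maximal uncertainty.  Undefined
    for K = 1.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2:
        raise ValueError("posteriors must be an n x K matrix")
    n, K = P.shape
    if K < 2:
        raise ValueError("entropy undefined for K = 1")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0.0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


def assignment_probability_matrix(fit: LPAFit) -> np.ndarray:
    """K x K matrix: entry (j, k) is the average posterior probability of
    class k among observations modally assigned to class j.  Rows sum to 1;
    an empty modal class yields a NaN row (flagged undefined)."""
    K = fit.K
    out = np.full((K, K), np.nan)
    for j in range(K):
        mask = fit.assignments == j
        if mask.any():
            out[j] = fit.posteriors[mask].mean(axis=0)
    return out


def _check_nested(fit_k: LPAFit, fit_km1: LPAFit) -> None:
    if fit_km1.K != fit_k.K - 1:
        raise ValueError(
            f"models must be nested with one class difference, got "
            f"K={fit_k.K} vs {fit_km1.K}"
        )
    if fit_k.n != fit_km1.n:
        raise ValueError("fits must be on identical data (n differs)")
    if fit_k.variance_structure != fit_km1.variance_structure:
        raise ValueError("fits must share the variance structure")


def lmr_alrt(fit_k: LPAFit, fit_km1: LPAFit, n: Optional[int] = None) -> dict:
    """Lo–Mendell–Rubin adjusted likelihood-ratio test of K-1 vs K classes.

    The adjusted statistic is 2*(logL_K - logL_{K-1}) divided by the
    correction 1 + 1/(d ln n), d = p_K - p_{K-1}.  Small p favors the
    larger model.  The p-value uses a chi-square(2d) reference: mixture
    LRTs violate the regularity behind the usual chi-square(d) law, and
    the doubled degrees of freedom are the classical rule of thumb for
    component-count tests in normal mixtures (a chi-square(d) reference
    is grossly anti-conservative here).  Still an approximation — see
    :func:`bootstrap_lrt` for the preferred decision tool.
    """
    _check_nested(fit_k, fit_km1)
    n = fit_k.n if n is None else n
    d = fit_k.n_params - fit_km1.n_params
    lr = 2.0 * (fit_k.logL - fit_km1.logL)
    if lr < 0:
        if lr < -1e-3:  # beyond numerical noise: a genuinely underfit start
            warnings.warn(
                f"negative LR statistic ({lr:.3g}): the larger model is "
                "underfit (local optimum); clamping to 0",
                stacklevel=2,
            )
        lr = 0.0
    correction = 1.0 + 1.0 / (d * np.log(n))
    statistic = lr / correction
    p = float(stats.chi2.sf(statistic, 2 * d)) if statistic > 0 else 1.0
    return {"statistic": float(statistic), "p": p, "df": d,
            "correction": float(correction)}


def _simulate_from_fit(fit: LPAFit, n: int, rng: np.random.Generator) -> np.ndarray:
    labels = rng.choice(fit.K, size=n, p=fit.weights / fit.weights.sum())
    sds = np.sqrt(fit.class_variances())
    return rng.normal(fit.means[labels], sds[labels])


def bootstrap_lrt(
    fit_k: LPAFit,
    fit_km1: LPAFit,
    B: int = 99,
    seed: Optional[int] = None,
    *,
    restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> dict:
    """Parametric bootstrap LRT of K-1 vs K classes.

    Simulates B datasets under the fitted (K-1)-class model, refits both
    models on each, and returns p = (1 + #{boot >= observed}) / (B + 1).
    A replicate whose EM fails entirely is redrawn (up to 5B attempts).
    """
    _check_nested(fit_k, fit_km1)
    if B < 19:
        raise ValueError("need B >= 19 bootstrap replicates")
    observed = max(0.0, 2.0 * (fit_k.logL - fit_km1.logL))
    rng = np.random.default_rng(seed)
    stats_boot: list[float] = []
    attempts = 0
    while len(stats_boot) < B:
        if attempts >= 5 * B:
            raise RuntimeError("too many failed bootstrap replicates")
        attempts += 1
        data = _simulate_from_fit(fit_km1, fit_km1.n, rng)
        try:
            seeds = rng.integers(0, 2**31 - 1, size=2)
            f0 = fit_lpa(data, fit_km1.K, restarts=restarts, max_iter=max_iter,
                         tol=tol, variance_structure=fit_km1.variance_structure,
                         seed=int(seeds[0]))
            f1 = fit_lpa(data, fit_k.K, restarts=restarts, max_iter=max_iter,
                         tol=tol, variance_structure=fit_k.variance_structure,
                         seed=int(seeds[1]))
        except ConvergenceError:
            continue
        stats_boot.append(max(0.0, 2.0 * (f1.logL - f0.logL)))
    n_ge = sum(1 for s in stats_boot if s >= observed)
    return {
        "statistic": observed,
        "p": (1.0 + n_ge) / (B + 1.0),
        "B": B,
        "replicates": np.asarray(stats_boot),
    }


@dataclass
class SelectionTable:
    """Model-selection summary over a contiguous K range."""

    rows: list[dict]
    chosen_K: int
    rationale: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def selection_rows(fits: Sequence[LPAFit]) -> list[dict]:
    """Build selection-table rows (ICs, entropy, LMR) from fitted models
    for a contiguous K range starting at 1."""
    fits = sorted(fits, key=lambda f: f.K)
    if [f.K for f in fits] != list(range(1, len(fits) + 1)):
        raise ValueError("need fits for a contiguous K range starting at 1")
    rows = []
    for i, fit in enumerate(fits):
        ics = fit.information_criteria()
        row = {
            "K": fit.K, "logL": fit.logL, "p": fit.n_params,
            "AIC": ics["AIC"], "BIC": ics["BIC"], "aBIC": ics["aBIC"],
            "entropy": entropy(fit.posteriors) if fit.K > 1 else None,
            "lmr_stat": None, "lmr_p": None,
        }
        if i > 0:
            test = lmr_alrt(fit, fits[i - 1])
            row["lmr_stat"], row["lmr_p"] = test["statistic"], test["p"]
        rows.append(row)
    return rows


def select_model(
    fits: Union[Sequence[LPAFit], Sequence[dict]],
    alpha: float = 0.05,
) -> SelectionTable:
    """Choose the class count from fits (or prebuilt selection rows).

    Composite rule: prefer the K (>= 2) whose LMR test is significant at
    ``alpha`` while the K+1 test is not (or K is the largest fitted);
    among several such K the one with the higher entropy wins; with no
    significant test anywhere, K = 1 is retained.  The rationale records
    where each information criterion attains its minimum, since the
    "lower is better" evidence may keep decreasing past the chosen K.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    if isinstance(fits[0], LPAFit):
        rows = selection_rows(fits)  # type: ignore[arg-type]
    else:
        rows = sorted((dict(r) for r in fits), key=lambda r: r["K"])  # type: ignore[union-attr]
        if [r["K"] for r in rows] != list(range(1, len(rows) + 1)):
            raise ValueError("need rows for a contiguous K range starting at 1")

    k_max = rows[-1]["K"]
    candidates = []
    for row in rows[1:]:
        K, p = row["K"], row["lmr_p"]
        if p is None or p >= alpha:
            continue
        nxt = next((r for r in rows if r["K"] == K + 1), None)
        if nxt is None or nxt["lmr_p"] is None or nxt["lmr_p"] >= alpha:
            candidates.append(row)

    if not candidates:
        chosen = 1
        reason = f"no LMR test significant at alpha={alpha}; 1-class model retained"
    elif len(candidates) == 1:
        chosen = candidates[0]["K"]
        reason = (
            f"LMR p={candidates[0]['lmr_p']:.3f} < {alpha} at K={chosen} and "
            f"non-significant at K={chosen + 1}" if chosen < k_max else
            f"LMR p={candidates[0]['lmr_p']:.3f} < {alpha} at the largest fitted K={chosen}"
        )
    else:
        best = max(candidates, key=lambda r: (r["entropy"] or -np.inf, -r["K"]))
        chosen = best["K"]
        reason = (
            f"{len(candidates)} K values pass the LMR rule; "
            f"K={chosen} has the highest entropy ({best['entropy']:.3f})"
        )

    ic_mins = {
        ic: min(rows, key=lambda r: r[ic])["K"] for ic in ("AIC", "BIC", "aBIC")
    }
    conflict = [f"{ic} minimal at K={k}" for ic, k in ic_mins.items() if k != chosen]
    rationale = reason + (
        "; note conflicting lower-is-better evidence: " + ", ".join(conflict)
        if conflict else ""
    )
    return SelectionTable(rows=rows, chosen_K=chosen, rationale=rationale)
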