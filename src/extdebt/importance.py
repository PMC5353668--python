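"""Decomposition of a linear model's R² across predictors.

Four ranking metrics, applied to the regression of richness on the eight
forest predictors:

* ``first``  — R² of each predictor entered alone;
* ``last``   — increase in R² when the predictor enters last;
* ``lmg``    — incremental R² averaged over all p! orders of entry (the
  Shapley decomposition of R²; sums exactly to the full-model R²);
* ``genizi`` — Genizi's decomposition via the symmetric square root of the
  predictor correlation matrix (also sums exactly to R²).

All subset R² values are computed from moment (correlation) matrices, so a
full bootstrap costs one covariance per resample plus 2^p small solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd

METRICS = ("lmg", "last", "first", "genizi")

__all__ = [
    "METRICS",
    "ImportanceResult",
    "r_squared_subsets",
    "lmg",
    "first",
    "last",
    "genizi",
    "relative_importance",
    "bootstrap_importance",
]

_MAX_PREDICTORS = 15


def _moments(X, y):
    """Correlation matrix of predictors and predictor–response correlations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of rows")
    if p > _MAX_PREDICTORS:
        raise ValueError(f"at most {_MAX_PREDICTORS} predictors supported (2^p enumeration)")
    if n <= p + 1:
        raise ValueError("need more observations than predictors")
    sd = X.std(axis=0)
    if np.any(sd == 0) or y.std() == 0:
        raise ValueError("constant predictor or response")
    Z = (X - X.mean(axis=0)) / sd
    yz = (y - y.mean()) / y.std()
    Rxx = (Z.T @ Z) / n
    rxy = (Z.T @ yz) / n
    return Rxx, rxy, p


def _subset_r2(Rxx, rxy, idx) -> float:
    if not idx:
        return 0.0
    idx = list(idx)
    sub = Rxx[np.ix_(idx, idx)]
    r = rxy[idx]
    beta = np.linalg.solve(sub, r)
    return float(r @ beta)


def _check_full_rank(Rxx):
    if np.linalg.matrix_rank(Rxx, tol=1e-10) < Rxx.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient full predictor matrix")


def _all_subsets(p: int) -> list[tuple]:
    return [idx for k in range(p + 1) for idx in combinations(range(p), k)]


def _subsets_from_moments(Rxx, rxy, p) -> dict[tuple, float]:
    _check_full_rank(Rxx)
    return {idx: _subset_r2(Rxx, rxy, idx) for idx in _all_subsets(p)}


def r_squared_subsets(X, y) -> dict[tuple, float]:
    """OLS R² (with intercept) for every predictor subset; R²(∅) = 0."""
    Rxx, rxy, p = _moments(X, y)
    return _subsets_from_moments(Rxx, rxy, p)


def _lmg_from_subsets(subsets: dict[tuple, float], p: int) -> np.ndarray:
    values = np.zeros(p)
    fact = [factorial(i) for i in range(p + 1)]
    for k in range(p):
        total = 0.0
        for idx, r2 in subsets.items():
            if k in idx:
                continue
            s = len(idx)
            w = fact[s] * fact[p - s - 1] / fact[p]
            with_k = tuple(sorted(idx + (k,)))
            total += w * (subsets[with_k] - r2)
        values[k] = total
    return values


def _lmg_m(Rxx, rxy, p):
    return _lmg_from_subsets(_subsets_from_moments(Rxx, rxy, p), p)


def _first_m(Rxx, rxy, p):
    return np.array([_subset_r2(Rxx, rxy, (k,)) for k in range(p)])


def _last_m(Rxx, rxy, p):
    _check_full_rank(Rxx)
    full = _subset_r2(Rxx, rxy, tuple(range(p)))
    return np.array([
        full - _subset_r2(Rxx, rxy, tuple(j for j in range(p) if j != k))
        for k in range(p)
    ])


def _genizi_m(Rxx, rxy, p):
    # genizi_k = ((R_xx^{1/2} β)_k)² with standardized coefficients β and the
    # symmetric PSD square root: since R² = (R^{1/2}β)ᵀ(R^{1/2}β), the shares
    # sum to R² exactly; with orthogonal predictors they reduce to β_k².
    evals, evecs = np.linalg.eigh(Rxx)
    if evals.min() <= 1e-10:
        raise np.linalg.LinAlgError("predictor correlation matrix is not positive definite")
    root = (evecs * np.sqrt(evals)) @ evecs.T
    beta = np.linalg.solve(Rxx, rxy)
    return (root @ beta) ** 2


def lmg(X, y) -> np.ndarray:
    """Shapley (order-averaged incremental R²) share per predictor."""
    return _lmg_m(*_moments(X, y))


def first(X, y) -> np.ndarray:
    """Univariate R² per predictor (entered first)."""
    return _first_m(*_moments(X, y))


def last(X, y) -> np.ndarray:
    """Incremental R² per predictor entered last: R²(full) − R²(full ∖ {k})."""
    return _last_m(*_moments(X, y))


def genizi(X, y) -> np.ndarray:
    """Genizi decomposition: genizi_k = ((R_xx^{1/2} β)_k)² with standardized
    coefficients β and the symmetric PSD square root of the predictor
    correlation matrix; the shares sum exactly to R²."""
    return _genizi_m(*_moments(X, y))


def lmg_bruteforce(X, y) -> np.ndarray:
    """Average incremental R² over all p! explicit orderings (oracle path;
    exponential, for small p only)."""
    Rxx, rxy, p = _moments(X, y)
    if p > 7:
        raise ValueError("brute-force enumeration limited to p <= 7")
    subsets = r_squared_subsets(X, y)
    values = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        seen: tuple = ()
        for k in order:
            before = subsets[tuple(sorted(seen))]
            seen = seen + (k,)
            values[k] += subsets[tuple(sorted(seen))] - before
    return values / len(orders)


_METRIC_FUNCS = {"lmg": lmg, "last": last, "first": first, "genizi": genizi}
_METRIC_FUNCS_M = {"lmg": _lmg_m, "last": _last_m, "first": _first_m, "genizi": _genizi_m}


def _metrics_from_moments(Rxx, rxy, p, metrics) -> dict[str, np.ndarray]:
    """All requested metrics from one set of moments; the subset-R² map is
    shared between lmg and last when both are requested."""
    out = {}
    if "lmg" in metrics or "last" in metrics:
        subsets = _subsets_from_moments(Rxx, rxy, p)
        if "lmg" in metrics:
            out["lmg"] = _lmg_from_subsets(subsets, p)
        if "last" in metrics:
            full = subsets[tuple(range(p))]
            out["last"] = np.array([
                full - subsets[tuple(j for j in range(p) if j != k)]
                for k in range(p)
            ])
    for m in metrics:
        if m not in out:
            out[m] = _METRIC_FUNCS_M[m](Rxx, rxy, p)
    return out


def relative_importance(X, y, names=None, metrics=METRICS, normalize: bool = False) -> pd.DataFrame:
    """Tidy per-predictor importance table (one row per predictor × metric).

    ``normalize=True`` rescales each metric to sum to 100% of R² (lmg and
    genizi already sum to R²; first and last generally do not).
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1] if X.ndim == 2 else 1
    names = list(names) if names is not None else [f"x{k}" for k in range(p)]
    Rxx, rxy, _ = _moments(X, y)
    _check_full_rank(Rxx)
    full_r2 = _subset_r2(Rxx, rxy, tuple(range(p)))
    values = _metrics_from_moments(Rxx, rxy, p, metrics)
    rows = []
    for metric in metrics:
        vals = values[metric]
        if normalize:
            vals = vals / vals.sum() * 100.0
        for name, v in zip(names, vals):
            rows.append({"predictor": name, "metric": metric, "value": v})
    df = pd.DataFrame(rows)
    df.attrs["r_squared"] = full_r2
    return df


@dataclass
class ImportanceResult:
    predictors: list
    metrics: tuple
    point: pd.DataFrame        # index predictor, columns metric
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    r_squared: float
    n_bootstrap: int
    n_skipped: int
    seed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for metric in self.metrics:
            for pred in self.predictors:
                rows.append({
                    "predictor": pred, "metric": metric,
                    "value": self.point.loc[pred, metric],
                    "ci_low": self.ci_low.loc[pred, metric],
                    "ci_high": self.ci_high.loc[pred, metric],
                })
        return pd.DataFrame(rows)


def bootstrap_importance(
    X,
    y,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    names=None,
    metrics=METRICS,
    ci_level: float = 0.95,
) -> ImportanceResult:
    """Case-resampling bootstrap of the importance metrics with percentile
    intervals; rank-deficient resamples are skipped and counted."""
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap iteration")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = list(names) if names is not None else [f"x{k}" for k in range(p)]
    Rxx, rxy, _ = _moments(X, y)
    _check_full_rank(Rxx)
    full_r2 = _subset_r2(Rxx, rxy, tuple(range(p)))
    point = _metrics_from_moments(Rxx, rxy, p, metrics)

    rng = np.random.default_rng(seed)
    draws = {m: np.full((n_bootstrap, p), np.nan) for m in metrics}
    skipped = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            Rb, rb, _ = _moments(X[idx], y[idx])
            vals = _metrics_from_moments(Rb, rb, p, metrics)
            for m in metrics:
                draws[m][b] = vals[m]
        except (np.linalg.LinAlgError, ValueError):
            skipped += 1
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    point_df = pd.DataFrame({m: point[m] for m in metrics}, index=names)
    lo = pd.DataFrame({m: np.nanquantile(draws[m], lo_q, axis=0) for m in metrics}, index=names)
    hi = pd.DataFrame({m: np.nanquantile(draws[m], hi_q, axis=0) for m in metrics}, index=names)
    return ImportanceResult(names, tuple(metrics), point_df, lo, hi,
                            full_r2, n_bootstrap, skipped, seed)
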