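"""Statistics helpers: correlation, regression, randomization test, batch
normalization.

Pearson correlation and ordinary least squares are delegated to scipy.  The
two-sided randomization (permutation) test on the difference of group means
enumerates all label assignments exhaustively when there are at most 20,000
of them, otherwise it falls back to seeded Monte-Carlo sampling with the
add-one correction (so p is never exactly zero).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import OxidimerError

__all__ = ["PairedSeries", "pearson_r2", "linear_regression", "randomization_test",
           "batch_normalize", "EXHAUSTIVE_LIMIT"]

EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned value series (e.g. the same energies at two theory levels)."""

    x: np.ndarray
    y: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise OxidimerError("paired series must be 1-D and equal length")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise OxidimerError("paired series contain missing values")


def _as_series(series) -> PairedSeries:
    if isinstance(series, PairedSeries):
        return series
    x, y = series
    return PairedSeries(x=np.asarray(x, float), y=np.asarray(y, float))


def pearson_r2(series) -> tuple:
    """(r, r²) of a paired series; constant input is an error (undefined r)."""
    s = _as_series(series)
    if s.x.size < 3:
        raise OxidimerError("need at least 3 points for a correlation")
    if np.ptp(s.x) == 0 or np.ptp(s.y) == 0:
        raise OxidimerError("correlation undefined for a constant series")
    r = float(_sps.pearsonr(s.x, s.y).statistic)
    return r, r * r


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    stderr_slope: float
    stderr_intercept: float


def linear_regression(series) -> RegressionResult:
    """Ordinary least squares y = slope*x + intercept."""
    s = _as_series(series)
    if s.x.size < 3:
        raise OxidimerError("need at least 3 points for a regression")
    if np.ptp(s.x) == 0:
        raise OxidimerError("regression undefined: x is constant (vertical line)")
    fit = _sps.linregress(s.x, s.y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r2=float(fit.rvalue) ** 2, stderr_slope=float(fit.stderr),
                            stderr_intercept=float(fit.intercept_stderr))


def _mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    return float(a.mean() - b.mean())


def randomization_test(group_a: Sequence[float], group_b: Sequence[float],
                       n_perm: int = 10_000, seed: Optional[int] = None,
                       statistic: Callable[[np.ndarray, np.ndarray], float] = _mean_difference,
                       ) -> float:
    """Two-sided randomization test for a difference between two groups.

    p is the proportion of label reassignments whose |statistic| is at least
    the observed |statistic|.  All C(n, n_a) assignments are enumerated when
    that count is ≤ 20,000 (the observed assignment is one of them, so p > 0
    automatically); otherwise ``n_perm`` seeded shuffles are drawn and the
    add-one correction is applied.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise OxidimerError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(statistic(a, b))
    total = math.comb(n, na)
    if total <= EXHAUSTIVE_LIMIT:
        if statistic is _mean_difference:
            # vectorized fast path for the default statistic
            idx = np.fromiter((i for keep in combinations(range(n), na) for i in keep),
                              dtype=np.intp, count=total * na).reshape(total, na)
            sums_a = pooled[idx].sum(axis=1)
            stat = sums_a / na - (pooled.sum() - sums_a) / (n - na)
            return int((np.abs(stat) >= observed - 1e-12).sum()) / total
        count = 0
        for keep in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(keep)] = True
            if abs(statistic(pooled[mask], pooled[~mask])) >= observed - 1e-12:
                count += 1
        return count / total
    if seed is None:
        raise OxidimerError("seed is required for Monte-Carlo permutation sampling")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:na], perm[na:])) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def batch_normalize(batches: Mapping[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    """Divide each value by its batch mean (assay normalization), preserving
    batch keys; concatenate with ``np.concatenate(list(result.values()))``."""
    out: Dict[str, np.ndarray] = {}
    for name, values in batches.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise OxidimerError(f"batch {name!r} is empty")
        mean = arr.mean()
        if mean == 0:
            raise OxidimerError(f"batch {name!r} has zero mean; cannot normalize")
        out[name] = arr / mean
    return out
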