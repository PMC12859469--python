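"""Singular spectrum analysis and the Mann–Kendall trend test.

SSA embeds a length-N series into an L x K Hankel trajectory matrix
(K = N - L + 1, trajectory[i, j] = x[i + j]), takes its SVD, and maps
selected eigentriples (singular value + left/right vectors) back to
series by summing their rank-1 matrices and averaging anti-diagonals
("hankelization").  Reconstruction from all eigentriples reproduces the
input exactly.

The weekly dispensing/centrality series are decomposed in two stages:

1. a basic SSA with lag L = 52 (one year of weeks) whose leading
   eigentriple group is the dominant trend;
2. a second SSA on the stage-1 residual with the maximal lag
   L = floor(N/2), whose top k eigentriples (default 25) are the
   oscillatory components F1..Fk ordered by singular value.

The headline reconstruction is trend + F1 + F2.  Variance shares are
squared singular values within their stage (a reconstructed-variance
estimator is available as an alternative).

Long-term monotone change is tested with the Mann–Kendall statistic
S = sum_{i<j} sign(x_j - x_i), tie-corrected variance, continuity
correction, and a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "SsaModel",
    "SsaDecomposition",
    "TrendTestResult",
    "embed",
    "reconstruct",
    "two_stage_ssa",
    "mann_kendall",
]


@dataclass
class SsaModel:
    """Hankel embedding of a series together with its SVD."""

    series: np.ndarray
    L: int
    trajectory: np.ndarray  # (L, K), K = N - L + 1
    U: np.ndarray
    s: np.ndarray  # singular values, non-increasing
    Vt: np.ndarray

    @property
    def N(self) -> int:
        return len(self.series)

    @property
    def K(self) -> int:
        return self.N - self.L + 1


def embed(series: np.ndarray, L: int) -> SsaModel:
    """Build the L x K trajectory matrix of a series and compute its SVD."""
    x = np.asarray(series, dtype=float)
    N = len(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if not 2 <= L <= N - 1:
        raise ValueError(f"L must satisfy 2 <= L <= N-1 = {N - 1}, got {L}")
    K = N - L + 1
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    traj = x[idx]
    U, s, Vt = np.linalg.svd(traj, full_matrices=False)
    return SsaModel(series=x, L=L, trajectory=traj, U=U, s=s, Vt=Vt)


def _hankelize(M: np.ndarray) -> np.ndarray:
    """Anti-diagonal averaging: map an L x K matrix back to a series."""
    L, K = M.shape
    N = L + K - 1
    idx = (np.arange(L)[:, None] + np.arange(K)[None, :]).ravel()
    sums = np.bincount(idx, weights=M.ravel(), minlength=N)
    counts = np.bincount(idx, minlength=N)
    return sums / counts


def reconstruct(model: SsaModel, components: Iterable[int]) -> np.ndarray:
    """Series reconstructed from the chosen eigentriples (0-based indices)."""
    comp = sorted(set(int(i) for i in components))
    if not comp:
        return np.zeros(model.N)
    if comp[0] < 0 or comp[-1] >= len(model.s):
        raise ValueError(f"component indices must be in [0, {len(model.s) - 1}]")
    c = np.asarray(comp)
    M = (model.U[:, c] * model.s[c]) @ model.Vt[c, :]
    return _hankelize(M)


@dataclass
class SsaDecomposition:
    """Two-stage SSA decomposition of one weekly series."""

    trend: np.ndarray
    components: np.ndarray  # (k, N): F1..Fk from stage 2
    remainder: np.ndarray  # stage-1 residual minus the k components
    trend_share: float  # stage-1 variance share of the trend group
    component_shares: np.ndarray  # stage-2 shares of F1..Fk, non-increasing
    reconstruction: np.ndarray  # trend + F1 + F2
    stage1: SsaModel = field(repr=False)
    stage2: SsaModel = field(repr=False)
    trend_components: tuple[int, ...] = (0,)

    @property
    def residual(self) -> np.ndarray:
        """Stage-1 residual (input minus trend)."""
        return self.stage1.series - self.trend


def _shares(model: SsaModel, method: str, parts: list[np.ndarray] | None = None):
    if method == "singular":
        return model.s**2 / float((model.s**2).sum())
    if method == "reconstruction_variance":
        total = float(np.var(model.series))
        return np.array([np.var(p) / total for p in parts])
    raise ValueError("share method must be 'singular' or 'reconstruction_variance'")


def two_stage_ssa(
    series: np.ndarray,
    L1: int = 52,
    n_components: int = 25,
    trend_components: tuple[int, ...] = (0,),
    share_method: str = "singular",
) -> SsaDecomposition:
    """Trend (stage 1, lag L1) + oscillatory components (stage 2, lag N//2).

    Requires N >= 2 * L1 (two full years of weeks at the default L1=52).
    Returns the top ``min(n_components, L2)`` stage-2 eigentriples as
    F1..Fk, ordered by singular value.
    """
    x = np.asarray(series, dtype=float)
    N = len(x)
    if N < 2 * L1:
        raise ValueError(f"series too short: need N >= {2 * L1}, got {N}")

    m1 = embed(x, L1)
    trend = reconstruct(m1, trend_components)
    resid = x - trend

    L2 = N // 2
    m2 = embed(resid, L2)
    k = int(min(n_components, len(m2.s)))
    comps = np.stack([reconstruct(m2, [i]) for i in range(k)])
    remainder = resid - comps.sum(axis=0)

    s1_shares = _shares(m1, share_method, [trend])
    if share_method == "singular":
        trend_share = float(s1_shares[list(trend_components)].sum())
        comp_shares = _shares(m2, "singular")[:k]
    else:
        trend_share = float(np.var(trend) / np.var(x))
        comp_shares = _shares(m2, "reconstruction_variance", list(comps))

    reconstruction = trend + comps[0] + (comps[1] if k > 1 else 0.0)
    return SsaDecomposition(
        trend=trend,
        components=comps,
        remainder=remainder,
        trend_share=trend_share,
        component_shares=np.asarray(comp_shares),
        reconstruction=reconstruction,
        stage1=m1,
        stage2=m2,
        trend_components=tuple(trend_components),
    )


@dataclass(frozen=True)
class TrendTestResult:
    """Mann–Kendall monotone-trend test result."""

    S: int
    var_S: float
    z: float
    p: float
    direction: str  # increasing / decreasing / none
    n: int


def mann_kendall(series: np.ndarray, alpha: float = 0.05) -> TrendTestResult:
    """Mann–Kendall test with tie correction and continuity correction.

    ``S = sum_{i<j} sign(x_j - x_i)``;
    ``var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` over tie groups
    of size t; ``z = (S -+ 1)/sqrt(var S)`` (0 when S = 0); two-sided
    normal p-value.  Direction is the sign of S when p < alpha.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann–Kendall needs at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    sgn = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(sgn, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_S = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if var_S <= 0:  # all values identical
        return TrendTestResult(S=0, var_S=0.0, z=0.0, p=1.0, direction="none", n=n)
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p < alpha and S > 0:
        direction = "increasing"
    elif p < alpha and S < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendTestResult(S=S, var_S=float(var_S), z=float(z), p=p, direction=direction, n=n)
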