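"""Nonparametric circadian rhythm detection (JTK_CYCLE-style scan).

The scan correlates each gene's time course with a grid of cosine reference
waveforms (periods across a configurable window, default 18-30 h; peak lags
stepped at the sampling interval) via Kendall's S statistic. Because only the
*ranks* of the reference matter, replicates and symmetric cosine values create
tie-groups; the null distribution of S under a uniformly random ordering of
the data respecting those tie-groups is the Jonckheere-Terpstra null, computed
exactly by generating-function (Gaussian-multinomial) convolution.

Per gene the minimum two-sided exact tail p over the grid is Bonferroni-
multiplied by the number of rank-distinct reference waveforms (capped at 1);
Benjamini-Hochberg q-values are computed across genes. Amplitude is estimated
by a least-squares cosinor fit at the selected (period, lag) and the relative
amplitude is amplitude / max expression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io_formats import TimeCourseMatrix

__all__ = [
    "ReferenceWaveform",
    "JTNull",
    "build_reference_grid",
    "exact_jt_null",
    "enumerated_jt_null",
    "jtk_scan",
    "estimate_amplitude",
    "rank_rel_amp",
    "REL_AMP_RANKS",
    "JTKCycle",
]


@dataclass(frozen=True)
class ReferenceWaveform:
    """A (period, lag) cosine reference reduced to integer ranks at the sample zts.

    ``group_ranks`` holds one dense rank per sample; equal cosine values (ties,
    e.g. from replicates or cosine symmetry) share a rank.
    """

    period: float
    lag: float
    group_ranks: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.lag < self.period):
            raise ValueError(f"lag {self.lag} outside [0, period={self.period})")


def _dense_ranks(values: np.ndarray, decimals: int = 9) -> tuple[int, ...]:
    """Dense integer ranks with ties, robust to float fuzz via rounding."""
    v = np.round(np.asarray(values, dtype=float), decimals)
    _, inv = np.unique(v, return_inverse=True)
    return tuple(int(i) for i in inv)


def _sampling_interval(zts: np.ndarray) -> float:
    u = np.sort(np.unique(zts))
    if len(u) < 2:
        raise ValueError("need at least 2 distinct zeitgeber times")
    return float(np.min(np.diff(u)))


def build_reference_grid(
    zts: Sequence[float],
    period_window: tuple[float, float] = (18.0, 30.0),
    period_step: float | None = None,
    lag_step: float | None = None,
    collapse: bool = True,
) -> list[ReferenceWaveform]:
    """Build the (period, lag) cosine reference grid for the given sample zts.

    Period endpoints default to the 18-30 h circadian window; both grid steps
    default to the sampling interval. Waveforms with identical rank patterns
    are collapsed to the first occurrence (period ascending, then lag
    ascending) when ``collapse`` is true; the collapsed count is the Bonferroni
    factor of the scan.
    """
    zts = np.asarray(zts, dtype=float)
    if len(np.unique(zts)) < 3:
        raise ValueError("reference grid needs at least 3 distinct timepoints")
    lo, hi = float(period_window[0]), float(period_window[1])
    if lo > hi:
        raise ValueError(f"period window low {lo} > high {hi}")
    step = _sampling_interval(zts)
    if period_step is None:
        period_step = step
    if lag_step is None:
        lag_step = step
    if hi > lo and period_step > (hi - lo):
        raise ValueError("empty period grid (step larger than window)")
    periods = np.arange(lo, hi + 1e-9, period_step)
    out: list[ReferenceWaveform] = []
    seen: set[tuple[int, ...]] = set()
    for period in periods:
        for lag in np.arange(0.0, period - 1e-9, lag_step):
            ranks = _dense_ranks(np.cos(2.0 * np.pi * (zts - lag) / period))
            if collapse:
                if ranks in seen:
                    continue
                seen.add(ranks)
            out.append(ReferenceWaveform(float(period), float(lag), ranks))
    if not out:
        raise ValueError("empty reference grid")
    return out


# ---------------------------------------------------------------------------
# exact null distribution
# ---------------------------------------------------------------------------


def _q_binomial(t: int, m: int) -> list[int]:
    """Coefficients of the Gaussian binomial [t+m choose t]_q (degree t*m).

    Built by exact integer polynomial multiplication by (1 - q^(m+i)) and
    synthetic division by (1 - q^i) for i = 1..t.
    """
    coef = [1]
    for i in range(1, t + 1):
        shift = m + i
        prod = [0] * (len(coef) + shift)
        for j, c in enumerate(coef):
            prod[j] += c
            prod[j + shift] -= c
        # divide by (1 - q^i): out[j] = prod[j] + out[j - i]
        out = [0] * (len(prod) - i)
        for j in range(len(out)):
            out[j] = prod[j] + (out[j - i] if j >= i else 0)
        coef = out
    # trim trailing zeros down to the known degree t*m
    return coef[: t * m + 1]


def _jt_counts(group_sizes: Sequence[int]) -> list[int]:
    """Exact counts of orderings by Jonckheere-Terpstra statistic value.

    The generating function of JT over uniformly random orderings with
    tie-groups of sizes t_1..t_g is the Gaussian multinomial
    [N; t_1..t_g]_q = prod_k [m_k + t_k choose t_k]_q with m_k cumulative.
    """
    counts = [1]
    m = 0
    for t in group_sizes:
        qb = _q_binomial(int(t), m)
        new = [0] * (len(counts) + len(qb) - 1)
        for a, ca in enumerate(counts):
            if ca:
                for b, cb in enumerate(qb):
                    if cb:
                        new[a + b] += ca * cb
        counts = new
        m += int(t)
    return counts


@dataclass
class JTNull:
    """Exact null over Kendall's S = 2*JT - M for a reference tie structure.

    ``s_values`` spans -M..M in steps of 2; ``pmf`` sums to 1 and is symmetric
    about 0. ``two_sided_tail[s]`` (s = 0..M) is P(|S| >= s) for any integer s.
    """

    max_s: int
    s_values: np.ndarray
    pmf: np.ndarray
    two_sided_tail: np.ndarray

    def two_sided_p(self, s_obs: float | np.ndarray) -> np.ndarray:
        """Exact two-sided tail probability P(|S_null| >= |s_obs|)."""
        s = np.minimum(np.ceil(np.abs(np.asarray(s_obs))).astype(int), self.max_s)
        return self.two_sided_tail[s]


def exact_jt_null(
    reference: ReferenceWaveform | Sequence[int], n_samples: int | None = None
) -> JTNull:
    """Exact Jonckheere-Terpstra/Kendall-S null for one reference waveform.

    ``reference`` may be a :class:`ReferenceWaveform` or a bare rank sequence.
    Raises if all reference ranks are tied (the statistic is undefined).
    """
    ranks = (
        reference.group_ranks
        if isinstance(reference, ReferenceWaveform)
        else tuple(reference)
    )
    if n_samples is not None and len(ranks) != n_samples:
        raise ValueError(f"reference has {len(ranks)} ranks, expected {n_samples}")
    n = len(ranks)
    sizes = sorted(np.bincount(np.asarray(ranks) - min(ranks)).tolist())
    sizes = [s for s in sizes if s > 0]
    if len(sizes) < 2:
        raise ValueError("all reference ranks tied: statistic undefined")
    max_s = (n * n - sum(s * s for s in sizes)) // 2
    counts = _jt_counts(sizes)
    total = sum(counts)
    pmf = np.array([c / total for c in counts], dtype=float)
    s_values = 2 * np.arange(len(counts)) - max_s
    # P(|S| >= s) for s = 0..M, exploiting support on s_values only
    tail = np.zeros(max_s + 1)
    for s_val, p in zip(s_values, pmf):
        a = abs(int(s_val))
        tail[: a + 1] += p  # contributes to all thresholds <= |s|
    return JTNull(max_s=max_s, s_values=s_values, pmf=pmf, two_sided_tail=tail)


def enumerated_jt_null(reference: ReferenceWaveform | Sequence[int]) -> JTNull:
    """Brute-force null by enumerating all n! orderings (test oracle, n <= 9)."""
    ranks = (
        np.asarray(reference.group_ranks)
        if isinstance(reference, ReferenceWaveform)
        else np.asarray(reference)
    )
    n = len(ranks)
    if n > 9:
        raise ValueError("enumeration oracle limited to n <= 9")
    i, j = np.triu_indices(n, k=1)
    ref_sign = np.sign(ranks[j] - ranks[i])
    max_s = int(np.sum(ref_sign != 0))
    from collections import Counter

    counter: Counter[int] = Counter()
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        s = int(np.sum(np.sign(p[j] - p[i]) * ref_sign))
        counter[s] += 1
    total = sum(counter.values())
    s_values = 2 * np.arange(max_s + 1) - max_s
    pmf = np.array([counter.get(int(s), 0) / total for s in s_values])
    tail = np.zeros(max_s + 1)
    for s_val, p in zip(s_values, pmf):
        tail[: abs(int(s_val)) + 1] += p
    return JTNull(max_s=max_s, s_values=s_values, pmf=pmf, two_sided_tail=tail)


# ---------------------------------------------------------------------------
# amplitude estimation and ranking
# ---------------------------------------------------------------------------


def estimate_amplitude(
    series: Sequence[float], zts: Sequence[float], period: float, lag: float
) -> tuple[float, float, float]:
    """Cosinor least-squares amplitude at fixed (period, lag).

    Fits y = b0 + b1 * cos(2*pi*(t - lag)/period); amp = max(b1, 0) (half
    peak-to-trough), max_expr = max(series), rel_amp = amp/max_expr (0 when the
    series maximum is 0). Degenerate inputs yield zeros, never an exception.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(zts, dtype=float)
    c = np.cos(2.0 * np.pi * (t - lag) / period)
    cvar = np.sum((c - c.mean()) ** 2)
    if cvar <= 0:
        b1 = 0.0
    else:
        b1 = float(np.sum((c - c.mean()) * (y - y.mean())) / cvar)
    amp = max(b1, 0.0)
    max_expr = float(np.max(y)) if len(y) else 0.0
    rel_amp = amp / max_expr if max_expr > 0 else 0.0
    return amp, max_expr, min(rel_amp, 1.0)


REL_AMP_RANKS = ("<0.1", "0.1-0.15", "0.15-0.2", "0.2-0.25", ">0.25")
_RANK_EDGES = (0.1, 0.15, 0.2, 0.25)


def rank_rel_amp(rel_amp: float) -> str:
    """Bin a relative amplitude into the 5 standard ranks.

    Bins are lower-open/upper-closed: 0.15 falls in "0.1-0.15".
    """
    r = float(rel_amp)
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"relative amplitude {r} outside [0, 1]")
    for edge, label in zip(_RANK_EDGES, REL_AMP_RANKS):
        if r <= edge:
            return label
    return REL_AMP_RANKS[-1]


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


class JTKCycle(BaseEstimator):
    """Sklearn-style estimator running the rhythm scan over a gene matrix.

    Parameters
    ----------
    period_window : (low, high) in hours; default the 18-30 h circadian window.
    period_step, lag_step : grid steps in hours; default the sampling interval.
    alpha : Bonferroni-adjusted significance gate for the ``rhythmic`` flag.

    Fitted attributes
    -----------------
    results_ : DataFrame with columns gene_id, p_adj, q, period, lag, tau,
        amp, max_expr, rel_amp, rhythmic (input gene order preserved).
    grid_ : the collapsed reference grid; n_references_ : Bonferroni factor.
    """

    def __init__(
        self,
        period_window: tuple[float, float] = (18.0, 30.0),
        period_step: float | None = None,
        lag_step: float | None = None,
        alpha: float = 0.05,
    ):
        self.period_window = period_window
        self.period_step = period_step
        self.lag_step = lag_step
        self.alpha = alpha

    def fit(self, X: TimeCourseMatrix | np.ndarray, y=None, *, zts=None, gene_ids=None):
        if isinstance(X, TimeCourseMatrix):
            values, zts_, gene_ids_ = X.values, X.zts, X.gene_ids
        else:
            if zts is None:
                raise ValueError("zts must be provided when X is a bare array")
            values = np.asarray(X, dtype=float)
            zts_ = np.asarray(zts, dtype=float)
            gene_ids_ = (
                list(gene_ids)
                if gene_ids is not None
                else [f"g{i}" for i in range(values.shape[0])]
            )
        grid = build_reference_grid(
            zts_, self.period_window, self.period_step, self.lag_step
        )
        self.grid_ = grid
        self.n_references_ = len(grid)
        self.results_ = _scan(values, zts_, gene_ids_, grid, self.alpha)
        return self

    def fit_predict(self, X, y=None, **kw) -> np.ndarray:
        """Fit and return the boolean rhythmic flags."""
        self.fit(X, y, **kw)
        return self.results_["rhythmic"].to_numpy()


def _scan(
    values: np.ndarray,
    zts: np.ndarray,
    gene_ids: Sequence[str],
    grid: list[ReferenceWaveform],
    alpha: float,
) -> pd.DataFrame:
    n_genes, n = values.shape
    i, j = np.triu_indices(n, k=1)
    # reference pair signs: refs x pairs
    ranks = np.array([w.group_ranks for w in grid])
    ref_signs = np.sign(ranks[:, j] - ranks[:, i]).astype(np.int64)
    data_signs = np.sign(values[:, j] - values[:, i]).astype(np.int64)
    S = data_signs @ ref_signs.T  # genes x refs

    # One exact null from the replicate tie structure (samples sharing a zt),
    # shared by every reference, so p-values are comparable across references
    # with different cosine tie patterns. Slightly conservative for references
    # whose own ties shrink the achievable |S|.
    null = exact_jt_null(_dense_ranks(zts))
    P = null.two_sided_p(S)

    bonf = len(grid)
    min_p = P.min(axis=1)
    p_adj = np.minimum(1.0, min_p * bonf)
    constant = np.all(values == values[:, [0]], axis=1)
    p_adj[constant] = 1.0

    periods = np.array([w.period for w in grid])
    lags = np.array([w.lag for w in grid])
    best_period = np.full(n_genes, np.nan)
    best_lag = np.full(n_genes, np.nan)
    tau = np.full(n_genes, np.nan)
    amp = np.full(n_genes, np.nan)
    rel_amp = np.full(n_genes, np.nan)
    max_expr = values.max(axis=1)
    # max |S| per reference (pairs with distinct reference ranks)
    ref_max_s = np.sum(ref_signs != 0, axis=1)

    for g in range(n_genes):
        if constant[g]:
            continue
        cand = np.flatnonzero(P[g] == min_p[g])
        # prefer positively correlated references (peak-phase reporting), then
        # smaller period, then smaller lag; grid is already ordered that way
        pos = cand[S[g, cand] > 0]
        pick = int(pos[0]) if len(pos) else int(cand[0])
        best_period[g] = periods[pick]
        best_lag[g] = lags[pick]
        tau[g] = S[g, pick] / ref_max_s[pick] if ref_max_s[pick] else 0.0
        a, m, r = estimate_amplitude(values[g], zts, periods[pick], lags[pick])
        amp[g], rel_amp[g] = a, r

    q = multipletests(p_adj, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "p_adj": p_adj,
            "q": q,
            "period": best_period,
            "lag": best_lag,
            "tau": tau,
            "amp": amp,
            "max_expr": max_expr,
            "rel_amp": rel_amp,
            "rhythmic": p_adj <= alpha,
        }
    )


def jtk_scan(
    matrix: TimeCourseMatrix,
    grid: list[ReferenceWaveform] | None = None,
    alpha: float = 0.05,
    period_window: tuple[float, float] = (18.0, 30.0),
    period_step: float | None = None,
    lag_step: float | None = None,
) -> pd.DataFrame:
    """Run the rhythm scan on a :class:`TimeCourseMatrix`; thin wrapper over
    :class:`JTKCycle` (or a caller-supplied reference grid)."""
    if grid is not None:
        if not grid:
            raise ValueError("empty reference grid")
        return _scan(matrix.values, matrix.zts, matrix.gene_ids, grid, alpha)
    est = JTKCycle(
        period_window=period_window,
        period_step=period_step,
        lag_step=lag_step,
        alpha=alpha,
    )
    est.fit(matrix)
    return est.results_
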