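"""Cross-condition comparison of rhythmic genes.

Covers the shared/only classification of rhythmic genes between two
conditions (e.g. conventionally raised vs germ-free), the two-level
attribution funnel assigning rhythms to the microbiota (group A), microbiota
and HDAC3 jointly (group B) or HDAC3 alone (group C), signed phase/amplitude
differences, amplitude t-tests, K-means temporal clustering with elbow
selection of K, mean-level up/down classification between genotypes, and the
phase x amplitude-rank polar summary.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .io_formats import TimeCourseMatrix
from .jtk import REL_AMP_RANKS, rank_rel_amp

__all__ = [
    "rhythmic_set",
    "classify_pair",
    "funnel_groups",
    "phase_amp_diff",
    "amplitude_ttest",
    "ElbowKMeans",
    "elbow_kmeans",
    "updown_split",
    "phase_polar_summary",
]


def rhythmic_set(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Gene ids flagged rhythmic at Bonferroni-adjusted ``alpha``."""
    mask = results["p_adj"] <= alpha
    return set(results.loc[mask, "gene_id"])


def _check_universe(*tables: pd.DataFrame) -> list[str]:
    universes = [set(t["gene_id"]) for t in tables]
    ref = universes[0]
    for u in universes[1:]:
        if u != ref:
            missing = sorted((ref - u) | (u - ref))
            raise ValueError(
                f"gene universes differ between result tables; "
                f"{len(missing)} discrepant ids, e.g. {missing[:10]}"
            )
    # preserve input order of the first table
    return list(tables[0]["gene_id"])


def classify_pair(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    alpha: float = 0.05,
    labels: tuple[str, str, str, str] = ("onlyA", "shared", "onlyB", "neither"),
) -> pd.DataFrame:
    """Label every gene of a common universe by rhythmicity in two conditions.

    ``shared`` = rhythmic in both at ``alpha``; ``onlyA``/``onlyB`` = rhythmic
    in exactly one; ``neither`` otherwise. Custom labels let callers emit the
    condition-pair naming used downstream (e.g. CVonly / CVshareGF / GFonly).
    """
    genes = _check_universe(res_a, res_b)
    only_a, shared, only_b, neither = labels
    ra, rb = rhythmic_set(res_a, alpha), rhythmic_set(res_b, alpha)
    lab = []
    for g in genes:
        in_a, in_b = g in ra, g in rb
        if in_a and in_b:
            lab.append(shared)
        elif in_a:
            lab.append(only_a)
        elif in_b:
            lab.append(only_b)
        else:
            lab.append(neither)
    return pd.DataFrame({"gene_id": genes, "pair_label": lab})


def funnel_groups(
    cv: pd.DataFrame,
    gf: pd.DataFrame,
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-level attribution funnel over four rhythm-result tables.

    First level: CVonly = rhythmic(cv) \\ rhythmic(gf) (microbiota-dependent),
    WTonly = rhythmic(wt) \\ rhythmic(ko) (HDAC3-dependent). Second level:
    A = CVonly \\ WTonly, B = CVonly & WTonly, C = WTonly \\ CVonly; all other
    genes get "none". ``cv`` and ``wt`` may be the same table (in the source
    study the conventionally raised wild-type dataset serves both
    comparisons).
    """
    genes = _check_universe(cv, gf, wt, ko)
    cv_only = rhythmic_set(cv, alpha) - rhythmic_set(gf, alpha)
    wt_only = rhythmic_set(wt, alpha) - rhythmic_set(ko, alpha)
    group = []
    for g in genes:
        in_cv, in_wt = g in cv_only, g in wt_only
        if in_cv and in_wt:
            group.append("B")
        elif in_cv:
            group.append("A")
        elif in_wt:
            group.append("C")
        else:
            group.append("none")
    out = pd.DataFrame({"gene_id": genes, "funnel_group": group})
    # hard invariant: A, B, C pairwise disjoint by construction; assert anyway
    counts = out["funnel_group"].value_counts()
    assert counts.reindex(["A", "B", "C"]).fillna(0).sum() <= len(genes)
    return out


def phase_amp_diff(
    res1: pd.DataFrame, res2: pd.DataFrame
) -> pd.DataFrame:
    """Signed phase and amplitude differences (condition 1 minus condition 2).

    phase_diff = lag1 - lag2 wrapped into (-period/2, period/2] using the mean
    of the two fitted periods; negative = advanced (earlier peak) in condition
    1. Genes without a defined lag in either table are excluded (logged via a
    warning).
    """
    a = res1.set_index("gene_id")
    b = res2.set_index("gene_id")
    common = [g for g in a.index if g in b.index]
    rows = []
    dropped = 0
    for g in common:
        lag1, lag2 = a.at[g, "lag"], b.at[g, "lag"]
        if np.isnan(lag1) or np.isnan(lag2):
            dropped += 1
            continue
        period = 0.5 * (a.at[g, "period"] + b.at[g, "period"])
        d = lag1 - lag2
        # wrap into (-period/2, period/2]
        d = d - period * np.floor(d / period + 0.5)
        if d == -period / 2:
            d = period / 2
        rows.append(
            {
                "gene_id": g,
                "phase_diff": d,
                "amp_diff": a.at[g, "amp"] - b.at[g, "amp"],
                "period": period,
            }
        )
    if dropped:
        warnings.warn(f"phase_amp_diff: excluded {dropped} genes lacking a defined lag")
    return pd.DataFrame(rows, columns=["gene_id", "phase_diff", "amp_diff", "period"])


def amplitude_ttest(
    rel_amps_1: Sequence[float],
    rel_amps_2: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided Student's t-test (unpaired, equal-variance by default) on the
    relative amplitudes of a gene group in two conditions."""
    x = np.asarray(rel_amps_1, dtype=float)
    y = np.asarray(rel_amps_2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        warnings.warn("amplitude_ttest: zero variance in both groups; p set to 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


class ElbowKMeans(ClusterMixin, BaseEstimator):
    """K-means over z-scored temporal profiles with elbow selection of K.

    The within-cluster sum of squares WSS(k) is computed for k = 1..k_max with
    fixed-seed multi-restart K-means; the selected K maximizes the second
    difference of log WSS (relative curvature) over interior k. ``k`` may be
    forced via ``k_override``.

    Fitted attributes: ``k_``, ``labels_`` (1-based cluster per gene),
    ``wss_`` (index k), ``cluster_profiles_`` (mean z-scored profile per
    cluster) and ``gene_ids_``.
    """

    def __init__(
        self,
        k_max: int = 10,
        random_state: int = 0,
        n_init: int = 10,
        k_override: int | None = None,
    ):
        self.k_max = k_max
        self.random_state = random_state
        self.n_init = n_init
        self.k_override = k_override

    def fit(self, X: TimeCourseMatrix | pd.DataFrame | np.ndarray, y=None):
        if isinstance(X, TimeCourseMatrix):
            profiles = X.timepoint_means()
        elif isinstance(X, pd.DataFrame):
            profiles = X
        else:
            profiles = pd.DataFrame(np.asarray(X, dtype=float))
        if self.k_max < 3:
            raise ValueError("k_max must be >= 3")
        if len(profiles) < self.k_max:
            raise ValueError(
                f"{len(profiles)} genes is fewer than k_max={self.k_max}"
            )
        Z = _zscore_rows(profiles.to_numpy())
        wss = {}
        models = {}
        for k in range(1, self.k_max + 1):
            km = KMeans(
                n_clusters=k, n_init=self.n_init, random_state=self.random_state
            ).fit(Z)
            wss[k] = float(km.inertia_)
            models[k] = km
        self.wss_ = pd.Series(wss, name="wss")
        if self.k_override is not None:
            k_sel = int(self.k_override)
        else:
            # elbow = max second difference of log WSS (relative curvature);
            # the raw-WSS second difference is dominated by the initial drop
            # and misses elbows at larger k
            lw = {k: np.log(max(wss[k], 1e-300)) for k in wss}
            second = {
                k: lw[k - 1] - 2 * lw[k] + lw[k + 1] for k in range(2, self.k_max)
            }
            k_sel = max(second, key=second.get)
        self.k_ = k_sel
        km = models[k_sel]
        self.labels_ = km.labels_ + 1
        self.gene_ids_ = list(profiles.index)
        self.cluster_profiles_ = pd.DataFrame(
            km.cluster_centers_,
            index=[c + 1 for c in range(k_sel)],
            columns=profiles.columns,
        )
        return self

    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids_, "cluster": self.labels_})


def elbow_kmeans(
    matrix: TimeCourseMatrix | pd.DataFrame,
    k_max: int = 10,
    seed: int = 0,
    k_override: int | None = None,
) -> ElbowKMeans:
    """Fit :class:`ElbowKMeans` on (replicate-averaged, z-scored) profiles."""
    return ElbowKMeans(k_max=k_max, random_state=seed, k_override=k_override).fit(
        matrix
    )


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def updown_split(
    matrix_wt: TimeCourseMatrix,
    matrix_ko: TimeCourseMatrix,
    gene_list: Sequence[str],
) -> dict[str, list[str]]:
    """Split ``gene_list`` by mean abundance across all timepoints/replicates.

    "upregulated" = higher mean in the knockout than in the wild type;
    ties go to "downregulated" with a warning.
    """
    wt = matrix_wt.restrict(gene_list)
    ko = matrix_ko.restrict(gene_list)
    wt_mean = wt.values.mean(axis=1)
    ko_mean = ko.values.mean(axis=1)
    ties = [g for g, w, k in zip(gene_list, wt_mean, ko_mean) if w == k]
    if ties:
        warnings.warn(
            f"updown_split: {len(ties)} exact mean ties assigned 'downregulated'"
        )
    up = [g for g, w, k in zip(gene_list, wt_mean, ko_mean) if k > w]
    down = [g for g in gene_list if g not in set(up)]
    return {"upregulated": up, "downregulated": down}


def phase_polar_summary(
    results: pd.DataFrame,
    rank_function: Callable[[float], str] = rank_rel_amp,
    lag_bin_width: float | None = None,
    period: float = 24.0,
) -> pd.DataFrame:
    """Histogram of rhythmic genes over lag bins x relative-amplitude ranks.

    One lag bin per sampling interval (inferred from the smallest spacing of
    the distinct lags present unless given); the grand total equals the number
    of rhythmic genes with defined lag and rel_amp.
    """
    rhythmic = results[results["rhythmic"]].dropna(subset=["lag", "rel_amp"])
    if lag_bin_width is None:
        lags = np.sort(rhythmic["lag"].unique())
        diffs = np.diff(lags)
        lag_bin_width = float(np.min(diffs[diffs > 0])) if len(diffs) else period
    n_bins = int(np.ceil(period / lag_bin_width))
    bin_edges = [i * lag_bin_width for i in range(n_bins)]
    out = pd.DataFrame(
        0, index=pd.Index(bin_edges, name="lag_bin"), columns=list(REL_AMP_RANKS)
    )
    for _, row in rhythmic.iterrows():
        b = bin_edges[int(np.floor((row["lag"] % period) / lag_bin_width))]
        out.loc[b, rank_function(row["rel_amp"])] += 1
    return out
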