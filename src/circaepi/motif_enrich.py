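"""Transcription-factor motif enrichment in gene promoters.

Motif sites (precomputed BED, or produced by the built-in PWM scanner at a
likelihood-ratio threshold) are mapped to promoter windows spanning -900..+100
of each TSS; per motif a 2x2 table is built from the four counts x1 (list
genes with the motif), x2 (list genes without), z1 (universe genes with) and
z2 (universe genes without), tested by Fisher's exact test with
Benjamini-Hochberg FDR across motifs.

The table actually tested uses background = universe minus the list (standard
practice); x1, x2, z1, z2 are reported verbatim alongside, where z counts run
over the whole universe and therefore include the list genes.

The PWM scanner computes, at every placement on both strands, the likelihood
ratio prod_i p_motif(base_i) / p_background(base_i) against a 0th-order
background (uniform by default) and reports placements with LR above the
threshold (default 500). N bases force LR = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chip_promoter import PromoterWindow, count_overlaps, make_promoter_windows
from .io_formats import GeneModel, IntervalSet

__all__ = [
    "PWM",
    "motif_promoter_windows",
    "genes_with_motif",
    "fisher_enrichment",
    "uniquely_enriched",
    "pwm_scan",
    "read_meme_pwms",
    "DEFAULT_LR_THRESHOLD",
]

DEFAULT_LR_THRESHOLD = 500.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """A position weight matrix of base probabilities plus a background.

    ``matrix`` is width x 4 (A, C, G, T order), each row summing to 1;
    ``background`` sums to 1. Zero entries are permitted only if a pseudocount
    was applied upstream (use :meth:`from_counts`).
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if np.any(self.matrix < 0) or np.any(self.background < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("PWM background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 1e-4,
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        m = c / c.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(motif_id, m, bg)


def motif_promoter_windows(
    models: Sequence[GeneModel],
    upstream: int = 900,
    downstream: int = 100,
) -> list[PromoterWindow]:
    """Promoter windows spanning -900..+100 of each TSS (strand-reflected,
    clipped at 0 with a warning)."""
    return make_promoter_windows(models, upstream=upstream, downstream=downstream)


def genes_with_motif(
    sites: IntervalSet, windows: Sequence[PromoterWindow]
) -> dict[str, set[str]]:
    """Map motif id -> set of gene ids whose window is hit by >= 1 site.

    Site records must carry the motif id in the BED name field; a site
    without one is a hard error. A site spanning two windows hits both genes
    (any-overlap rule).
    """
    df = sites.df
    if df["name"].isna().any():
        bad = int(df.index[df["name"].isna()][0])
        raise ValueError(f"motif site record {bad} has no motif id in the name field")
    out: dict[str, set[str]] = {}
    for motif_id, sub in df.groupby("name", sort=False):
        counts = count_overlaps(IntervalSet(sub), windows)
        out[str(motif_id)] = {
            w.gene_id for w, c in zip(windows, counts) if c > 0
        }
    return out


def fisher_enrichment(
    list_genes: Iterable[str],
    universe_genes: Iterable[str],
    motif_gene_sets: Mapping[str, Iterable[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-motif Fisher's exact tests of a gene list against the universe.

    Returns one row per motif with the verbatim counts x1 (list genes with
    motif), x2 (list without), z1 (universe with), z2 (universe without), the
    odds ratio of the tested table (list vs universe-minus-list), the exact p
    (two-sided by default; ``alternative="greater"`` for enrichment-only) and
    the Benjamini-Hochberg FDR across motifs.
    """
    lst = set(list_genes)
    uni = set(universe_genes)
    if not lst or not uni:
        raise ValueError("gene list and universe must be non-empty")
    if not lst <= uni:
        raise ValueError("gene list is not a subset of the universe")
    rows = []
    for motif_id in motif_gene_sets:
        hits = set(motif_gene_sets[motif_id]) & uni
        x1 = len(hits & lst)
        x2 = len(lst) - x1
        z1 = len(hits)
        z2 = len(uni) - z1
        bg_with = z1 - x1
        bg_without = (len(uni) - len(lst)) - bg_with
        table = np.array([[x1, x2], [bg_with, bg_without]])
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append(
            {
                "motif_id": motif_id,
                "x1": x1,
                "x2": x2,
                "z1": z1,
                "z2": z2,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def uniquely_enriched(
    enrich_a: pd.DataFrame,
    enrich_b: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Motifs significant (fdr < threshold) in exactly one of two clusters."""
    sig_a = set(enrich_a.loc[enrich_a["fdr"] < fdr_threshold, "motif_id"])
    sig_b = set(enrich_b.loc[enrich_b["fdr"] < fdr_threshold, "motif_id"])
    return {
        "only_a": sorted(sig_a - sig_b),
        "only_b": sorted(sig_b - sig_a),
    }


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N etc.) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        mask = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
        arr[mask] = idx
    return arr


def pwm_scan(
    sequences: Iterable,
    pwm: PWM,
    lr_threshold: float = DEFAULT_LR_THRESHOLD,
) -> IntervalSet:
    """Scan sequences on both strands for PWM placements with LR > threshold.

    ``sequences`` yields Biopython SeqRecords or (id, sequence) pairs.
    Sites are emitted as 0-based motif-width intervals with name = motif id,
    score = natural-log likelihood ratio and the strand of the match; a '-'
    strand site's coordinates are those of the matched segment on the forward
    sequence. Sequences shorter than the motif yield no sites.
    """
    w = pwm.width
    with np.errstate(divide="ignore"):
        logm = np.log(pwm.matrix)  # -inf where probability 0
        logb = np.log(pwm.background)
    # pad a 5th column for N: -inf in motif (forces LR=0), 0 contribution in bg
    logm5 = np.hstack([logm - logb[None, :], np.full((w, 1), -np.inf)])
    # reverse-complement score matrix: position w-1-i, complemented base
    rc = logm5[::-1, [3, 2, 1, 0, 4]]
    log_thr = np.log(lr_threshold)
    records = []
    for item in sequences:
        if hasattr(item, "seq"):
            seq_id, seq = str(item.id), str(item.seq)
        else:
            seq_id, seq = str(item[0]), str(item[1])
        n = len(seq)
        if n < w:
            continue
        enc = _encode(seq)
        idx = np.lib.stride_tricks.sliding_window_view(enc, w)
        pos = np.arange(w)
        fwd = logm5[pos, idx].sum(axis=1)
        rev = rc[pos, idx].sum(axis=1)
        for start in np.flatnonzero(fwd > log_thr):
            records.append(
                (seq_id, int(start), int(start) + w, pwm.motif_id, float(fwd[start]), "+")
            )
        for start in np.flatnonzero(rev > log_thr):
            records.append(
                (seq_id, int(start), int(start) + w, pwm.motif_id, float(rev[start]), "-")
            )
    if not records:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"]))
    return IntervalSet.from_records(records)


def read_meme_pwms(path: str | Path) -> list[PWM]:
    """Read MEME minimal-format motifs into :class:`PWM` objects (background
    taken from the file's background line when present, else uniform)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    bg = getattr(parsed, "background", None)
    background = (
        np.array([bg[b] for b in "ACGT"]) if bg else np.full(4, 0.25)
    )
    for m in parsed:
        pwm = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in "ACGT"])
        # renormalize tiny float drift from the parser
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
        out.append(PWM(m.name or m.base_id, pwm, background / background.sum()))
    return out
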