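"""Fully labeled synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
cosine-shaped 24-h rhythms with condition-specific gene blocks, amplitude
attenuation and phase shifts between conditions, arrhythmic background genes,
rhythmic promoter read pileups, and motif-site maps with planted enrichment —
and return ground-truth tables sufficient to score detection, classification,
phase recovery and enrichment without re-deriving truth.

Expression model for a rhythmic gene g in condition c:

    y(t) = M_g * (1 + a_gc * cos(2*pi*(t - phi_gc)/period)) * noise,  clipped at 0

with a_gc set so the noiseless relative amplitude (cosinor amplitude divided
by series maximum) equals the block's target: a = r/(1 - r). Baselines M_g
are log-normal (FPKM-like right skew); the default noise is mean-one
log-normal multiplicative with CV 0.2 (a Gaussian option with SD = cv x level
is available for analytic checks). Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GeneSetCollection, IntervalSet, SampleMeta, TimeCourseMatrix

__all__ = [
    "BlockSpec",
    "SimSpec",
    "simulate_expression",
    "two_condition_spec",
    "funnel_spec",
    "simulate_gene_models",
    "ChipSimSpec",
    "simulate_chip",
    "simulate_motifs",
    "simulate_gene_sets",
]

DEFAULT_ZTS = tuple(float(z) for z in range(0, 24, 3))
DEFAULT_REL_AMP = 0.3
DEFAULT_NOISE_CV = 0.2


@dataclass(frozen=True)
class BlockSpec:
    """A block of genes sharing rhythmicity structure across conditions.

    ``rhythmic_in`` lists the conditions where the block oscillates;
    ``rel_amp`` may be a scalar or a per-condition mapping of noiseless
    relative-amplitude targets; ``phase_shift`` maps condition -> hours added
    to the gene's base peak phase (e.g. a +3 h delay in one condition).
    """

    name: str
    n_genes: int
    rhythmic_in: tuple[str, ...] = ()
    rel_amp: float | Mapping[str, float] = DEFAULT_REL_AMP
    phase_shift: Mapping[str, float] = field(default_factory=dict)

    def rel_amp_for(self, condition: str) -> float:
        if isinstance(self.rel_amp, Mapping):
            return float(self.rel_amp[condition])
        return float(self.rel_amp)


@dataclass(frozen=True)
class SimSpec:
    """Study design for the expression simulator; ``seed`` is mandatory."""

    conditions: tuple[str, ...]
    blocks: tuple[BlockSpec, ...]
    seed: int
    zts: tuple[float, ...] = DEFAULT_ZTS
    replicates: int = 2
    period: float = 24.0
    noise_cv: float = DEFAULT_NOISE_CV
    noise_model: str = "lognormal"  # or "gaussian"
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    phases_on_grid: bool = True

    def __post_init__(self) -> None:
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for b in self.blocks:
            for c in b.rhythmic_in:
                if c not in self.conditions:
                    raise ValueError(f"block {b.name!r} rhythmic in unknown condition {c!r}")
                r = b.rel_amp_for(c)
                if not (0.0 < r < 1.0):
                    raise ValueError(
                        f"block {b.name!r}: infeasible rel_amp target {r} (need 0 < r < 1)"
                    )

    @property
    def n_genes(self) -> int:
        return sum(b.n_genes for b in self.blocks)


def two_condition_spec(
    n_shared: int = 100,
    n_a_only: int = 50,
    n_b_only: int = 50,
    n_arrhythmic: int = 300,
    conditions: tuple[str, str] = ("CV", "GF"),
    rel_amp: float = DEFAULT_REL_AMP,
    shared_rel_amp_b: float | None = None,
    phase_shift_b: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SimSpec:
    """Two-condition design with shared/only/arrhythmic blocks.

    ``shared_rel_amp_b`` attenuates the shared block's amplitude in the second
    condition (germ-free-style dampening); ``phase_shift_b`` delays (positive)
    the shared block's peak in the second condition by that many hours.
    """
    a, b = conditions
    shared_amp: float | dict = rel_amp
    if shared_rel_amp_b is not None:
        shared_amp = {a: rel_amp, b: shared_rel_amp_b}
    blocks = (
        BlockSpec(
            "shared",
            n_shared,
            (a, b),
            shared_amp,
            {b: phase_shift_b} if phase_shift_b else {},
        ),
        BlockSpec(f"{a}_only", n_a_only, (a,), rel_amp),
        BlockSpec(f"{b}_only", n_b_only, (b,), rel_amp),
        BlockSpec("arrhythmic", n_arrhythmic, ()),
    )
    return SimSpec(conditions=(a, b), blocks=blocks, seed=seed, **kwargs)


def funnel_spec(
    n_a: int = 100,
    n_b: int = 100,
    n_c: int = 100,
    n_null: int = 700,
    rel_amp: float = DEFAULT_REL_AMP,
    seed: int = 0,
    **kwargs,
) -> SimSpec:
    """Four-condition benchmark for the microbiota/HDAC3 attribution funnel.

    Group A (microbiota-driven): rhythmic in CV, WT and KO but not GF.
    Group B (microbiota + HDAC3): rhythmic in CV and WT only.
    Group C (HDAC3-driven): rhythmic in CV, GF and WT but not KO.
    Nulls are arrhythmic everywhere.
    """
    conditions = ("CV", "GF", "WT", "KO")
    blocks = (
        BlockSpec("A", n_a, ("CV", "WT", "KO"), rel_amp),
        BlockSpec("B", n_b, ("CV", "WT"), rel_amp),
        BlockSpec("C", n_c, ("CV", "GF", "WT"), rel_amp),
        BlockSpec("none", n_null, ()),
    )
    return SimSpec(conditions=conditions, blocks=blocks, seed=seed, **kwargs)


def simulate_expression(
    spec: SimSpec,
) -> tuple[dict[str, TimeCourseMatrix], pd.DataFrame]:
    """Generate one :class:`TimeCourseMatrix` per condition plus a truth table.

    The truth table has one row per gene with its block, base peak phase, and
    per-condition columns ``rhythmic_<c>``, ``lag_<c>`` and ``rel_amp_<c>``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    baselines = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, n)
    if spec.phases_on_grid:
        base_phase = rng.choice(np.asarray(spec.zts), n)
    else:
        base_phase = rng.uniform(0, spec.period, n)

    sample_meta = [
        SampleMeta(f"ZT{zt:g}_r{r + 1}", float(zt), r + 1, "")
        for zt in spec.zts
        for r in range(spec.replicates)
    ]
    tvec = np.array([s.zt for s in sample_meta])

    truth = pd.DataFrame({"gene_id": gene_ids, "base_phase": base_phase})
    blocks_per_gene = np.repeat(
        [b.name for b in spec.blocks], [b.n_genes for b in spec.blocks]
    )
    truth["block"] = blocks_per_gene

    block_of = {}
    start = 0
    for b in spec.blocks:
        for i in range(start, start + b.n_genes):
            block_of[i] = b
        start += b.n_genes

    matrices: dict[str, TimeCourseMatrix] = {}
    for cond in spec.conditions:
        signal = np.tile(baselines[:, None], (1, len(tvec)))
        lag_col = np.full(n, np.nan)
        rel_col = np.zeros(n)
        rhythmic_col = np.zeros(n, dtype=bool)
        for i in range(n):
            b = block_of[i]
            if cond in b.rhythmic_in:
                r = b.rel_amp_for(cond)
                a = r / (1.0 - r)
                phi = (base_phase[i] + b.phase_shift.get(cond, 0.0)) % spec.period
                signal[i] = baselines[i] * (
                    1.0 + a * np.cos(2.0 * np.pi * (tvec - phi) / spec.period)
                )
                lag_col[i] = phi
                rel_col[i] = r
                rhythmic_col[i] = True
        if spec.noise_model == "lognormal":
            sigma = np.sqrt(np.log1p(spec.noise_cv**2))
            noise = rng.lognormal(-sigma**2 / 2.0, sigma, signal.shape)
            values = signal * noise
        else:
            values = signal + rng.normal(0.0, spec.noise_cv, signal.shape) * signal
        values = np.clip(values, 0.0, None)
        samples = [
            SampleMeta(f"{cond}_{s.sample_id}", s.zt, s.replicate, cond)
            for s in sample_meta
        ]
        matrices[cond] = TimeCourseMatrix(gene_ids, values, samples)
        truth[f"rhythmic_{cond}"] = rhythmic_col
        truth[f"lag_{cond}"] = lag_col
        truth[f"rel_amp_{cond}"] = rel_col
    return matrices, truth


# ---------------------------------------------------------------------------
# gene models and promoter reads
# ---------------------------------------------------------------------------


def simulate_gene_models(
    n_genes: int,
    seed: int = 0,
    chrom: str = "chr1",
    spacing: int = 6000,
    jitter: int = 500,
    offset: int = 5000,
    gene_ids: Sequence[str] | None = None,
) -> list[GeneModel]:
    """Evenly spaced TSSs with jitter and random strands; windows built from
    the default spacing never overlap, so per-gene truth stays clean."""
    rng = np.random.default_rng(seed)
    ids = list(gene_ids) if gene_ids is not None else [f"g{i:05d}" for i in range(n_genes)]
    if len(ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    models = []
    for i, gid in enumerate(ids):
        tss = offset + i * spacing + int(rng.integers(-jitter, jitter + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, chrom, strand, tss))
    return models


@dataclass(frozen=True)
class ChipSimSpec:
    """Design for the promoter read-pileup simulator.

    Rhythmic-acetylation genes get per-timepoint Poisson read counts whose
    means follow a cosine with relative amplitude (max - min)/max equal to
    ``rhythmic_rel_amp``; other genes a constant mean. Background reads are
    scattered uniformly genome-wide.
    """

    seed: int
    zts: tuple[float, ...] = DEFAULT_ZTS
    base_mean: float = 200.0
    rhythmic_rel_amp: float = 0.7
    read_length: int = 50
    background_reads: int = 2000
    period: float = 24.0


def simulate_chip(
    spec: ChipSimSpec,
    gene_models: Sequence[GeneModel],
    rhythmic_genes: Iterable[str] = (),
    phase_by_gene: Mapping[str, float] | None = None,
) -> tuple[dict[float, IntervalSet], pd.Series]:
    """Per-timepoint promoter read sets plus the truth relative amplitudes.

    Truth rel_amp is computed from the Poisson means, i.e. (max - min)/max of
    the noiseless mean track over the sampled timepoints.
    """
    from .chip_promoter import make_promoter_windows

    rng = np.random.default_rng(spec.seed)
    windows = make_promoter_windows(gene_models)
    rhythmic = set(rhythmic_genes)
    phase_by_gene = dict(phase_by_gene or {})
    genome_end = max(w.end for w in windows) + 10000
    r = spec.rhythmic_rel_amp
    b = r / (2.0 - r)  # cosine mean m0*(1 + b*cos) has (max-min)/max = 2b/(1+b)

    zts = np.asarray(spec.zts)
    mean_tracks: dict[str, np.ndarray] = {}
    for w in windows:
        if w.gene_id in rhythmic:
            phi = phase_by_gene.get(w.gene_id, float(rng.choice(zts)))
            mean_tracks[w.gene_id] = spec.base_mean * (
                1.0 + b * np.cos(2.0 * np.pi * (zts - phi) / spec.period)
            )
        else:
            mean_tracks[w.gene_id] = np.full(len(zts), spec.base_mean)

    reads_by_zt: dict[float, IntervalSet] = {}
    for t_idx, zt in enumerate(zts):
        rows = []
        for w in windows:
            lam = mean_tracks[w.gene_id][t_idx]
            count = int(rng.poisson(lam))
            if count:
                hi = max(w.start + 1, w.end - spec.read_length)
                starts = rng.integers(w.start, hi, count)
                for s in starts:
                    rows.append((w.chrom, int(s), int(s) + spec.read_length))
        bg_starts = rng.integers(0, genome_end, spec.background_reads)
        chrom = windows[0].chrom
        for s in bg_starts:
            rows.append((chrom, int(s), int(s) + spec.read_length))
        reads_by_zt[float(zt)] = IntervalSet.from_records(rows)

    truth = pd.Series(
        {
            g: (trk.max() - trk.min()) / trk.max() if trk.max() > 0 else 0.0
            for g, trk in mean_tracks.items()
        },
        name="true_rel_amp",
    )
    return reads_by_zt, truth


# ---------------------------------------------------------------------------
# motif sites and gene sets
# ---------------------------------------------------------------------------


def simulate_motifs(
    universe_models: Sequence[GeneModel],
    planted_list: Iterable[str],
    planted_motif: str = "motif_planted",
    n_null_motifs: int = 99,
    rate_in: float = 0.8,
    rate_background: float = 0.1,
    null_rate: float = 0.1,
    site_length: int = 10,
    seed: int = 0,
) -> tuple[IntervalSet, dict]:
    """Motif-site map with one planted enriched motif among null motifs.

    The planted motif's sites appear in the -900..+100 promoter windows of
    ``planted_list`` genes with probability ``rate_in`` and of background
    genes with ``rate_background``; null motifs at ``null_rate`` everywhere.
    """
    from .motif_enrich import motif_promoter_windows

    rng = np.random.default_rng(seed)
    windows = motif_promoter_windows(universe_models)
    planted = set(planted_list)
    rows = []

    def place(window, motif_id):
        hi = max(window.start + 1, window.end - site_length)
        s = int(rng.integers(window.start, hi))
        rows.append((window.chrom, s, s + site_length, motif_id, 0.0, "+"))

    for w in windows:
        p = rate_in if w.gene_id in planted else rate_background
        if rng.random() < p:
            place(w, planted_motif)
    null_ids = [f"motif_null{i:03d}" for i in range(n_null_motifs)]
    for motif_id in null_ids:
        for w in windows:
            if rng.random() < null_rate:
                place(w, motif_id)
    truth = {
        "planted_motif": planted_motif,
        "null_motifs": null_ids,
        "planted_list": sorted(planted),
    }
    return IntervalSet.from_records(rows), truth


def simulate_gene_sets(
    universe: Sequence[str],
    n_blocks: int = 3,
    terms_per_block: int = 4,
    genes_per_term: int = 50,
    within_overlap: float = 0.8,
    across_overlap: float = 0.05,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Term collection with planted block structure for kappa-network tests.

    Terms within a block share ``within_overlap`` of a block core; terms in
    different blocks share only ``across_overlap`` by random leakage. Returns
    the collection and the term -> block truth labels.
    """
    rng = np.random.default_rng(seed)
    uni = list(universe)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    labels: dict[str, int] = {}
    n_core = int(round(genes_per_term * within_overlap))
    for blk in range(n_blocks):
        core = list(rng.choice(uni, n_core, replace=False))
        for t in range(terms_per_block):
            term = f"T{blk}_{t}"
            extra_n = genes_per_term - n_core
            pool = [g for g in uni if g not in core]
            extra = list(rng.choice(pool, extra_n, replace=False))
            leak_n = int(round(genes_per_term * across_overlap))
            members = core + extra
            if leak_n:
                members = members[: genes_per_term - leak_n] + list(
                    rng.choice(pool, leak_n, replace=False)
                )
            # dedupe preserving order
            seen: dict[str, None] = {}
            for g in members:
                seen.setdefault(g, None)
            sets[term] = (f"block {blk}", tuple(seen))
            labels[term] = blk
    return GeneSetCollection(sets, universe=uni), labels
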