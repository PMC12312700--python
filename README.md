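# circaepi

Circadian rhythm detection and microbiota/HDAC3 attribution analysis for
intestinal-epithelial transcriptome and promoter-acetylation data.

## What this package is for

The gut epithelium runs a daily program: metabolic and immune genes peak at
night when mice feed, protein-synthesis and cell-cycle genes peak during the
day. Two regulators shape these rhythms — the gut microbiota and the histone
deacetylase HDAC3. Dissecting who drives which rhythm requires a complete
analysis chain: detect rhythmic transcripts per condition (conventionally
raised CV, germ-free GF, *Hdac3*-wild-type WT, intestinal *Hdac3*-knockout
KO), compare amplitudes and phases across conditions, attribute each rhythm
to the microbiota and/or HDAC3, quantify promoter H3K9ac oscillation, and ask
which transcription-factor motifs mark the affected promoters.

`circaepi` implements that chain as a tested, deterministic library + CLI for
computational biologists, starting from an FPKM matrix, BED read/site files,
gene models and GMT gene sets. A first-class synthetic-data module generates
fully labeled inputs for every stage, so the whole pipeline can be exercised
and scored against ground truth.

## The statistics at the core

**Rhythm detection.** For each gene the scan computes Kendall's
S = Σ_{i<j} sgn(x_j − x_i)·sgn(r_j − r_i) between the expression values and
the ranks r of a cosine reference cos(2π(t − φ)/P), over a grid of periods
P ∈ [18, 30] h and peak lags φ (both stepped at the sampling interval).
Replicates and cosine symmetry create tie-groups in the reference; under a
uniformly random ordering of the data the statistic follows the exact
Jonckheere–Terpstra null, whose probability mass function the package
computes by Gaussian-multinomial generating-function convolution (verified
against full n! enumeration). Per gene, p = min over references of the
two-sided exact tail, Bonferroni-multiplied by the number of rank-distinct
references; Benjamini–Hochberg q across genes. Amplitude is a least-squares
cosinor fit at the chosen (P, φ); relative amplitude = amplitude / max
expression, binned into the 5 ranks <0.1, 0.1-0.15, 0.15-0.2, 0.2-0.25,
>0.25.

**Attribution funnel.** CVonly = rhythmic(CV) \ rhythmic(GF); WTonly =
rhythmic(WT) \ rhythmic(KO); group A = CVonly \ WTonly (microbiota-driven),
B = CVonly ∩ WTonly (microbiota + HDAC3), C = WTonly \ CVonly (HDAC3-driven).

**Promoter acetylation.** Reads overlapping the −1500..+500 window around
each TSS (strand-oriented, ≥1 bp overlap) are counted per timepoint,
normalized per million aligned reads; relative amplitude =
(max − min)/max, split at 0.466 (0.5 available as an alternative preset).

**Enrichment.** Motifs: per-motif 2×2 counts x1/x2/z1/z2 (list/universe ×
with/without motif in the −900..+100 promoter window), Fisher's exact test,
BH FDR; an optional PWM scanner reports sites with likelihood ratio > 500.
Gene sets: hypergeometric over-representation plus Cohen's-kappa term
networks (κ = (Pr(a) − Pr(e))/(1 − Pr(e)), edges at κ ≥ 0.4, functional
groups = connected components).

## Worked example

```bash
circaepi simulate --outdir sim --seed 7 --n-per-group 60 --n-null 220
circaepi jtk --expr sim/expr_CV.tsv --samples sim/samples_CV.tsv --out rhythm_CV.tsv
```

prints

```
simulated 400 genes x 4 conditions -> sim
174/400 genes rhythmic at alpha 0.05
```

The benchmark plants 60 genes per attribution group (A: rhythmic except
germ-free; B: rhythmic only in CV and WT; C: lost only in the knockout) and
220 arrhythmic genes; CV carries 60 + 60 + 60 = 180 true rhythms, and the
scan flags 174 genes at Bonferroni-adjusted p ≤ 0.05 at the generator's
default signal-to-noise (relative amplitude 0.3, log-normal noise CV 0.2).
Running the scans for all four conditions and

```bash
circaepi compare --funnel rhythm_CV.tsv rhythm_GF.tsv rhythm_WT.tsv rhythm_KO.tsv --out funnel.tsv
```

labels each gene A/B/C/none; on this benchmark the assignment matches the
planted groups for 95.5% of genes (compare against `sim/truth.tsv`). The full flow — scans,
funnel, phase differences, clustering, promoter signal, motif and gene-set
enrichment — runs end-to-end with

```bash
circaepi run --outdir out --seed 7
```

Library use mirrors scikit-learn:

```python
from circaepi import JTKCycle
from circaepi.io_formats import read_expression_table

matrix = read_expression_table("sim/expr_CV.tsv", "sim/samples_CV.tsv")
est = JTKCycle(period_window=(18, 30), alpha=0.05).fit(matrix)
est.results_.head()  # gene_id, p_adj, q, period, lag, tau, amp, max_expr, rel_amp, rhythmic
```

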