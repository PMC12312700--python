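"""Readers, writers and validated containers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:

* :class:`TimeCourseMatrix` — genes x samples expression abundances (FPKM or
  simulated equivalents) with zeitgeber time / replicate / condition metadata.
* :class:`GeneModel` — gene id, chromosome, strand and strand-resolved TSS.
* :class:`IntervalSet` — 0-based half-open genomic intervals (aligned reads,
  motif sites); the single internal coordinate convention is BED's.
* :class:`GeneSetCollection` — GMT-style term -> member-gene sets.

Expression tables are accepted as-is with no re-normalization; upstream
alignment/quantification is outside the pipeline. Missing values are not
permitted in expression matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "TimeCourseMatrix",
    "GeneModel",
    "IntervalSet",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "read_sample_annotations",
    "write_sample_annotations",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: zeitgeber time (h), replicate and condition label."""

    sample_id: str
    zt: float
    replicate: int
    condition: str

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.zt) < 24.0):
            raise ValueError(
                f"sample {self.sample_id!r}: zeitgeber time {self.zt} outside [0, 24)"
            )
        if int(self.replicate) < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class TimeCourseMatrix:
    """Genes x samples abundance matrix with validated sample metadata.

    Invariants enforced at construction: unique gene ids, matching dimensions,
    finite non-negative values, at least two distinct zeitgeber times and
    unique (zt, replicate, condition) triplets.
    """

    gene_ids: list[str]
    values: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {n_genes} matrix rows"
            )
        if n_samples != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} sample annotations but {n_samples} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("expression abundances must be non-negative")
        triplets = [(s.zt, s.replicate, s.condition) for s in self.samples]
        if len(set(triplets)) != len(triplets):
            raise ValueError("(zt, replicate, condition) triplets are not unique")
        if len(set(s.zt for s in self.samples)) < 2:
            raise ValueError("need at least 2 distinct zeitgeber times")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def zts(self) -> np.ndarray:
        return np.array([s.zt for s in self.samples], dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def restrict(self, genes: Sequence[str]) -> "TimeCourseMatrix":
        """Row-subset to ``genes`` (order preserved); unknown ids are a hard error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return TimeCourseMatrix(list(genes), self.values[rows], list(self.samples))

    def timepoint_means(self) -> pd.DataFrame:
        """Replicate-averaged genes x zt matrix (columns sorted by zt)."""
        df = self.to_frame()
        zts = self.zts
        out = {}
        for zt in sorted(set(zts)):
            out[zt] = df.loc[:, zts == zt].mean(axis=1)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene's chromosome, strand and strand-resolved transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if int(self.tss) < 0:
            raise ValueError(f"gene {self.gene_id!r}: TSS must be >= 0")


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class IntervalSet:
    """A set of 0-based half-open genomic intervals backed by a DataFrame.

    Columns: chrom, start, end and (optionally null) name, score, strand.
    ``total_count`` is the number of records, used for per-million read
    normalization downstream.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _BED_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df = df[_BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            i = bad[0]
            raise ValueError(
                f"malformed interval (start >= end) at record {i}: "
                f"{df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']}"
            )
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple]
    ) -> "IntervalSet":
        rows = []
        for rec in records:
            rec = tuple(rec)
            row = dict(zip(_BED_COLUMNS, rec + (None,) * (6 - len(rec))))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=_BED_COLUMNS))

    @property
    def total_count(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


@dataclass
class GeneSetCollection:
    """Term id -> (description, member gene ids); members unique within a set."""

    sets: dict[str, tuple[str, tuple[str, ...]]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for term, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {term!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {term!r} has duplicate members")

    def members(self, term: str) -> set[str]:
        return set(self.sets[term][1])

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_sample_annotations(path: str | Path) -> list[SampleMeta]:
    """Read a sample-annotation TSV with columns sample_id, zt, replicate, condition."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "zt", "replicate", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample annotation file missing columns: {sorted(missing)}")
    return [
        SampleMeta(r.sample_id, float(r.zt), int(r.replicate), r.condition)
        for r in df.itertuples(index=False)
    ]


def write_sample_annotations(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_table(
    path: str | Path,
    sample_annotations: str | Path | Sequence[SampleMeta],
) -> TimeCourseMatrix:
    """Read a tab-separated expression table (column 1 = gene id, header = sample ids).

    ``sample_annotations`` may be a path to an annotation TSV or an in-memory
    list of :class:`SampleMeta`; annotations are matched to columns by
    sample id when all ids match, otherwise positionally.
    """
    if isinstance(sample_annotations, (str, Path)):
        samples = read_sample_annotations(sample_annotations)
    else:
        samples = list(sample_annotations)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] != len(samples):
        raise ValueError(
            f"expression table has {df.shape[1]} sample columns but the "
            f"annotation lists {len(samples)} samples"
        )
    gene_ids = [str(g) for g in df.index]
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric cell at gene {bad!r}, column {col!r} in {path}"
            ) from None
    # match annotations to header by sample id when possible
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) == len(samples) and all(c in by_id for c in df.columns):
        samples = [by_id[c] for c in df.columns]
    return TimeCourseMatrix(gene_ids, values, samples)


def write_expression_table(matrix: TimeCourseMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3+ into an :class:`IntervalSet` (0-based half-open, as on disk).

    Comment (#), ``track`` and ``browser`` lines are tolerated; a record with
    start >= end is a hard error naming the line.
    """
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: malformed interval start={start} >= end={end}"
                )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) > 3 else None,
                    "score": float(fields[4])
                    if len(fields) > 4 and fields[4] not in (".", "")
                    else None,
                    "strand": fields[5] if len(fields) > 5 else None,
                }
            )
    if not rows:
        return IntervalSet(pd.DataFrame(columns=_BED_COLUMNS))
    return IntervalSet(pd.DataFrame(rows, columns=_BED_COLUMNS))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED3 or BED6 depending on whether name/score/strand are populated."""
    df = intervals.df
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            fields = [str(rec.chrom), str(rec.start), str(rec.end)]
            if rec.name is not None or rec.score is not None or rec.strand is not None:
                fields += [
                    str(rec.name) if rec.name is not None else ".",
                    ("%g" % rec.score) if rec.score is not None else "0",
                    str(rec.strand) if rec.strand is not None else ".",
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like TSV (gene_id, chrom, strand, txStart, txEnd).

    TSS = txStart on '+' and txEnd on '-'. A header row starting with
    ``gene_id`` is tolerated.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            gene_id, chrom, strand, tx_start, tx_end = fields[:5]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r} for {gene_id!r}"
                )
            tss = int(tx_start) if strand == "+" else int(tx_end)
            models.append(GeneModel(gene_id, chrom, strand, tss))
    return models


def write_gene_models(
    models: Sequence[GeneModel], path: str | Path, tx_length: int = 2000
) -> None:
    """Write models back out in refFlat-like form (txStart/txEnd reconstructed
    so the strand-resolved TSS round-trips)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttxStart\ttxEnd\n")
        for m in models:
            if m.strand == "+":
                start, end = m.tss, m.tss + tx_length
            else:
                start, end = max(0, m.tss - tx_length), m.tss
            fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term, description, members...). Duplicate members within
    one line are deduplicated; duplicate term ids across lines are a hard error."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m, None)
            sets[term] = (desc, tuple(seen))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
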