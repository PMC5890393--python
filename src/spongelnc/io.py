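"""Core data containers and standard-format readers/writers.

Expression data travel as an :class:`ExpressionMatrix` (genes x samples,
integer counts with an optional normalized layer), gene models as
:class:`GeneAnnotation` records with 0-based half-open exon intervals, and
sample-level information as a plain pandas DataFrame indexed by sample id
with ``group`` and ``total_reads`` columns.

Coordinate convention: GFF3 is read as 1-based closed and converted to
0-based half-open on input; BED is already half-open and read natively.
All interval logic elsewhere in the package assumes half-open coordinates.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("spongelnc")

CODING = "coding"
LNCRNA = "lncRNA"
BIOTYPES = (CODING, LNCRNA)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with per-gene biotype.

    ``counts`` holds raw non-negative integer counts.  ``normalized`` and
    ``size_factors`` are attached by median-of-ratios normalization and are
    ``None`` before that step.
    """

    counts: pd.DataFrame
    biotype: pd.Series
    normalized: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.biotype = self.biotype.reindex(self.counts.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()
            raise ValueError(f"genes missing biotype: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        norm = self.normalized[samples] if self.normalized is not None else None
        sf = self.size_factors[samples] if self.size_factors is not None else None
        return ExpressionMatrix(self.counts[samples], self.biotype, norm, sf)

    def lnc_genes(self) -> pd.Index:
        return self.genes[self.biotype.values == LNCRNA]

    def coding_genes(self) -> pd.Index:
        return self.genes[self.biotype.values == CODING]


def read_counts(path: str) -> ExpressionMatrix:
    """Read a count matrix from TSV (genes x samples) or MatrixMarket.

    TSV layout: first column ``gene_id``, optional ``biotype`` column, then
    one column per sample.  MTX layout: ``path`` plus sibling files
    ``path + '.rows'`` (gene_id<TAB>biotype) and ``path + '.cols'``
    (sample ids, one per line).
    """
    if str(path).endswith(".mtx"):
        return _read_counts_mtx(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty counts file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"counts file {path} has no sample columns")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if "biotype" in df.columns:
        biotype = df.pop("biotype").astype(str)
    else:
        biotype = pd.Series(CODING, index=df.index)
    bad = df.columns[df.isna().any(axis=0)].tolist()
    if bad or df.isna().any().any():
        raise ValueError(f"ragged or missing values in counts file {path}: columns {bad}")
    counts = df.astype(np.int64)
    return ExpressionMatrix(counts, biotype)


def write_counts(matrix: ExpressionMatrix, path: str) -> None:
    """Write counts to TSV (or MTX when the path ends in ``.mtx``)."""
    if str(path).endswith(".mtx"):
        _write_counts_mtx(matrix, path)
        return
    out = matrix.counts.copy()
    out.insert(0, "biotype", matrix.biotype)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def _read_counts_mtx(path: str) -> ExpressionMatrix:
    from scipy.io import mmread

    raw = mmread(path)
    mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
    rows = pd.read_csv(path + ".rows", sep="\t", header=None, names=["gene_id", "biotype"], dtype=str)
    cols = [line.strip() for line in open(path + ".cols") if line.strip()]
    counts = pd.DataFrame(mat.astype(np.int64), index=rows["gene_id"].tolist(), columns=cols)
    counts.index.name = "gene_id"
    return ExpressionMatrix(counts, pd.Series(rows["biotype"].tolist(), index=counts.index))


def _write_counts_mtx(matrix: ExpressionMatrix, path: str) -> None:
    from scipy import sparse
    from scipy.io import mmwrite

    mmwrite(path if path.endswith(".mtx") else path + ".mtx",
            sparse.coo_matrix(matrix.counts.values))
    with open(path + ".rows", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{matrix.biotype[g]}\n")
    with open(path + ".cols", "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample, group, total_reads."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    for col in ("sample", "group", "total_reads"):
        if col not in meta.columns:
            raise ValueError(f"metadata file {path} missing column {col!r}")
    if meta["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    meta = meta.set_index("sample")
    meta["total_reads"] = meta["total_reads"].astype(np.int64)
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def merge_intervals(ivs):
    """Merge overlapping/adjacent half-open intervals; returns sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in ivs)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"interval end must exceed start: ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model: contig, strand and merged exon intervals (0-based half-open)."""

    gene_id: str
    biotype: str
    contig: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", tuple(merge_intervals(self.exons)))

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        """Transcript length: sum of exon lengths in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def read_annotation(path: str) -> list[GeneAnnotation]:
    """Read gene models from GFF3 or BED12 (by extension)."""
    if str(path).endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gff3(path)


_BIOTYPE_RE = re.compile(r"biotype=([^;]+)")


def _read_gff3(path: str) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if "biotype" not in gene.attributes:
            raise ValueError(f"gene {gene.id} missing biotype attribute")
        biotype = gene.attributes["biotype"][0]
        exons = [(f.start - 1, f.end) for f in db.children(gene, featuretype="exon")]
        if not exons:
            # single-exon genes may omit exon features; the gene span stands in
            exons = [(gene.start - 1, gene.end)]
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {gene.id}: exon end < start ({s + 1}, {e})")
        genes.append(GeneAnnotation(gene.id, biotype, gene.seqid, gene.strand,
                                    tuple(exons)))
    return genes


def _read_bed12(path: str) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            contig, start, _end, name, _score, strand = parts[:6]
            start = int(start)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + off, start + off + size)
                     for off, size in zip(offsets, sizes)]
            # biotype carried in the name as id|biotype
            if "|" in name:
                gene_id, biotype = name.split("|", 1)
            else:
                gene_id, biotype = name, CODING
            genes.append(GeneAnnotation(gene_id, biotype, contig, strand, tuple(exons)))
    return genes


def write_gff3(genes, path: str) -> None:
    """Write gene + exon features with biotype attributes (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.span[0], g.gene_id)):
            s, e = g.span
            fh.write(f"{g.contig}\tspongelnc\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};biotype={g.biotype}\n")
            for i, (xs, xe) in enumerate(g.exons, start=1):
                fh.write(f"{g.contig}\tspongelnc\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


def annotation_biotypes(genes) -> dict:
    return {g.gene_id: g.biotype for g in genes}


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All thresholds and paths for a full pipeline run.

    Thresholds default to the published analysis values: samples with fewer
    than one million reads are discarded, differential expression is called
    at a 5% FDR, co-expression edges need |r| >= 0.95 at p < 0.05, and
    homology pairs must satisfy e-value < 1e-5.
    """

    counts: str | None = None
    metadata: str | None = None
    counts_dev_a: str | None = None
    counts_dev_b: str | None = None
    annotation_a: str | None = None
    annotation_b: str | None = None
    homology: str | None = None
    outdir: str = "spongelnc_out"
    min_reads: int = 1_000_000
    fdr: float = 0.05
    r_pos: float = 0.95
    r_neg: float = -0.95
    edge_p: float = 0.05
    evalue: float = 1e-5
    correlation_method: str = "pearson"
    min_shared_pairs: int = 1
    n_perm: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1) or not (0 < self.edge_p <= 1):
            raise ValueError("fdr and edge_p must be in (0, 1)")
        if not (0 < self.r_pos <= 1) or not (-1 <= self.r_neg < 0):
            raise ValueError("r_pos in (0,1], r_neg in [-1,0) required")
        if self.min_reads < 0 or self.evalue <= 0:
            raise ValueError("min_reads >= 0 and evalue > 0 required")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Index)):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
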