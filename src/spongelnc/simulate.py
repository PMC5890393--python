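"""Two-species synthetic expression data with planted structure.

The generator emulates the data shape of a sponge cell-type / developmental
CEL-seq study: a three-cell-type count matrix with unbalanced replicates
(15 archeocyte, 10 choanocyte, 6 pinacocyte retained after QC, plus planted
sub-threshold libraries so that 39 raw samples filter down to 31), a
stage-indexed developmental time course per species, gene models placed on
synthetic contigs with controlled positional classes, and a many-to-many
coding-gene homology table with optional spurious pairs.

Counts are negative binomial via a gamma-Poisson mixture.  Planted
co-expression modules share a latent stage profile: member gene g carries
latent sqrt(rho) * z_module + sqrt(1 - rho) * eps_g, so the expected latent
pairwise correlation within a module is exactly rho; negative-edge members
get a sign-flipped loading.  Background genes have independent latents.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (CODING, LNCRNA, ExpressionMatrix, GeneAnnotation,
                 write_counts, write_gff3, write_sample_metadata)

DEFAULT_CELLTYPE_REPLICATES = {"archeocyte": 15, "choanocyte": 10, "pinacocyte": 6}
DEFAULT_SUBTHRESHOLD = {"choanocyte": 5, "pinacocyte": 3}  # 39 raw -> 31 kept


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module, optionally mirrored across species."""

    name: str
    hub_a: str | None
    members_a: tuple
    hub_b: str | None = None
    members_b: tuple = ()
    latent_corr: float = 0.99
    conserved: bool = False
    n_negative_a: int = 0
    n_negative_b: int = 0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_coding_a: int = 300
    n_lnc_a: int = 40
    n_coding_b: int = 300
    n_lnc_b: int = 40
    n_stages: int = 16
    celltype_replicates: dict = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_REPLICATES))
    subthreshold_replicates: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTHRESHOLD))
    nb_dispersion: float = 0.05          # cell-type counts
    dev_dispersion: float = 0.01         # developmental counts
    module_spec: list | None = None      # None -> build_default_modules()
    latent_amplitude: float = 1.0        # log-scale amplitude of stage profiles
    homology_noise: float = 0.005        # spurious fraction of homology table
    ortholog_fraction: float = 0.5       # background coding genes with orthologs
    n_weak_homology: int = 5             # rows above the E-value cutoff
    library_size_range: tuple = (2_000_000, 12_000_000)
    subthreshold_read_range: tuple = (150_000, 950_000)
    base_mean_celltype: float = 100.0
    base_mean_dev: float = 1000.0
    de_fraction: float = 0.10
    de_fold_change: float = 4.0
    silent_fraction: float = 0.02
    fraction_intergenic: float = 0.5
    fraction_antisense: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_coding_a", "n_lnc_a", "n_coding_b", "n_lnc_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_stages < 3:
            raise ValueError("n_stages must be >= 3")
        if not 0 <= self.homology_noise < 1:
            raise ValueError("homology_noise must be in [0, 1)")
        if self.n_lnc_a > self.n_coding_a or self.n_lnc_b > self.n_coding_b:
            raise ValueError("annotation layout needs n_lnc <= n_coding")


@dataclass
class SimulatedBundle:
    counts_celltype_a: ExpressionMatrix
    meta_celltype_a: pd.DataFrame
    counts_dev_a: ExpressionMatrix
    meta_dev_a: pd.DataFrame
    counts_dev_b: ExpressionMatrix
    meta_dev_b: pd.DataFrame
    annotation_a: list
    annotation_b: list
    homology: list  # rows (gene_a, gene_b, evalue, description)
    truth: dict


# ---------------------------------------------------------------------------
# Gene universes and default planted modules
# ---------------------------------------------------------------------------

def gene_ids(config: SimulationConfig, species: str) -> tuple[list, list]:
    n_cod = config.n_coding_a if species == "A" else config.n_coding_b
    n_lnc = config.n_lnc_a if species == "A" else config.n_lnc_b
    coding = [f"cod{species}{i:04d}" for i in range(n_cod)]
    lnc = [f"lnc{species}{i:03d}" for i in range(n_lnc)]
    return coding, lnc


def build_default_modules(config: SimulationConfig) -> list[ModuleSpec]:
    """Three conserved modules plus one private module per species.

    Conserved modules have eight coding members per species; one member per
    module carries a negative (sign-flipped) loading, mirroring networks
    with both positive and negative edges.
    """
    cod_a, lnc_a = gene_ids(config, "A")
    cod_b, lnc_b = gene_ids(config, "B")
    size = 8
    specs = []
    for m in range(3):
        specs.append(ModuleSpec(
            name=f"conserved_{m + 1}",
            hub_a=lnc_a[m], members_a=tuple(cod_a[m * size:(m + 1) * size]),
            hub_b=lnc_b[m], members_b=tuple(cod_b[m * size:(m + 1) * size]),
            latent_corr=0.99, conserved=True,
            n_negative_a=1, n_negative_b=1))
    specs.append(ModuleSpec(
        name="private_A", hub_a=lnc_a[3],
        members_a=tuple(cod_a[3 * size:4 * size]),
        latent_corr=0.99, conserved=False))
    specs.append(ModuleSpec(
        name="private_B", hub_a=None, members_a=(),
        hub_b=lnc_b[3], members_b=tuple(cod_b[3 * size:4 * size]),
        latent_corr=0.99, conserved=False))
    return specs


def _validate_modules(config: SimulationConfig, specs) -> None:
    for species in ("A", "B"):
        coding, lnc = gene_ids(config, species)
        coding_set, lnc_set = set(coding), set(lnc)
        used: set = set()
        for s in specs:
            hub = s.hub_a if species == "A" else s.hub_b
            members = s.members_a if species == "A" else s.members_b
            if not 0 <= s.latent_corr <= 1:
                raise ValueError(f"module {s.name}: latent_corr outside [0, 1]")
            if hub is None and not members:
                continue
            if hub is None or hub not in lnc_set:
                raise ValueError(f"module {s.name}: hub {hub!r} not a known "
                                 f"species-{species} lncRNA")
            bad = [m for m in members if m not in coding_set]
            if bad:
                raise ValueError(f"module {s.name}: members outside configured "
                                 f"gene counts: {bad[:3]}")
            overlap = used & set(members)
            if overlap:
                raise ValueError(f"module {s.name}: members shared with another "
                                 f"module: {sorted(overlap)[:3]}")
            used |= set(members)
    for s in specs:
        if s.conserved and not (s.members_a and s.members_b):
            raise ValueError(f"module {s.name}: conserved flag requires members "
                             "in both species")


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with var = mu + a * mu^2."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape)
    pos = (alpha > 0) & (mu > 0)
    lam = np.array(mu)
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam[pos] = rng.gamma(shape, alpha[pos] * mu[pos])
    return rng.poisson(lam).astype(np.int64)


def simulate_celltype_counts(config: SimulationConfig, truth: dict,
                             rng: np.random.Generator):
    """Cell-type count matrix + sample metadata for species A.

    Planted DE genes get ``de_fold_change`` in their target cell type;
    sub-threshold samples (below the 1M-read QC cut) are appended per
    ``subthreshold_replicates`` and recorded in the truth so downstream
    filtering can be checked against the planted 39 -> 31 design.
    """
    coding, lnc = gene_ids(config, "A")
    genes = coding + lnc
    biotype = pd.Series([CODING] * len(coding) + [LNCRNA] * len(lnc), index=genes)

    base = config.base_mean_celltype * rng.lognormal(0.0, 1.0, size=len(genes))
    silent = rng.random(len(genes)) < config.silent_fraction
    base[silent] = 0.0

    types = sorted(config.celltype_replicates)
    de_mask = (~silent) & (rng.random(len(genes)) < config.de_fraction)
    de_target = {genes[i]: types[rng.integers(len(types))]
                 for i in np.flatnonzero(de_mask)}

    lo, hi = config.library_size_range
    mid = float(np.sqrt(lo * hi))
    columns, total_reads, groups, sub_ids = [], [], [], []
    for ct in types:
        n_keep = config.celltype_replicates[ct]
        n_sub = config.subthreshold_replicates.get(ct, 0)
        for i in range(n_keep + n_sub):
            sid = f"{ct}_{i + 1:02d}"
            columns.append(sid)
            groups.append(ct)
            if i < n_keep:
                total_reads.append(int(rng.integers(lo, hi + 1)))
            else:
                slo, shi = config.subthreshold_read_range
                total_reads.append(int(rng.integers(slo, shi + 1)))
                sub_ids.append(sid)

    fc = np.ones((len(genes), len(columns)))
    for gi, g in enumerate(genes):
        if g in de_target:
            for si, ct in enumerate(groups):
                if ct == de_target[g]:
                    fc[gi, si] = config.de_fold_change
    depth = np.array(total_reads, dtype=float) / mid
    mu = base[:, None] * fc * depth[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=columns), biotype)
    meta = pd.DataFrame({"group": groups, "total_reads": total_reads},
                        index=pd.Index(columns, name="sample"))
    truth["de_genes"] = dict(sorted(de_target.items()))
    truth["silent_genes_a"] = [genes[i] for i in np.flatnonzero(silent)]
    truth["subthreshold_samples"] = sub_ids
    return matrix, meta


def simulate_dev_counts(config: SimulationConfig, species: str, specs,
                        truth: dict, rng: np.random.Generator):
    """Stage-indexed developmental counts with planted module structure."""
    coding, lnc = gene_ids(config, species)
    genes = coding + lnc
    biotype = pd.Series([CODING] * len(coding) + [LNCRNA] * len(lnc), index=genes)
    n_stages = config.n_stages

    latent = {g: rng.normal(size=n_stages) for g in genes}  # background

    def _unit(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.linalg.norm(v)

    membership: dict = {}
    for s in specs:
        hub = s.hub_a if species == "A" else s.hub_b
        members = s.members_a if species == "A" else s.members_b
        n_neg = s.n_negative_a if species == "A" else s.n_negative_b
        if hub is None and not members:
            continue
        # unit-norm shared profile; member residuals are orthonormalized so
        # the empirical latent correlation with the hub is exactly sqrt(rho)
        z = _unit(rng.normal(size=n_stages))
        scale = np.sqrt(n_stages)  # back to ~unit per-stage variance
        latent[hub] = z * scale
        negatives = list(members[:n_neg])
        rho = s.latent_corr
        for m in members:
            eps = _unit(rng.normal(size=n_stages))
            eps = eps - np.dot(eps, z) * z
            norm = np.linalg.norm(eps)
            if norm > 0:
                eps = eps / norm
            l = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            if m in negatives:
                l = -l
            latent[m] = l * scale
        membership[s.name] = {"hub": hub, "members": list(members),
                              "negative_members": negatives,
                              "latent_corr": rho, "conserved": s.conserved}

    base = config.base_mean_dev * rng.lognormal(0.0, 0.5, size=len(genes))
    depth = rng.uniform(0.8, 1.2, size=n_stages)
    amp = config.latent_amplitude
    mu = np.vstack([base[i] * np.exp(amp * latent[g] - amp**2 / 2.0) * depth
                    for i, g in enumerate(genes)])
    counts = _nb_draw(rng, mu, config.dev_dispersion)

    columns = [f"stage_{t + 1:02d}" for t in range(n_stages)]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=columns), biotype)
    meta = pd.DataFrame({"group": columns,
                         "total_reads": counts.sum(axis=0).astype(int)},
                        index=pd.Index(columns, name="sample"))
    truth[f"modules_{species.lower()}"] = membership
    return matrix, meta


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, species: str,
                        truth: dict | None = None) -> list:
    """Gene models on synthetic contigs with controlled lncRNA placement.

    Each lncRNA is paired with one coding gene (two exons at a 10 kb pitch,
    50 genes per contig) and placed to force its positional class:
    intergenic lncRNAs sit in the gap downstream of their partner, antisense
    lncRNAs overlap the partner's first exon on the opposite strand, and the
    remainder sit inside the partner's intron on the same strand.
    """
    coding_ids, lnc_ids = gene_ids(config, species)
    per_contig = 50
    genes: list[GeneAnnotation] = []
    offsets = {}
    for i, gid in enumerate(coding_ids):
        contig = f"contig{species}_{i // per_contig + 1}"
        o = (i % per_contig) * 10_000
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneAnnotation(gid, CODING, contig, strand,
                                    ((o, o + 500), (o + 1500, o + 2000))))
        offsets[i] = (contig, o, strand)

    n_lnc = len(lnc_ids)
    n_int = int(round(config.fraction_intergenic * n_lnc))
    n_anti = int(round(config.fraction_antisense * n_lnc))
    n_int = min(n_int, n_lnc)
    n_anti = min(n_anti, n_lnc - n_int)
    classes = (["intergenic"] * n_int + ["antisense_exon_overlap"] * n_anti
               + ["genic_other"] * (n_lnc - n_int - n_anti))

    planted: dict = {}
    opposite = {"+": "-", "-": "+"}
    for j, (lid, cls) in enumerate(zip(lnc_ids, classes)):
        contig, o, cstrand = offsets[j]
        if cls == "intergenic":
            exons = ((o + 5000, o + 5400), (o + 5800, o + 6000))
            strand = "+"
        elif cls == "antisense_exon_overlap":
            exons = ((o + 100, o + 600),)
            strand = opposite[cstrand]
        else:  # inside the partner's intron, same strand
            exons = ((o + 700, o + 1300),)
            strand = cstrand
        genes.append(GeneAnnotation(lid, LNCRNA, contig, strand, exons))
        planted[lid] = cls
    if truth is not None:
        truth[f"position_classes_{species.lower()}"] = planted
    return genes


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

def simulate_homology(config: SimulationConfig, specs, truth: dict,
                      rng: np.random.Generator) -> list:
    """Coding-gene homology rows (gene_a, gene_b, evalue, description).

    Conserved modules contribute member-to-member ortholog pairs (with one
    extra many-to-many hit per module); a configurable fraction of
    background coding genes are paired index-to-index; spurious pairs are
    sprinkled at rate ``homology_noise`` of the true table and recorded in
    the truth.  A few rows above the E-value cutoff exercise loader
    filtering.
    """
    cod_a, _ = gene_ids(config, "A")
    cod_b, _ = gene_ids(config, "B")
    module_genes_a = {g for s in specs for g in s.members_a}
    module_genes_b = {g for s in specs for g in s.members_b}

    def ev(lo=-50, hi=-10):
        return 10.0 ** rng.uniform(lo, hi)

    rows: list[tuple] = []
    for s in specs:
        if not s.conserved:
            continue
        k = min(len(s.members_a), len(s.members_b))
        for i in range(k):
            rows.append((s.members_a[i], s.members_b[i], ev(),
                         f"ortholog_{s.name}"))
        # one many-to-many hit per conserved module
        if k >= 2:
            rows.append((s.members_a[0], s.members_b[1], ev(-20, -8),
                         f"ortholog_{s.name}_secondary"))

    bg_a = [g for g in cod_a if g not in module_genes_a]
    bg_b = [g for g in cod_b if g not in module_genes_b]
    n_bg = int(round(config.ortholog_fraction * min(len(bg_a), len(bg_b))))
    for i in range(n_bg):
        rows.append((bg_a[i], bg_b[i], ev(), "ortholog_background"))

    n_spurious = int(round(config.homology_noise / (1.0 - config.homology_noise)
                           * len(rows)))
    spurious = []
    for _ in range(n_spurious):
        pair = (cod_a[rng.integers(len(cod_a))], cod_b[rng.integers(len(cod_b))],
                ev(-9, -6), "spurious")
        rows.append(pair)
        spurious.append([pair[0], pair[1]])

    for _ in range(config.n_weak_homology):
        rows.append((cod_a[rng.integers(len(cod_a))],
                     cod_b[rng.integers(len(cod_b))],
                     10.0 ** rng.uniform(-4, 0), "weak_hit_above_cutoff"))

    truth["spurious_homology"] = spurious
    return sorted(rows)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full two-species bundle.  Deterministic given the seed."""
    specs = (config.module_spec if config.module_spec is not None
             else build_default_modules(config))
    _validate_modules(config, specs)
    rng = np.random.default_rng(config.seed)
    truth: dict = {
        "seed": config.seed,
        "conserved_module_pairs": [[s.hub_a, s.hub_b] for s in specs
                                   if s.conserved],
    }
    annotation_a = simulate_annotation(config, "A", truth)
    annotation_b = simulate_annotation(config, "B", truth)
    counts_ct, meta_ct = simulate_celltype_counts(config, truth, rng)
    counts_dev_a, meta_dev_a = simulate_dev_counts(config, "A", specs, truth, rng)
    counts_dev_b, meta_dev_b = simulate_dev_counts(config, "B", specs, truth, rng)
    homology = simulate_homology(config, specs, truth, rng)
    return SimulatedBundle(counts_ct, meta_ct, counts_dev_a, meta_dev_a,
                           counts_dev_b, meta_dev_b, annotation_a, annotation_b,
                           homology, truth)


def write_bundle(bundle: SimulatedBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    j = os.path.join
    write_counts(bundle.counts_celltype_a, j(outdir, "counts_celltype_A.tsv"))
    write_sample_metadata(bundle.meta_celltype_a, j(outdir, "meta_celltype_A.tsv"))
    write_counts(bundle.counts_dev_a, j(outdir, "counts_dev_A.tsv"))
    write_sample_metadata(bundle.meta_dev_a, j(outdir, "meta_dev_A.tsv"))
    write_counts(bundle.counts_dev_b, j(outdir, "counts_dev_B.tsv"))
    write_sample_metadata(bundle.meta_dev_b, j(outdir, "meta_dev_B.tsv"))
    write_gff3(bundle.annotation_a, j(outdir, "annotation_A.gff3"))
    write_gff3(bundle.annotation_b, j(outdir, "annotation_B.gff3"))
    with open(j(outdir, "homology.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tevalue\tdescription\n")
        for a, b, e, d in bundle.homology:
            fh.write(f"{a}\t{b}\t{e:.3e}\t{d}\n")
    with open(j(outdir, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
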