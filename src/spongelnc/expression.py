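"""Sample QC, normalization, pairwise NB differential expression, cell-type
enrichment calls and expression-quartile binning.

The analysis mirrors a CEL-seq cell-type workflow: samples below a total-read
threshold are discarded, counts are normalized by median-of-ratios size
factors, each pair of cell types is tested gene-by-gene with a negative
binomial Wald test (method-of-moments dispersion), p-values are adjusted per
contrast with Benjamini-Hochberg, significant genes are assigned a Venn-style
enrichment category, and lncRNA expression is binned into global quartiles.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("spongelnc")

DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5  # stabilises log fold changes at low counts


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_samples(matrix: ExpressionMatrix, meta: pd.DataFrame,
                   min_reads: int = 1_000_000) -> ExpressionMatrix:
    """Drop samples with fewer than ``min_reads`` total reads.

    The threshold is exclusive on the low side: a sample with exactly
    ``min_reads`` reads is retained.  Column order is preserved.
    """
    missing = [s for s in matrix.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    keep = [s for s in matrix.samples if meta.loc[s, "total_reads"] >= min_reads]
    if not keep:
        dropped = ", ".join(matrix.samples)
        raise ValueError(
            f"no samples with >= {min_reads} reads; discarded all of: {dropped}")
    n_drop = len(matrix.samples) - len(keep)
    if n_drop:
        logger.info("filter_samples: discarded %d of %d samples (< %d reads)",
                    n_drop, len(matrix.samples), min_reads)
    return matrix.subset_samples(keep)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_median_of_ratios(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios (size factor) normalization.

    For each sample, the size factor is the median over reference genes
    (genes with nonzero counts in every sample) of the ratio of the gene's
    count to its geometric mean across samples.  When no reference gene
    exists the function falls back to library-size factors (total counts
    scaled to geometric mean one) with a warning.
    """
    counts = matrix.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("normalization requires >= 2 samples")
    ref = (counts > 0).all(axis=1)
    if ref.any():
        logc = np.log(counts.loc[ref])
        geo = logc.mean(axis=1)
        ratios = np.exp(logc.sub(geo, axis=0))
        sf = ratios.median(axis=0)
    else:
        logger.warning("no gene nonzero in all samples; "
                       "falling back to library-size normalization")
        lib = counts.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("cannot normalize: sample(s) with zero total counts")
        sf = lib / np.exp(np.log(lib).mean())
    sf.name = "size_factor"
    normalized = counts.div(sf, axis=1)
    return ExpressionMatrix(matrix.counts, matrix.biotype, normalized, sf)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def de_test_pairwise(matrix: ExpressionMatrix, meta: pd.DataFrame,
                     group_a: str, group_b: str) -> pd.DataFrame:
    """Per-gene NB Wald test between two sample groups.

    The per-group mean is taken on normalized counts; the NB dispersion is a
    pooled method-of-moments estimate across both groups, floored at a small
    positive constant.  The Wald statistic for the log fold change is
    referred to a t distribution with ``n_a + n_b - 2`` degrees of freedom.
    Genes with zero raw counts in every sample of both groups get p = NA and
    are excluded from the BH adjustment.

    Returns a DataFrame with columns gene, contrast, log2fc, p, Q, where
    log2fc is log2(mean_A / mean_B) for contrast "A_vs_B".
    """
    if matrix.normalized is None:
        matrix = normalize_median_of_ratios(matrix)
    for g in (group_a, group_b):
        if g not in set(meta["group"]):
            raise ValueError(f"group {g!r} absent from metadata")
    samp_a = [s for s in matrix.samples if meta.loc[s, "group"] == group_a]
    samp_b = [s for s in matrix.samples if meta.loc[s, "group"] == group_b]
    if len(samp_a) < 2 or len(samp_b) < 2:
        raise ValueError("both groups need >= 2 samples after QC")

    a = matrix.normalized[samp_a].values
    b = matrix.normalized[samp_b].values
    raw_a = matrix.counts[samp_a].values
    raw_b = matrix.counts[samp_b].values
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
        alpha_b = np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
    alpha = ((n_a - 1) * alpha_a + (n_b - 1) * alpha_b) / (n_a + n_b - 2)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2((mu_a + _PSEUDOCOUNT) / (mu_b + _PSEUDOCOUNT))
    # delta-method SE of the log-mean difference under NB variance mu+alpha*mu^2
    v_a = (mu_a + alpha * mu_a**2) / n_a
    v_b = (mu_b + alpha * mu_b**2) / n_b
    se = np.sqrt(v_a / (mu_a + _PSEUDOCOUNT) ** 2
                 + v_b / (mu_b + _PSEUDOCOUNT) ** 2) / np.log(2)

    informative = (raw_a.sum(axis=1) + raw_b.sum(axis=1)) > 0
    p = np.full(len(mu_a), np.nan)
    ok = informative & (se > 0)
    tstat = np.zeros(len(mu_a))
    tstat[ok] = log2fc[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n_a + n_b - 2)
    p[informative & ~ok] = 1.0  # no variability but counts present

    out = pd.DataFrame({
        "gene": matrix.genes,
        "contrast": f"{group_a}_vs_{group_b}",
        "log2fc": np.where(informative, log2fc, np.nan),
        "p": p,
    })
    out["Q"] = bh_adjust(out["p"].values)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[mask] = adj
    return q


# ---------------------------------------------------------------------------
# Enrichment (Venn) categories
# ---------------------------------------------------------------------------

def de_all_pairs(matrix: ExpressionMatrix, meta: pd.DataFrame,
                 groups=None) -> pd.DataFrame:
    """Run all pairwise contrasts among ``groups`` (default: all in meta)."""
    if groups is None:
        groups = sorted(set(meta.loc[list(matrix.samples), "group"]))
    tables = [de_test_pairwise(matrix, meta, a, b)
              for a, b in combinations(groups, 2)]
    return pd.concat(tables, ignore_index=True)


def call_enrichment(de_results: pd.DataFrame, matrix: ExpressionMatrix,
                    meta: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Assign each differentially expressed gene to a Venn category.

    A gene is DE when Q < ``q_threshold`` in at least one pairwise contrast.
    A cell type belongs to the gene's category when the gene's normalized
    mean in that type exceeds its mean in every type it was significantly
    compared against.  Singleton categories are reported as "X-enriched";
    larger sets are joined with "+".
    """
    if matrix.normalized is None:
        raise ValueError("normalized counts required; run normalization first")
    group_means = {}
    for g in sorted(set(meta.loc[list(matrix.samples), "group"])):
        cols = [s for s in matrix.samples if meta.loc[s, "group"] == g]
        group_means[g] = matrix.normalized[cols].mean(axis=1)

    sig = de_results[de_results["Q"] < q_threshold]
    records = []
    for gene, rows in sig.groupby("gene", sort=True):
        contrasts = [tuple(c.split("_vs_")) for c in rows["contrast"]]
        involved = {t for pair in contrasts for t in pair}
        winners = set()
        for t in involved:
            opponents = [a if b == t else b for a, b in contrasts if t in (a, b)]
            if opponents and all(group_means[t][gene] > group_means[o][gene]
                                 for o in opponents):
                winners.add(t)
        if not winners:
            continue
        label = "+".join(sorted(winners)) + "-enriched"
        records.append({"gene": gene, "category": label,
                        "n_significant_contrasts": len(rows)})
    return pd.DataFrame(records, columns=["gene", "category",
                                          "n_significant_contrasts"])


# ---------------------------------------------------------------------------
# Expression quartiles
# ---------------------------------------------------------------------------

def quartile_bins(matrix: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Bin gene expression into global quartiles Q1 (low) .. Q4 (high).

    Each gene's summary value is the median of its nonzero normalized counts
    across all samples; genes with no nonzero count are left unassigned.
    The 25/50/75th percentiles of the pooled summary values define global
    breakpoints, and within each group a gene's quartile is the bin of its
    group-mean normalized count against those breakpoints.
    """
    if matrix.normalized is None:
        raise ValueError("normalized counts required; run normalization first")
    norm = matrix.normalized
    nonzero = norm.where(norm > 0)
    summary = nonzero.median(axis=1)  # NaN for all-zero genes
    expressed = summary.dropna()
    if len(expressed) < 4:
        raise ValueError("need >= 4 genes with nonzero expression for quartiles")
    breaks = np.percentile(expressed.values, [25, 50, 75])

    groups = sorted(set(meta.loc[list(matrix.samples), "group"]))
    records = []
    for g in groups:
        cols = [s for s in matrix.samples if meta.loc[s, "group"] == g]
        means = norm[cols].mean(axis=1)
        for gene in expressed.index:
            q = 1 + int(np.searchsorted(breaks, means[gene], side="left"))
            records.append({"gene": gene, "group": g, "quartile": f"Q{q}"})
    return pd.DataFrame(records, columns=["gene", "group", "quartile"])
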