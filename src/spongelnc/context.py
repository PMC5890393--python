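"""Positional classification of lncRNAs and structural comparisons.

A lncRNA is classified relative to the coding gene complement as

* ``antisense_exon_overlap`` — at least one lncRNA exon overlaps a coding
  exon on the opposite strand (priority class, i.e. checked first);
* ``intergenic`` — the lncRNA span overlaps no coding gene span on either
  strand;
* ``genic_other`` — everything else (e.g. intronic or same-strand overlap).

Structural comparisons (transcript length, exon count, positional-class
proportions) between two lncRNA sets use a Mann-Whitney U test (exact by
enumeration for small samples) and Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .io import CODING, LNCRNA, GeneAnnotation

EXACT_MWU_MAX_N = 12  # combined sample size up to which the exact test is used


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

INTERGENIC = "intergenic"
ANTISENSE = "antisense_exon_overlap"
GENIC_OTHER = "genic_other"
POSITION_CLASSES = (INTERGENIC, ANTISENSE, GENIC_OTHER)


@dataclass(frozen=True)
class PositionClass:
    lnc_id: str
    position_class: str
    supporting: tuple = ()


def _overlaps(a: tuple, b: tuple) -> bool:
    """Half-open interval overlap."""
    return a[0] < b[1] and b[0] < a[1]


def classify_lncrna_position(lnc: GeneAnnotation, coding) -> PositionClass:
    """Classify one lncRNA against a collection of coding gene models."""
    if lnc.biotype != LNCRNA:
        raise ValueError(f"{lnc.gene_id} is not a lncRNA")
    same_contig = [c for c in coding if c.biotype == CODING and c.contig == lnc.contig]

    antisense_support = []
    for c in same_contig:
        if c.strand == lnc.strand:
            continue
        if any(_overlaps(le, ce) for le in lnc.exons for ce in c.exons):
            antisense_support.append(c.gene_id)
    if antisense_support:
        return PositionClass(lnc.gene_id, ANTISENSE, tuple(sorted(antisense_support)))

    span_support = [c.gene_id for c in same_contig if _overlaps(lnc.span, c.span)]
    if not span_support:
        return PositionClass(lnc.gene_id, INTERGENIC)
    return PositionClass(lnc.gene_id, GENIC_OTHER, tuple(sorted(span_support)))


def classify_all(lncs, coding) -> list[PositionClass]:
    return [classify_lncrna_position(l, coding) for l in lncs]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j, ties count 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (reported for x) with a two-sided p-value.

    For combined sample sizes up to 12 the null distribution of U is built
    by exhaustive enumeration of all group assignments of the pooled values
    (tie-aware); the two-sided p is the doubled smaller exact tail, capped
    at one.  Larger samples use the normal approximation with tie correction
    and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("non-numeric (NaN) input")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)

    if n1 + n2 <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([x, y])
        total = comb(n1 + n2, n1)
        n_ge = n_le = 0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u >= u_obs - eps:
                n_ge += 1
            if u <= u_obs + eps:
                n_le += 1
        p = min(1.0, 2.0 * min(n_ge, n_le) / total)
        return u_obs, p

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    mean_u = n1 * n2 / 2.0
    z = (u_obs - mean_u - 0.5 * np.sign(u_obs - mean_u)) / np.sqrt(sigma2)
    return u_obs, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one.  The odds ratio is the
    sample (unconditional) odds ratio ad/bc, ``inf`` when bc = 0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integers")
    a, b = t[0]
    c, d = t[1]
    row1, col1, n = a + b, a + c, t.sum()
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise ValueError("Fisher's exact test requires positive margins")

    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())

    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), min(1.0, p)


# ---------------------------------------------------------------------------
# Structural comparison report
# ---------------------------------------------------------------------------

def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sem = 0.0 if values.size < 2 else float(np.std(values, ddof=1) / np.sqrt(values.size))
    return mean, sem


def compare_structural_features(lnc_a, lnc_b, coding=None) -> dict:
    """Compare two lncRNA sets on length, exon count and positional classes.

    Returns a nested dict: for each feature the per-set mean and SEM plus a
    Mann-Whitney p-value, and (when ``coding`` is given) per positional
    class the counts, proportions and a Fisher's exact p on the 2x2 table
    (in-class vs not x set A vs set B).
    """
    lnc_a, lnc_b = list(lnc_a), list(lnc_b)
    if not lnc_a or not lnc_b:
        raise ValueError("both lncRNA sets must be non-empty")
    report: dict = {"n_a": len(lnc_a), "n_b": len(lnc_b), "features": {}}

    for feature, getter in (("length", lambda g: g.length),
                            ("exon_count", lambda g: g.n_exons)):
        va = np.array([getter(g) for g in lnc_a], dtype=float)
        vb = np.array([getter(g) for g in lnc_b], dtype=float)
        mean_a, sem_a = _mean_sem(va)
        mean_b, sem_b = _mean_sem(vb)
        u, p = mann_whitney_u(va, vb)
        report["features"][feature] = {
            "mean_a": mean_a, "sem_a": sem_a,
            "mean_b": mean_b, "sem_b": sem_b,
            "U": u, "p": p,
        }

    if coding is not None:
        classes_a = [c.position_class for c in classify_all(lnc_a, coding)]
        classes_b = [c.position_class for c in classify_all(lnc_b, coding)]
        report["position_classes"] = {}
        for cls in POSITION_CLASSES:
            ka = sum(1 for c in classes_a if c == cls)
            kb = sum(1 for c in classes_b if c == cls)
            entry = {"count_a": ka, "count_b": kb,
                     "prop_a": ka / len(lnc_a), "prop_b": kb / len(lnc_b)}
            table = [[ka, len(lnc_a) - ka], [kb, len(lnc_b) - kb]]
            try:
                odds, p = fisher_exact(table)
                entry["odds_ratio"], entry["fisher_p"] = odds, p
            except ValueError:
                entry["odds_ratio"], entry["fisher_p"] = float("nan"), float("nan")
            report["position_classes"][cls] = entry
    return report
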