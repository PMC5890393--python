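"""Co-expression networks over developmental stages, with lncRNA hubs.

Edges connect differentially expressed genes whose expression profiles
across stages correlate strongly (r >= 0.95 or r <= -0.95, both inclusive)
with a nominally significant p-value (p < 0.05, strict).  Correlations are
Pearson on log2(normalized + 1) profiles by default; Spearman is available.
A module is the ego network of one lncRNA hub: the coding genes directly
connected to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CODING, LNCRNA, ExpressionMatrix

logger = logging.getLogger("spongelnc")

R_POSITIVE = 0.95
R_NEGATIVE = -0.95
EDGE_P_MAX = 0.05


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson/Spearman r via the t transform, n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def edge_criterion(r: float, p: float, r_pos: float = R_POSITIVE,
                   r_neg: float = R_NEGATIVE, p_max: float = EDGE_P_MAX) -> bool:
    """Keep an edge iff (r >= r_pos or r <= r_neg) and p < p_max.

    The correlation thresholds are inclusive; the p threshold is strict.
    """
    return bool(((r >= r_pos) or (r <= r_neg)) and (p < p_max))


def correlation_with_p(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation of two equal-length profiles with a two-sided p-value.

    Constant profiles have no defined correlation: (nan, nan) is returned
    and a warning logged so callers can skip the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("profiles must have length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant profile: correlation undefined, pair skipped")
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(_corr_p(np.array([r]), x.size)[0])


@dataclass(frozen=True)
class CoexpressionModule:
    """One lncRNA hub with its directly co-expressed coding genes."""

    hub: str
    members: tuple  # coding gene ids
    species: str = ""
    edges: tuple = ()  # (member, r, p, sign) records

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


def build_network(matrix: ExpressionMatrix, de_genes,
                  r_pos: float = R_POSITIVE, r_neg: float = R_NEGATIVE,
                  p_max: float = EDGE_P_MAX,
                  method: str = "pearson") -> pd.DataFrame:
    """All-pairs co-expression edges among the DE genes.

    Profiles are log2(normalized + 1) across the stage samples.  An edge is
    kept iff (r >= r_pos or r <= r_neg) and p < p_max.  Returns a DataFrame
    with columns gene_a, gene_b (a < b lexicographically), r, p, sign.
    """
    de_genes = sorted(de_genes)
    missing = [g for g in de_genes if g not in matrix.genes]
    if missing:
        raise ValueError(f"DE genes absent from matrix: {missing[:5]}")
    if matrix.normalized is None:
        raise ValueError("normalized counts required; run normalization first")
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("network construction requires >= 3 stages")

    prof = np.log2(matrix.normalized.loc[de_genes].values + 1.0)
    if method == "spearman":
        prof = np.apply_along_axis(stats.rankdata, 1, prof)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    sd = prof.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant profile(s) skipped in network construction",
                       int(constant.sum()))
    keep = ~constant
    genes = [g for g, k in zip(de_genes, keep) if k]
    prof = prof[keep]
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "sign"])

    rmat = np.corrcoef(prof)
    iu, ju = np.triu_indices(len(genes), k=1)
    r = rmat[iu, ju]
    p = _corr_p(r, n)
    hit = np.array([edge_criterion(ri, pi, r_pos, r_neg, p_max)
                    for ri, pi in zip(r, p)])
    if not hit.any():
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "sign"])
    edges = pd.DataFrame({
        "gene_a": [genes[i] for i in iu[hit]],
        "gene_b": [genes[j] for j in ju[hit]],
        "r": r[hit],
        "p": p[hit],
    })
    edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
    return edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def extract_modules(edges: pd.DataFrame, biotypes: dict,
                    species: str = "") -> list[CoexpressionModule]:
    """One module per lncRNA hub: its coding-gene ego network.

    lncRNA-lncRNA edges are retained in the edge table but do not create
    module members; a lncRNA with no coding neighbour yields no module.
    """
    unknown = sorted({g for g in pd.concat([edges["gene_a"], edges["gene_b"]])
                      if g not in biotypes}) if len(edges) else []
    if unknown:
        raise ValueError(f"edge genes without biotype annotation: {unknown[:5]}")
    neighbours: dict[str, list] = {}
    for row in edges.itertuples(index=False):
        for hub, other in ((row.gene_a, row.gene_b), (row.gene_b, row.gene_a)):
            if biotypes[hub] == LNCRNA and biotypes[other] == CODING:
                neighbours.setdefault(hub, []).append(
                    (other, row.r, row.p, row.sign))
    modules = []
    for hub in sorted(neighbours):
        recs = sorted(neighbours[hub])
        modules.append(CoexpressionModule(
            hub=hub, members=tuple(m for m, *_ in recs),
            species=species, edges=tuple(recs)))
    return modules


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_edges_tsv(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sif(edges: pd.DataFrame, path: str) -> None:
    """Simple interaction format: gene_a <coexpression-sign> gene_b."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\t{row.sign}\t{row.gene_b}\n")


def write_graphml(edges: pd.DataFrame, biotypes: dict, path: str) -> None:
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, r=float(row.r), p=float(row.p),
                   sign=row.sign)
    hubs = {n for n in g.nodes if biotypes.get(n) == LNCRNA}
    for n in g.nodes:
        g.nodes[n]["biotype"] = biotypes.get(n, "unknown")
        g.nodes[n]["hub"] = n in hubs
    nx.write_graphml(g, path)


def write_node_attributes(edges: pd.DataFrame, biotypes: dict, path: str) -> None:
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    with open(path, "w") as fh:
        fh.write("gene\tbiotype\thub\n")
        for n in nodes:
            bt = biotypes.get(n, "unknown")
            fh.write(f"{n}\t{bt}\t{str(bt == LNCRNA).lower()}\n")
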