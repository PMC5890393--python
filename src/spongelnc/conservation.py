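"""Cross-species conserved co-expression module calling via coding-gene
homology.

lncRNAs evolve too fast for direct sequence comparison, so conservation of
a lncRNA-hub module is inferred through its coding members: a module pair
(one hub per species) is called putatively conserved when at least one
homologous coding-gene pair (BLASTp-style table, e-value < 1e-5, strict)
links their member sets.  An optional permutation test quantifies how easily
the observed sharing arises from random module membership.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .network import CoexpressionModule

logger = logging.getLogger("spongelnc")

EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class HomologyPair:
    gene_a: str
    gene_b: str
    evalue: float = 0.0
    description: str = ""


@dataclass(frozen=True)
class ConservedModuleMatch:
    module_a: str  # hub lncRNA id, species A
    module_b: str  # hub lncRNA id, species B
    shared_pairs: tuple  # HomologyPair records with members in both modules

    @property
    def n_shared(self) -> int:
        return len(self.shared_pairs)


_UNICODE_MINUS = "−"
_SCI_NOTATION = re.compile(r"^\s*([0-9.]+)\s*[x×*]\s*10\s*\^?\s*([+-]?\d+)\s*$")


def parse_evalue(text) -> float:
    """Parse an E-value, tolerating unicode minus and '1 x 10-5' notation."""
    s = str(text).strip().replace(_UNICODE_MINUS, "-")
    m = _SCI_NOTATION.match(s)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    return float(s)


def load_homology(path: str, evalue_max: float = EVALUE_MAX) -> list[HomologyPair]:
    """Load a homology-pair TSV (gene_a, gene_b[, evalue[, description]]).

    Rows with evalue >= ``evalue_max`` are dropped (the cutoff is a strict
    '<').  Duplicate pairs — including symmetric duplicates — are collapsed,
    keeping the smallest E-value.
    """
    best: dict[tuple, HomologyPair] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("gene_a", "gene_b", "query"):
                continue
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed homology row")
            gene_a, gene_b = parts[0].strip(), parts[1].strip()
            try:
                ev = parse_evalue(parts[2]) if len(parts) > 2 and parts[2].strip() else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad E-value {parts[2]!r}") from exc
            if ev < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            if not ev < evalue_max:
                continue
            desc = parts[3].strip() if len(parts) > 3 else ""
            key = tuple(sorted((gene_a, gene_b)))
            pair = HomologyPair(gene_a, gene_b, ev, desc)
            if key not in best or ev < best[key].evalue:
                best[key] = pair
    return sorted(best.values(), key=lambda p: (p.gene_a, p.gene_b))


def best_hit_only(pairs) -> list[HomologyPair]:
    """Restrict to each species-A gene's lowest-E-value partner (ties kept)."""
    by_a: dict[str, float] = {}
    for p in pairs:
        by_a[p.gene_a] = min(by_a.get(p.gene_a, np.inf), p.evalue)
    return [p for p in pairs if p.evalue == by_a[p.gene_a]]


def match_modules(modules_a, modules_b, homology,
                  min_shared_pairs: int = 1) -> list[ConservedModuleMatch]:
    """Call conserved module pairs: >= ``min_shared_pairs`` homologous
    coding-gene pairs with one member in each module.

    Matches are sorted by shared-pair count (descending), then hub ids.
    """
    matches = []
    for ma in modules_a:
        set_a = ma.member_set
        for mb in modules_b:
            set_b = mb.member_set
            shared = tuple(p for p in homology
                           if p.gene_a in set_a and p.gene_b in set_b)
            if len(shared) >= max(1, min_shared_pairs):
                matches.append(ConservedModuleMatch(ma.hub, mb.hub, shared))
    return sorted(matches, key=lambda m: (-m.n_shared, m.module_a, m.module_b))


def overlap_permutation_p(match: ConservedModuleMatch, modules_a, modules_b,
                          homology, n_perm: int = 1000, seed: int = 0,
                          universe_b=None) -> float:
    """Permutation p-value for a match's shared-pair count.

    Species-B module memberships are redrawn ``n_perm`` times as random
    gene sets of the same size from the species-B gene universe (default:
    the union of all species-B module members); the p-value is the add-one
    smoothed fraction of permutations reaching at least the observed count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mod_a = {m.hub: m for m in modules_a}[match.module_a]
    mod_b = {m.hub: m for m in modules_b}[match.module_b]
    if universe_b is None:
        universe_b = sorted({g for m in modules_b for g in m.members})
    universe_b = np.asarray(sorted(universe_b), dtype=object)
    size_b = len(mod_b.member_set & set(universe_b))
    relevant = [p for p in homology if p.gene_a in mod_a.member_set]
    observed = sum(1 for p in relevant if p.gene_b in mod_b.member_set)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = set(rng.choice(universe_b, size=size_b, replace=False))
        count = sum(1 for p in relevant if p.gene_b in perm)
        if count >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_conserved(matches, path: str | None = None) -> str:
    """Render matches as a per-module table of homologous gene pairs.

    One block per species-A module heading; within a block, rows are
    "<gene_a>-<gene_b><TAB><description>" in deterministic (sorted) order.
    """
    lines = ["module_a\tmodule_b\tgene_pair\tdescription"]
    for m in matches:
        for p in sorted(m.shared_pairs, key=lambda p: (p.gene_a, p.gene_b)):
            lines.append(f"{m.module_a}\t{m.module_b}\t"
                         f"{p.gene_a}-{p.gene_b}\t{p.description}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def conservation_summary(matches, modules_a, modules_b) -> dict:
    conserved_a = sorted({m.module_a for m in matches})
    conserved_b = sorted({m.module_b for m in matches})
    return {
        "n_modules_a": len(list(modules_a)),
        "n_modules_b": len(list(modules_b)),
        "n_matches": len(matches),
        "n_conserved_modules_a": len(conserved_a),
        "n_conserved_modules_b": len(conserved_b),
        "conserved_modules_a": conserved_a,
        "conserved_modules_b": conserved_b,
        "shared_pairs_per_match": {f"{m.module_a}|{m.module_b}": m.n_shared
                                   for m in matches},
    }


# ---------------------------------------------------------------------------
# Published worked example
# ---------------------------------------------------------------------------

def load_published_example():
    """The published three-module worked example, as analysis-ready objects.

    Returns ``(modules_a, modules_b, homology)`` reconstructed from the
    printed table of conserved homologous gene pairs: species A modules are
    the Amphimedon lncRNA headings with their Aqu2.1 coding members,
    species B modules carry synthetic Sycon hub ids (``SciLnc_<heading>``;
    the source names only the Amphimedon hubs) with the scigt coding
    members, and the homology table is exactly the printed pair list.
    """
    ref = resources.files("spongelnc") / "data" / "conserved_module_pairs.tsv"
    with resources.as_file(ref) as p:
        table = pd.read_csv(p, sep="\t", dtype=str)
    modules_a, modules_b, homology = [], [], []
    seen = set()
    for heading in dict.fromkeys(table["module"]):
        block = table[table["module"] == heading]
        members_a = tuple(sorted(set(block["amphimedon_gene"])))
        members_b = tuple(sorted(set(block["sycon_gene"])))
        modules_a.append(CoexpressionModule(hub=heading, members=members_a,
                                            species="Amphimedon"))
        modules_b.append(CoexpressionModule(hub=f"SciLnc_{heading}",
                                            members=members_b, species="Sycon"))
        for row in block.itertuples(index=False):
            key = (row.amphimedon_gene, row.sycon_gene)
            if key not in seen:
                seen.add(key)
                homology.append(HomologyPair(row.amphimedon_gene, row.sycon_gene,
                                             0.0, row.description))
    homology.sort(key=lambda p: (p.gene_a, p.gene_b))
    return modules_a, modules_b, homology
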