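"""Conserved-gene supermatrix construction and neighbor-joining phylogeny.

Per-gene alignment blocks (aligned externally, e.g. with MAFFT) are
concatenated column-wise into a supermatrix with per-block gap padding for
absent taxa. Pairwise distances use the p-distance by default (the fraction
of differing sites among pairwise comparable, gap/N-free sites) or the JC69
correction -(3/4)ln(1 - 4p/3). Trees come from the canonical agglomerative
neighbor-joining algorithm (Q-criterion) with bootstrap support from column
resampling. Maximum-likelihood and Bayesian searches are out of scope; the
supermatrix can be exported (PHYLIP/NEXUS) for external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .model import FeatureTable, Mitogenome, MitokitError
from .sequtils import splice_feature

logger = logging.getLogger(__name__)

#: The conserved protein-coding genes shared and consistently annotated
#: across Ophiocordycipitaceae mitogenomes; runtime-configurable.
DEFAULT_CONSERVED_PCGS = ("ATP8", "COX2", "NAD2", "NAD3", "NAD4L")

# Common mitochondrial gene-symbol synonyms, normalised after uppercasing
# and stripping spaces/hyphens/underscores.
_GENE_SYNONYMS = {
    "CO1": "COX1", "COI": "COX1", "CO2": "COX2", "COII": "COX2",
    "CO3": "COX3", "COIII": "COX3", "CYTB": "COB", "CYB": "COB",
    "ND1": "NAD1", "ND2": "NAD2", "ND3": "NAD3", "ND4": "NAD4",
    "ND4L": "NAD4L", "ND5": "NAD5", "ND6": "NAD6",
    "ATPASE8": "ATP8", "ATP6": "ATP6",
}


def normalize_gene_symbol(name: str) -> str:
    key = name.upper().replace(" ", "").replace("-", "").replace("_", "")
    return _GENE_SYNONYMS.get(key, key)


@dataclass
class GeneAlignmentBlock:
    """One gene's aligned sequences across taxa."""

    gene_name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise MitokitError(f"block {self.gene_name!r}: duplicate taxa")
        if len(self.taxa) != len(self.rows):
            raise MitokitError(f"block {self.gene_name!r}: taxa/rows mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise MitokitError(f"block {self.gene_name!r}: unequal row lengths")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class Supermatrix:
    """Concatenated gene blocks with a partition table (1-based inclusive)."""

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def block(self, gene_name: str) -> GeneAlignmentBlock:
        """Slice one partition back out (round-trip check for concatenation)."""
        for (g, s, e) in self.partitions:
            if g == gene_name:
                return GeneAlignmentBlock(
                    gene_name=g,
                    taxa=list(self.taxa),
                    rows=[r[s - 1:e] for r in self.rows],
                )
        raise KeyError(gene_name)

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)} {self.width}"]
        for t, r in zip(self.taxa, self.rows):
            lines.append(f"{t.replace(' ', '_')}  {r}")
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        lines = [
            "#NEXUS", "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.width};",
            "  FORMAT DATATYPE=DNA GAP=- MISSING=N;",
            "  MATRIX",
        ]
        for t, r in zip(self.taxa, self.rows):
            lines.append(f"    {t.replace(' ', '_')}  {r}")
        lines += ["  ;", "END;", "BEGIN SETS;"]
        for (g, s, e) in self.partitions:
            lines.append(f"  CHARSET {g} = {s}-{e};")
        lines += ["END;"]
        return "\n".join(lines) + "\n"


def extract_conserved_pcgs(
    genomes: Sequence[Mitogenome],
    feature_tables: Sequence[FeatureTable],
    gene_list: Sequence[str] = DEFAULT_CONSERVED_PCGS,
) -> dict[str, dict[str, str]]:
    """Spliced, orientation-corrected sequences per conserved gene per taxon.

    A taxon lacking a gene's annotation is dropped from that gene's set with
    a logged warning (it stays in every other set).
    """
    out: dict[str, dict[str, str]] = {normalize_gene_symbol(g): {} for g in gene_list}
    for genome, table in zip(genomes, feature_tables):
        by_symbol = {normalize_gene_symbol(f.name): f for f in table}
        for gene in gene_list:
            symbol = normalize_gene_symbol(gene)
            feature = by_symbol.get(symbol)
            if feature is None:
                logger.warning(
                    "taxon %s lacks an annotation for %s; dropped from that block",
                    genome.id, gene,
                )
                continue
            out[symbol][genome.id] = splice_feature(genome, feature)
    return out


def concatenate_blocks(blocks: Sequence[GeneAlignmentBlock]) -> Supermatrix:
    """Column-wise concatenation with gap padding for taxa absent from a block."""
    taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    col = 1
    for b in blocks:
        w = b.width
        row_of = dict(zip(b.taxa, b.rows))
        for t in taxa:
            parts[t].append(row_of.get(t, "-" * w))
        partitions.append((b.gene_name, col, col + w - 1))
        col += w
    return Supermatrix(
        taxa=taxa,
        rows=["".join(parts[t]) for t in taxa],
        partitions=partitions,
    )


# ------------------------------------------------------------- distances

def _encode(rows: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    return arr


def distance_matrix(
    supermatrix: Supermatrix | GeneAlignmentBlock,
    model: str = "p",
    gap_handling: str = "pairwise",
) -> pd.DataFrame:
    """Pairwise p-distance or JC69 matrix.

    Sites with a gap or N in either member of a pair are excluded for that
    pair (pairwise deletion); ``gap_handling="complete"`` instead drops any
    column containing a gap/N in any taxon before comparing.
    """
    taxa = supermatrix.taxa
    if len(taxa) < 2:
        raise MitokitError("distance matrix needs >= 2 taxa")
    if model not in ("p", "jc69"):
        raise MitokitError(f"unknown distance model {model!r}")
    arr = _encode(supermatrix.rows)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    if gap_handling == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    elif gap_handling != "pairwise":
        raise MitokitError(f"unknown gap handling {gap_handling!r}")
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise MitokitError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable sites"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if model == "jc69":
                if p >= 0.75:
                    raise MitokitError(
                        f"JC69 undefined for p={p:.3f} between "
                        f"{taxa[i]!r} and {taxa[j]!r}"
                    )
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=list(taxa), columns=list(taxa))


# ------------------------------------------------------------- NJ

class PhyloTree:
    """A phylogenetic tree with branch lengths and optional edge supports.

    Thin wrapper over a dendropy Tree; ``as_newick()`` round-trips and
    internal-node labels carry bootstrap support percentages.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(
            dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=False)
        )

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return sorted(
            lf.taxon.label for lf in self._tree.leaf_node_iter() if lf.taxon
        )

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side excluding the
        alphabetically first leaf."""
        leaves = set(self.leaf_labels())
        anchor = min(leaves)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = {
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon
            }
            side = clade if anchor not in clade else leaves - clade
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(frozenset(side))
        return out

    def has_split(self, taxon_set: Iterable[str]) -> bool:
        """Does the unrooted tree contain the split taxon_set | complement?"""
        leaves = set(self.leaf_labels())
        taxa = set(taxon_set)
        if not taxa <= leaves:
            raise MitokitError("taxon set contains non-leaves")
        anchor = min(leaves)
        side = taxa if anchor not in taxa else leaves - taxa
        return frozenset(side) in self.bipartitions()

    def is_monophyletic(self, taxon_set: Iterable[str], outgroup: str) -> bool:
        """Do the taxa form a complete clade once rooted at the outgroup?"""
        taxon_set = set(taxon_set)
        leaves = set(self.leaf_labels())
        if outgroup not in leaves:
            raise MitokitError(f"outgroup {outgroup!r} is not a leaf")
        if not taxon_set <= leaves - {outgroup}:
            raise MitokitError("taxon set must be leaves excluding the outgroup")
        if len(taxon_set) <= 1 or taxon_set == leaves - {outgroup}:
            return True
        anchor = min(leaves)
        side = taxon_set if anchor not in taxon_set else leaves - taxon_set
        # rooted at the outgroup, taxon_set is a clade iff {taxon_set,
        # complement} is a bipartition of the unrooted tree (the outgroup
        # lies in the complement by construction).
        return frozenset(side) in self.bipartitions()


def nj_tree(dist: pd.DataFrame) -> PhyloTree:
    """Neighbor joining (Saitou-Nei Q-criterion) on a distance matrix.

    Deterministic: ties in Q are broken by smallest index pair. Negative
    branch lengths are clamped to zero. Returns an unrooted tree (a
    trifurcation at the last join for >= 3 taxa; for 2 taxa each leaf gets
    half the pairwise distance).
    """
    taxa = list(dist.index)
    D = dist.to_numpy(dtype=float).copy()
    n = len(taxa)
    if n < 2:
        raise MitokitError("NJ needs >= 2 taxa")
    nodes = [str(t) for t in taxa]

    def clamp(x: float) -> float:
        return max(0.0, float(x))

    while n > 3:
        r = D.sum(axis=1)
        best, bi, bj = None, -1, -1
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, bi, bj = q, i, j
        li = clamp(0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (n - 2)))
        lj = clamp(D[bi, bj] - (0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (n - 2))))
        new_node = f"({nodes[bi]}:{li:.10g},{nodes[bj]}:{lj:.10g})"
        new_row = 0.5 * (D[bi] + D[bj] - D[bi, bj])
        keep = [k for k in range(n) if k not in (bi, bj)]
        D_new = np.zeros((n - 1, n - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = new_row[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [new_node]
        n -= 1

    if n == 2:
        d = D[0, 1]
        newick = f"({nodes[0]}:{clamp(d / 2):.10g},{nodes[1]}:{clamp(d / 2):.10g});"
    else:
        la = clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
        lb = clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
        lc = clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
        newick = (
            f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"
        )
    return PhyloTree.from_newick(newick)


def bootstrap(
    supermatrix: Supermatrix,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
    gap_handling: str = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_reps`` times with a seeded
    generator; the support of each internal edge of the full-data tree is
    the percentage of replicate trees containing the same bipartition.
    Reproducible bit-for-bit for a fixed seed.
    """
    if n_reps < 1:
        raise MitokitError("n_reps must be >= 1")
    main = nj_tree(distance_matrix(supermatrix, model, gap_handling))
    rng = np.random.default_rng(seed)
    width = supermatrix.width
    counts: dict[frozenset[str], int] = {bp: 0 for bp in main.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rows = ["".join(r[c] for c in cols) for r in supermatrix.rows]
        rep = Supermatrix(taxa=list(supermatrix.taxa), rows=rows)
        rep_tree = nj_tree(distance_matrix(rep, model, gap_handling))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    leaves = set(main.leaf_labels())
    anchor = min(leaves)
    for node in main.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
        side = clade if anchor not in clade else leaves - clade
        key = frozenset(side)
        if key in counts:
            node.label = f"{100.0 * counts[key] / n_reps:g}"
    return main


def is_monophyletic(tree: PhyloTree, taxon_set: Iterable[str], outgroup: str) -> bool:
    return tree.is_monophyletic(taxon_set, outgroup)
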