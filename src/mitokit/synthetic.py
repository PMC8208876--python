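"""Synthetic mitogenome-like fixtures with ground-truth manifests.

Everything the analysis stages consume can be generated here with a known
answer: genomes at a target GC with planted perfect SSRs and screened
(SSR-free) flanks, gene tables with nested intronic ORFs, strain panels
carrying a known set of substitution and indel events (built directly in
alignment space, so the true alignment is exact by construction and no
aligner is involved), and supermatrices evolved along a known tree under
Jukes-Cantor substitution.

Defaults emulate the statistical structure of fungal endosymbiont
mitogenomes: ~30% GC, tens of kilobases, short SSRs, and panels of five
near-identical strains carrying a handful of events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .model import (
    FeatureTable,
    GeneFeature,
    Mitogenome,
    MitokitError,
    SSRRecord,
    SSR_TYPE_BY_UNIT_LEN,
    StrainAlignment,
    VariantEvent,
)
from .phylo import GeneAlignmentBlock, PhyloTree, Supermatrix, concatenate_blocks
from .ssr import REJECTED, SSRConfig, TandemRepeat, classify_ssr, find_ssrs, is_primitive

_ALPHABET = np.array(list("ACGT"))

#: GC fraction of the endosymbiont mitogenomes this generator emulates.
DEFAULT_GC = 0.307


# ------------------------------------------------------------- genomes

def generate_genome(
    length: int, gc_target: float = DEFAULT_GC, seed: int = 0, genome_id: str = "synthetic"
) -> Mitogenome:
    """An i.i.d. random genome with P(G)+P(C) = gc_target."""
    if length < 1000:
        raise MitokitError("generate_genome: length must be >= 1000")
    if not (0.0 <= gc_target <= 1.0):
        raise MitokitError("generate_genome: gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    seq = "".join(rng.choice(_ALPHABET, size=length, p=p))
    return Mitogenome(id=genome_id, sequence=seq, circular=True)


# ------------------------------------------------------------- SSR planting

@dataclass
class SyntheticManifest:
    """Ground truth for a generated fixture; replaying (seed, specs) is exact."""

    seed: int
    genome_length: int = 0
    gc_target: float = DEFAULT_GC
    planted_ssrs: list[SSRRecord] = field(default_factory=list)
    planted_features: Optional[FeatureTable] = None
    planted_events: list[VariantEvent] = field(default_factory=list)
    generating_tree: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "gc_target": self.gc_target,
            "planted_ssrs": [
                {
                    "unit": r.unit, "copy_number": r.copy_number,
                    "start": r.start, "end": r.end, "category": r.category,
                }
                for r in self.planted_ssrs
            ],
            "planted_events": [
                {
                    "vtype": e.vtype, "msa_start": e.msa_start,
                    "msa_end": e.msa_end, "carriers": sorted(e.carriers),
                    "base_change": e.base_change,
                }
                for e in self.planted_events
            ],
            "generating_tree": self.generating_tree,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def plant_ssrs(
    genome: Mitogenome,
    ssr_specs: Sequence[tuple[str, int]],
    seed: int = 0,
    config: SSRConfig | None = None,
    max_retries: int = 100,
) -> tuple[Mitogenome, SyntheticManifest]:
    """Embed perfect repeats into a genome and screen everything else.

    Each spec is ``(unit, copy_number)``; specs must classify into one of
    the three tiers under ``config``. Repeats are written at random
    collision-free positions (flanks of at least one unit length plus
    margin), then the whole sequence is screened: any scanner hit that is
    not a planted record has its span re-sampled, repeatedly, until a full
    scan detects exactly the planted set. Raises after ``max_retries``
    screening passes.
    """
    config = config or SSRConfig()
    rng = np.random.default_rng(seed)
    n = len(genome)
    p = np.array(
        [(1 - DEFAULT_GC) / 2, DEFAULT_GC / 2, DEFAULT_GC / 2, (1 - DEFAULT_GC) / 2]
    )

    planted: list[tuple[int, int, str, int]] = []   # (start0, end0, unit, copies)
    for unit, copies in ssr_specs:
        unit = unit.upper()
        if not is_primitive(unit):
            raise MitokitError(f"planted unit {unit!r} is not primitive")
        cand = TandemRepeat(unit, copies, 1, len(unit) * copies, 0)
        if classify_ssr(cand, config) == REJECTED:
            raise MitokitError(
                f"spec {unit!r} x {copies} would be rejected by the classifier"
            )

    seq = list(genome.sequence)
    margin = 12  # screened flank: > one unit length for every allowed unit
    for unit, copies in ssr_specs:
        span = len(unit) * copies
        placed = False
        for _ in range(max_retries * 10):
            start0 = int(rng.integers(margin, n - span - margin))
            lo, hi = start0 - margin, start0 + span + margin
            if all(not (lo <= s_end and s_start <= hi) for (s_start, s_end, _, _) in planted):
                seq[start0:start0 + span] = list(unit * copies)
                planted.append((start0, start0 + span - 1, unit, copies))
                placed = True
                break
        if not placed:
            raise MitokitError(
                f"could not place {unit!r} x {copies} within the retry budget"
            )
    planted.sort()

    protected = np.zeros(n, dtype=bool)
    for (s0, e0, _, _) in planted:
        protected[s0:e0 + 1] = True
    expected = {(s0 + 1, e0 + 1, u, c) for (s0, e0, u, c) in planted}

    for _ in range(max_retries):
        catalog = find_ssrs("".join(seq), config, genome_id=genome.id)
        found = {(r.start, r.end, r.unit, r.copy_number) for r in catalog}
        if found == expected:
            new_genome = Mitogenome(
                id=genome.id, sequence="".join(seq), circular=genome.circular,
                source_accession=genome.source_accession,
            )
            records = [
                SSRRecord(
                    ssr_id="", category=classify_ssr(
                        TandemRepeat(u, c, s, e, 0), config
                    ),
                    ssr_type=SSR_TYPE_BY_UNIT_LEN[len(u)],
                    unit=u, copy_number=c, start=s, end=e, genome_id=genome.id,
                )
                for (s, e, u, c) in sorted(expected)
            ]
            manifest = SyntheticManifest(
                seed=seed, genome_length=n, planted_ssrs=records
            )
            return new_genome, manifest
        # re-sample the offending spans (one base of margin), skipping
        # planted positions
        for key in found - expected:
            s, e = key[0] - 1, key[1] - 1
            for pos in range(max(0, s - 1), min(n, e + 2)):
                if not protected[pos]:
                    seq[pos] = str(rng.choice(_ALPHABET, p=p))
        # a planted record can only be missing if an accidental overlap beat
        # it in conflict resolution; the resampling above already repairs the
        # offending flanks.
    raise MitokitError("screening did not converge within the retry budget")


# ------------------------------------------------------------- feature tables

def generate_feature_table(
    genome_length: int, seed: int = 0, genome_id: str = "synthetic"
) -> FeatureTable:
    """A small annotation with single- and multi-exon genes, a nested
    intronic ORF (the LAGLIDADG-endonuclease pattern), a tRNA, and an rRNA.

    Top-level gene spans are non-overlapping; one multi-exon CDS carries a
    nested CDS wholly inside its intron.
    """
    if genome_length < 12000:
        raise MitokitError("generate_feature_table needs >= 12 kb")
    rng = np.random.default_rng(seed)
    features: list[GeneFeature] = []
    cursor = int(rng.integers(200, 400))

    def advance(span: int) -> tuple[int, int]:
        nonlocal cursor
        start = cursor + int(rng.integers(150, 400))
        end = start + span - 1
        cursor = end
        return start, end

    # host gene with two exons and a nested ORF inside the intron
    s, e = advance(3000)
    exon1 = (s, s + 599)
    exon2 = (e - 899, e)
    features.append(
        GeneFeature("COX1", "CDS", s, e, "reverse", 2, [exon1, exon2])
    )
    orf_start = exon1[1] + 150
    orf_end = orf_start + 509
    features.append(
        GeneFeature(
            "LAGLIDADG endonuclease", "CDS", orf_start, orf_end, "reverse", 1,
            nested_in_intron_of="COX1",
        )
    )
    s, e = advance(900)
    features.append(GeneFeature("NAD2", "CDS", s, e, "reverse", 1))
    s, e = advance(450)
    features.append(GeneFeature("NAD3", "CDS", s, e, "forward", 1))
    s, e = advance(300)
    features.append(GeneFeature("ATP8", "CDS", s, e, "reverse", 1))
    s, e = advance(72)
    features.append(GeneFeature("tRNA-Glu", "tRNA", s, e, "reverse", 1))
    s, e = advance(1400)
    features.append(
        GeneFeature("Small subunit rRNA", "rRNA", s, e, "reverse", 1)
    )
    s, e = advance(276)
    features.append(GeneFeature("NAD4L", "CDS", s, e, "reverse", 1))
    s, e = advance(894)
    features.append(GeneFeature("COX2", "CDS", s, e, "reverse", 1))
    if cursor >= genome_length:
        raise MitokitError("genome too short for the generated layout")
    return FeatureTable(genome_id=genome_id, features=features)


# ------------------------------------------------------------- strain panels

@dataclass
class VariantSpec:
    """One event to plant, in alignment coordinates.

    For insertions, ``carrier_allele`` holds the inserted bases and the
    span is ``msa_start .. msa_start+len-1``. For deletions and SNPs,
    ``ref_allele`` (optional) forces the ancestral bases at the site.
    """

    vtype: str
    msa_start: int
    carriers: frozenset[str]
    carrier_allele: str = ""
    ref_allele: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        self.carriers = frozenset(self.carriers)
        if self.vtype == "insertion":
            if not self.carrier_allele:
                raise MitokitError("insertion spec needs carrier_allele bases")
            self.length = len(self.carrier_allele)
        elif self.vtype == "deletion":
            if self.ref_allele:
                self.length = len(self.ref_allele)
            if self.length < 1:
                raise MitokitError("deletion spec needs ref_allele or length")
        elif self.vtype == "SNP":
            if len(self.carrier_allele) != 1:
                raise MitokitError("SNP spec needs a single carrier base")
            self.length = 1
        else:
            raise MitokitError(f"unknown event type {self.vtype!r}")

    @property
    def msa_end(self) -> int:
        return self.msa_start + self.length - 1


def derive_strain_panel(
    genome: Mitogenome,
    event_specs: Sequence[VariantSpec],
    strain_ids: Sequence[str],
    seed: int = 0,
) -> tuple[StrainAlignment, SyntheticManifest]:
    """Build the true multi-strain alignment carrying exactly the given events.

    Events are placed in alignment coordinates, so the alignment is exact by
    construction; the column-majority consensus equals the ancestral genome
    (with gaps at insertion columns), which requires every carrier set to be
    a strict minority of the strains.
    """
    strain_ids = list(strain_ids)
    if len(strain_ids) < 2:
        raise MitokitError("a panel needs >= 2 strains")
    n = len(strain_ids)
    specs = sorted(event_specs, key=lambda s: s.msa_start)
    prev = None
    for sp in specs:
        if not sp.carriers <= set(strain_ids):
            raise MitokitError(f"carriers {sorted(sp.carriers)} not all in panel")
        if len(sp.carriers) > (n - 1) // 2:
            raise MitokitError(
                "carrier sets must be strict minorities for consensus == ancestor"
            )
        if prev is not None and sp.msa_start <= prev.msa_end:
            raise MitokitError("overlapping event specs")
        if (
            prev is not None
            and sp.msa_start == prev.msa_end + 1
            and sp.vtype == prev.vtype
            and sp.carriers == prev.carriers
        ):
            raise MitokitError(
                "adjacent same-type same-carrier specs would merge on calling"
            )
        prev = sp

    ins_len = sum(sp.length for sp in specs if sp.vtype == "insertion")
    aligned_length = len(genome) + ins_len
    if specs and specs[-1].msa_end > aligned_length:
        raise MitokitError("event spec beyond the alignment end")

    ancestor = list(genome.sequence)
    consensus = []
    rows = {sid: [] for sid in strain_ids}
    by_col: dict[int, tuple[VariantSpec, int]] = {}
    for sp in specs:
        for k in range(sp.length):
            by_col[sp.msa_start + k] = (sp, k)

    gpos = 0  # 0-based ancestor pointer
    for col in range(1, aligned_length + 1):
        hit = by_col.get(col)
        if hit is not None and hit[0].vtype == "insertion":
            sp, k = hit
            consensus.append("-")
            for sid in strain_ids:
                rows[sid].append(sp.carrier_allele[k] if sid in sp.carriers else "-")
            continue
        base = ancestor[gpos]
        if hit is not None:
            sp, k = hit
            if sp.ref_allele:
                base = sp.ref_allele[k]
                ancestor[gpos] = base
            if sp.vtype == "SNP" and base == sp.carrier_allele:
                raise MitokitError(
                    f"SNP spec at column {col}: ancestor base equals the "
                    "carrier allele; give ref_allele"
                )
        consensus.append(base)
        for sid in strain_ids:
            if hit is None or sid not in hit[0].carriers:
                rows[sid].append(base)
            elif hit[0].vtype == "SNP":
                rows[sid].append(hit[0].carrier_allele)
            else:  # deletion
                rows[sid].append("-")
        gpos += 1

    aln = StrainAlignment(
        strain_ids=strain_ids, rows=["".join(rows[sid]) for sid in strain_ids]
    )
    events = [
        VariantEvent(
            vtype=sp.vtype,
            msa_start=sp.msa_start,
            msa_end=sp.msa_end,
            carriers=sp.carriers,
            consensus_allele=(
                "-" if sp.vtype == "insertion"
                else "".join(consensus[sp.msa_start - 1:sp.msa_end])
            ),
            carrier_allele="-" if sp.vtype == "deletion" else sp.carrier_allele,
        )
        for sp in specs
    ]
    manifest = SyntheticManifest(
        seed=seed, genome_length=len(genome), planted_events=events
    )
    return aln, manifest


def random_panel_specs(
    genome: Mitogenome,
    strain_ids: Sequence[str],
    n_events: int,
    seed: int = 0,
) -> list[VariantSpec]:
    """Random non-interacting event specs for recovery testing."""
    rng = np.random.default_rng(seed)
    strain_ids = list(strain_ids)
    n = len(strain_ids)
    max_carriers = max(1, (n - 1) // 2)
    specs: list[VariantSpec] = []
    taken: list[tuple[int, int]] = []
    margin = 2
    attempts = 0
    while len(specs) < n_events and attempts < 1000:
        attempts += 1
        vtype = str(rng.choice(["SNP", "insertion", "deletion"]))
        length = 1 if vtype == "SNP" else int(rng.integers(1, 11))
        start = int(rng.integers(margin + 1, len(genome) - length - margin))
        end = start + length - 1
        if any(start <= e + margin and s - margin <= end for (s, e) in taken):
            continue
        k = int(rng.integers(1, max_carriers + 1))
        carriers = frozenset(rng.choice(strain_ids, size=k, replace=False).tolist())
        if vtype == "SNP":
            ref = str(rng.choice(_ALPHABET))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            specs.append(VariantSpec("SNP", start, carriers, alt, ref))
        elif vtype == "insertion":
            allele = "".join(rng.choice(_ALPHABET, size=length))
            specs.append(VariantSpec("insertion", start, carriers, allele))
        else:
            specs.append(VariantSpec("deletion", start, carriers, length=length))
        taken.append((start, end))
    if len(specs) < n_events:
        raise MitokitError("could not place the requested number of events")
    # re-map starts to alignment coordinates: columns shift right by the
    # total length of insertions placed before them.
    specs.sort(key=lambda s: s.msa_start)
    shift = 0
    for sp in specs:
        sp.msa_start += shift
        if sp.vtype == "insertion":
            shift += sp.length
    return specs


#: The study panel: five strains, 2 SNPs + 3 insertions + 2 deletions with
#: the published alignment coordinates, carriers, and alleles.
WBPH_STRAINS = ("KR", "KR.1D", "KR.5D", "KR.11D", "WGS")


def wbph_panel_specs() -> list[VariantSpec]:
    return [
        VariantSpec("insertion", 4209, frozenset({"KR.1D", "KR.5D"}), "CC"),
        VariantSpec("insertion", 27476, frozenset({"KR.1D"}), "TGGGCCCCCC"),
        VariantSpec("SNP", 27487, frozenset({"KR.1D"}), "C", "A"),
        VariantSpec("deletion", 32727, frozenset({"KR.5D"}), ref_allele="CC"),
        VariantSpec("SNP", 37574, frozenset({"KR.5D"}), "T", "A"),
        VariantSpec("insertion", 38727, frozenset({"KR.1D"}), "G"),
        VariantSpec("deletion", 38728, frozenset({"KR.5D"}), ref_allele="GGG"),
    ]


# ------------------------------------------------------------- supermatrices

def _as_dendropy(tree) -> dendropy.Tree:
    if isinstance(tree, PhyloTree):
        return tree.dendropy_tree
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def simulate_supermatrix(
    tree,
    block_lengths: dict[str, int] | Sequence[int],
    subst_rate: float = 1.0,
    seed: int = 0,
) -> tuple[list[GeneAlignmentBlock], Supermatrix]:
    """Evolve gap-free gene blocks along a tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site scaled by
    ``subst_rate``; per edge the per-site change probability is
    (3/4)(1 - exp(-4 rate t / 3)), with the replacement base uniform over
    the other three. Multifurcating trees are accepted.
    """
    if subst_rate <= 0:
        raise MitokitError("subst_rate must be > 0")
    dtree = _as_dendropy(tree)
    rng = np.random.default_rng(seed)
    if isinstance(block_lengths, dict):
        items = list(block_lengths.items())
    else:
        items = [(f"gene{i+1}", L) for i, L in enumerate(block_lengths)]
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    blocks: list[GeneAlignmentBlock] = []
    for gene, L in items:
        seqs: dict[int, np.ndarray] = {}
        root = dtree.seed_node
        seqs[id(root)] = rng.integers(0, 4, size=L)
        for node in dtree.preorder_node_iter():
            if node is root:
                continue
            parent_seq = seqs[id(node.parent_node)]
            t = (node.edge.length or 0.0) * subst_rate
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            child = parent_seq.copy()
            hit = rng.random(L) < p_change
            if hit.any():
                child[hit] = (
                    child[hit] + rng.integers(1, 4, size=int(hit.sum()))
                ) % 4
            seqs[id(node)] = child
        rows = []
        for lf in dtree.leaf_node_iter():
            rows.append("".join(_ALPHABET[seqs[id(lf)]]))
        blocks.append(GeneAlignmentBlock(gene_name=gene, taxa=list(leaves), rows=rows))
    return blocks, concatenate_blocks(blocks)
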