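"""Core domain types for mitogenome comparative analysis.

All genomic coordinates are 1-based inclusive throughout the public API,
matching the convention of mitogenome annotation tables and GFF3. Any
half-open arithmetic is internal and never visible at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

VALID_BASES = set("ACGTN")
GAP = "-"

FEATURE_TYPES = ("CDS", "tRNA", "rRNA")

SSR_TYPE_BY_UNIT_LEN = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}

# Catalog id prefixes by unit length, mirroring published SSR-database ids
# (M0000001-style; hepta uses the "cHp" prefix).
SSR_ID_PREFIX = {
    1: "M", 2: "D", 3: "T", 4: "Te", 5: "P",
    6: "H", 7: "cHp", 8: "O", 9: "N", 10: "De",
}


class MitokitError(Exception):
    """Base class for all package errors."""


@dataclass
class Mitogenome:
    """One mitochondrial genome sequence.

    Topology is recorded (fungal mitogenomes are circular molecules) but
    coordinate arithmetic never wraps the origin: no annotated feature in
    the genomes this package targets spans the junction.
    """

    id: str
    sequence: str
    circular: bool = True
    source_accession: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise MitokitError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise MitokitError(
                f"genome {self.id!r}: non-IUPAC DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """An annotated gene interval (1-based inclusive span).

    ``exons`` is optional: published mitogenome gene tables often give the
    span and the exon count but not the exon coordinates. Operations that
    need exon structure (splicing, intron-aware classification) state so.
    ``nested_in_intron_of`` marks an intron-encoded ORF (e.g. a LAGLIDADG
    homing endonuclease inside a host gene's group-I intron).
    """

    name: str
    feature_type: str
    start: int
    end: int
    strand: str = "forward"
    n_exons: int = 1
    exons: Optional[list[tuple[int, int]]] = None
    nested_in_intron_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise MitokitError(
                f"feature {self.name!r}: unknown type {self.feature_type!r}"
            )
        if self.strand not in ("forward", "reverse"):
            raise MitokitError(
                f"feature {self.name!r}: malformed strand {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise MitokitError(
                f"feature {self.name!r}: invalid span {self.start}..{self.end}"
            )
        if self.n_exons < 1:
            raise MitokitError(f"feature {self.name!r}: n_exons must be >= 1")
        if self.exons is not None:
            exons = sorted(tuple(e) for e in self.exons)
            if len(exons) != self.n_exons:
                raise MitokitError(
                    f"feature {self.name!r}: {len(exons)} exon intervals "
                    f"but n_exons={self.n_exons}"
                )
            prev_end = self.start - 1
            for (s, e) in exons:
                if s > e or s < self.start or e > self.end:
                    raise MitokitError(
                        f"feature {self.name!r}: exon {s}..{e} outside span"
                    )
                if s <= prev_end:
                    raise MitokitError(
                        f"feature {self.name!r}: overlapping exons"
                    )
                prev_end = e
            self.exons = exons

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Exon sub-intervals; the full span when none are recorded."""
        if self.exons is not None:
            return list(self.exons)
        return [(self.start, self.end)]

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty without exon detail)."""
        if self.exons is None or len(self.exons) < 2:
            return []
        out = []
        for (a, b) in zip(self.exons, self.exons[1:]):
            if a[1] + 1 <= b[0] - 1:
                out.append((a[1] + 1, b[0] - 1))
        return out


@dataclass
class FeatureTable:
    """Ordered gene annotation for one genome.

    Features are kept sorted by start; duplicate names (multiple
    "LAGLIDADG endonuclease" ORFs, "Hypothetical protein"s) are
    disambiguated with an ordinal suffix so every name is unique.
    """

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: dict[str, int] = {}
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.name] = counts.get(f.name, 0) + 1
        for f in self.features:
            if counts[f.name] > 1:
                seen[f.name] = seen.get(f.name, 0) + 1
                f.name = f"{f.name}_{seen[f.name]}"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class StrainAlignment:
    """A multiple sequence alignment of conspecific whole mitogenomes."""

    strain_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.rows):
            raise MitokitError("strain_ids and rows length mismatch")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise MitokitError("duplicate strain ids in alignment")
        self.rows = [r.upper() for r in self.rows]
        if self.rows:
            width = len(self.rows[0])
            for sid, r in zip(self.strain_ids, self.rows):
                if len(r) != width:
                    raise MitokitError(
                        f"ragged alignment: row {sid!r} has length {len(r)}, "
                        f"expected {width}"
                    )
                bad = set(r) - (VALID_BASES | {GAP})
                if bad:
                    raise MitokitError(
                        f"row {sid!r}: invalid characters {sorted(bad)}"
                    )

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def row(self, strain_id: str) -> str:
        return self.rows[self.strain_ids.index(strain_id)]

    def ungapped(self, strain_id: str) -> str:
        return self.row(strain_id).replace(GAP, "")


@dataclass
class SSRRecord:
    """One perfect tandem repeat accepted by the three-tier classifier."""

    ssr_id: str
    category: str           # normal | extended | potential
    ssr_type: str           # mono .. deca
    unit: str
    copy_number: int
    start: int              # 1-based inclusive
    end: int
    genome_id: str = ""
    position_class: Optional["PositionClass"] = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.unit) * self.copy_number:
            raise MitokitError(
                f"SSR {self.ssr_id or self.unit}: span {self.start}..{self.end} "
                f"inconsistent with {self.unit!r} x {self.copy_number}"
            )
        expected = SSR_TYPE_BY_UNIT_LEN[len(self.unit)]
        if self.ssr_type != expected:
            raise MitokitError(
                f"SSR {self.ssr_id}: type {self.ssr_type!r} but unit length "
                f"{len(self.unit)} implies {expected!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SSRCatalog:
    """All accepted SSRs of one genome, sorted by start."""

    genome_id: str
    records: list[SSRRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class PositionClass:
    """Positional classification of an interval against an annotation."""

    klass: str                       # genic | intronic_orf | intronic | intergenic
    genes: list[str] = field(default_factory=list)
    approximate: bool = False        # True in exon-less two-class mode

    def __post_init__(self) -> None:
        if self.klass == "intergenic" and self.genes:
            raise MitokitError("intergenic classification must list no genes")
        if self.klass != "intergenic" and not self.genes:
            raise MitokitError(f"{self.klass} classification must list genes")


@dataclass
class VariantEvent:
    """One SNP / insertion / deletion in alignment coordinates.

    Polarity is relative to the per-column majority consensus: carriers
    holding bases where the consensus is gapped form an insertion
    ("- to CC"), carriers gapped where the consensus holds bases form a
    deletion ("CC to -").
    """

    vtype: str                       # SNP | insertion | deletion
    msa_start: int                   # 1-based alignment column
    msa_end: int
    carriers: frozenset[str]
    consensus_allele: str
    carrier_allele: str
    position_note: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in ("SNP", "insertion", "deletion"):
            raise MitokitError(f"unknown variant type {self.vtype!r}")
        if self.msa_start > self.msa_end:
            raise MitokitError("msa_start > msa_end")
        if not self.carriers:
            raise MitokitError("variant with empty carrier set")
        self.carriers = frozenset(self.carriers)
        if self.vtype == "SNP":
            if len(self.consensus_allele) != 1 or len(self.carrier_allele) != 1:
                raise MitokitError("SNP alleles must be single bases")
            if GAP in (self.consensus_allele, self.carrier_allele):
                raise MitokitError("SNP alleles may not be gaps")

    @property
    def base_change(self) -> str:
        return f"{self.consensus_allele} to {self.carrier_allele}"


@dataclass
class VariationSummary:
    """Per-panel variation counts and alignment-coverage percentages."""

    n_genomes: int
    aligned_length: int
    n_snps: int
    snp_coverage_pct: float
    n_indels: int                    # gap-bearing polymorphic columns
    indel_coverage_pct: float
    n_indel_events: Optional[int] = None


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Any-overlap (>= 1 shared base) between two 1-based inclusive intervals."""
    return a_start <= b_end and b_start <= a_end
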