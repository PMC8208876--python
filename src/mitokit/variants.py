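"""Intraspecific SNP / INDEL identification from a whole-mitogenome MSA.

The caller works per alignment column against the majority consensus:

* a gap-free polymorphic column yields one SNP event per distinct minority
  allele;
* maximal runs of consecutive columns with the same polymorphic gap pattern
  and carrier set merge into one insertion (consensus gapped, carriers hold
  bases) or deletion (consensus holds bases, carriers gapped) event.

Coverage percentages are taken over alignment columns (aligned length);
"number of INDELs" in that summary is the column count (each column of a
10-column insertion counts), while events are what the variant table lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    FeatureTable,
    GeneFeature,
    Mitogenome,
    MitokitError,
    StrainAlignment,
    VariantEvent,
    VariationSummary,
    interval_overlap,
)
from .positions import classify_interval
from .sequtils import splice_feature, translate_mito

_BASES = set("ACGT")


@dataclass
class CallerConfig:
    reference_strain: Optional[str] = None   # tie-break favourite; default first strain


def _check_alignment(aln: StrainAlignment) -> None:
    if aln.n_strains < 2:
        raise MitokitError("variant calling needs >= 2 strains")
    if aln.aligned_length == 0:
        raise MitokitError("zero-length alignment")


def consensus_sequence(aln: StrainAlignment, config: CallerConfig | None = None) -> str:
    """Per-column majority residue (gap is a residue; N is missing).

    Ties are broken in favour of the designated reference strain's residue,
    then alphabetically ('-' sorts before bases).
    """
    _check_alignment(aln)
    config = config or CallerConfig()
    ref = config.reference_strain or aln.strain_ids[0]
    ref_row = aln.row(ref)
    cols = []
    for c in range(aln.aligned_length):
        counts: dict[str, int] = {}
        for r in aln.rows:
            ch = r[c]
            if ch == "N":
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if not counts:                       # all-N column
            cols.append("N")
            continue
        best = max(counts.values())
        tied = sorted(ch for ch, k in counts.items() if k == best)
        ref_ch = ref_row[c]
        cols.append(ref_ch if ref_ch in tied else tied[0])
    return "".join(cols)


def call_variants(
    aln: StrainAlignment, config: CallerConfig | None = None
) -> list[VariantEvent]:
    """All SNP, insertion, and deletion events relative to the consensus."""
    _check_alignment(aln)
    config = config or CallerConfig()
    cons = consensus_sequence(aln, config)
    L = aln.aligned_length
    events: list[VariantEvent] = []

    # --- SNPs: per column, one event per distinct minority base
    for c in range(L):
        cc = cons[c]
        if cc not in _BASES:
            continue
        by_allele: dict[str, set[str]] = {}
        for sid, row in zip(aln.strain_ids, aln.rows):
            ch = row[c]
            if ch in _BASES and ch != cc:
                by_allele.setdefault(ch, set()).add(sid)
        for allele in sorted(by_allele):
            events.append(
                VariantEvent(
                    vtype="SNP",
                    msa_start=c + 1,
                    msa_end=c + 1,
                    carriers=frozenset(by_allele[allele]),
                    consensus_allele=cc,
                    carrier_allele=allele,
                )
            )

    # --- INDELs: merge maximal runs with identical type + carrier set.
    # N is missing: it never makes a strain a carrier and never breaks a run.
    def column_indel(c: int) -> tuple[str, frozenset[str]] | None:
        cc = cons[c]
        if cc == "-":
            carriers = frozenset(
                sid for sid, row in zip(aln.strain_ids, aln.rows) if row[c] in _BASES
            )
            return ("insertion", carriers) if carriers else None
        carriers = frozenset(
            sid for sid, row in zip(aln.strain_ids, aln.rows) if row[c] == "-"
        )
        return ("deletion", carriers) if carriers else None

    run_start = None
    run_key: tuple[str, frozenset[str]] | None = None
    for c in range(L + 1):
        key = column_indel(c) if c < L else None
        if key == run_key and key is not None:
            continue
        if run_key is not None:
            vtype, carriers = run_key
            s, e = run_start, c - 1
            if vtype == "insertion":
                donor = aln.row(sorted(carriers)[0])
                cons_allele, carr_allele = "-", donor[s:e + 1]
            else:
                cons_allele, carr_allele = cons[s:e + 1], "-"
            events.append(
                VariantEvent(
                    vtype=vtype,
                    msa_start=s + 1,
                    msa_end=e + 1,
                    carriers=carriers,
                    consensus_allele=cons_allele,
                    carrier_allele=carr_allele,
                )
            )
        run_start, run_key = c, key

    events.sort(key=lambda ev: (ev.msa_start, ev.msa_end, ev.vtype, ev.carrier_allele))
    return events


def indel_column_count(aln: StrainAlignment) -> int:
    """Alignment columns whose gap pattern is polymorphic (some gapped, some not)."""
    _check_alignment(aln)
    count = 0
    for c in range(aln.aligned_length):
        col = [row[c] for row in aln.rows]
        if any(ch == "-" for ch in col) and any(ch in _BASES for ch in col):
            count += 1
    return count


def coverage_pct(count: int, aligned_length: int) -> float:
    """Percentage of alignment columns: 100 * count / aligned_length."""
    if aligned_length <= 0:
        raise MitokitError("aligned length must be positive")
    return 100.0 * count / aligned_length


def summarize_variation(
    aln: StrainAlignment, config: CallerConfig | None = None
) -> VariationSummary:
    """Panel-level counts and coverage percentages (full precision)."""
    _check_alignment(aln)
    events = call_variants(aln, config)
    n_snps = sum(1 for e in events if e.vtype == "SNP")
    n_indel_events = len(events) - n_snps
    n_indel_cols = indel_column_count(aln)
    L = aln.aligned_length
    return VariationSummary(
        n_genomes=aln.n_strains,
        aligned_length=L,
        n_snps=n_snps,
        snp_coverage_pct=coverage_pct(n_snps, L),
        n_indels=n_indel_cols,
        indel_coverage_pct=coverage_pct(n_indel_cols, L),
        n_indel_events=n_indel_events,
    )


# ------------------------------------------------------------- annotation

def msa_to_reference_coord(aln: StrainAlignment, reference_strain: str, column: int) -> int:
    """Reference genome coordinate (1-based) of an alignment column.

    Counts non-gap reference bases up to and including the column; for a
    column where the reference is gapped this returns the coordinate of the
    last reference base before it.
    """
    row = aln.row(reference_strain)
    if not (1 <= column <= len(row)):
        raise MitokitError(f"column {column} outside alignment")
    return len(row[:column].replace("-", ""))


def _codon_effect(
    genome: Mitogenome, feature: GeneFeature, genome_pos: int, alt_base: str
) -> str | None:
    """Amino-acid effect of a substitution at genome_pos inside a CDS."""
    exons = feature.exon_intervals()
    offset = 0
    tidx = None
    for (s, e) in exons:
        if s <= genome_pos <= e:
            tidx = offset + (genome_pos - s)
            break
        offset += e - s + 1
    if tidx is None:
        return None                      # position falls in an intron
    transcript = splice_feature(genome, feature)
    if feature.strand == "reverse":
        tidx = len(transcript) - 1 - tidx
        alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_base]
    else:
        alt = alt_base
    usable = len(transcript) - len(transcript) % 3
    if tidx >= usable:
        return None
    ci = tidx // 3
    codon = transcript[ci * 3:ci * 3 + 3]
    mutated = codon[:tidx % 3] + alt + codon[tidx % 3 + 1:]
    aa_ref = translate_mito(codon)
    aa_alt = translate_mito(mutated)
    if aa_ref == aa_alt:
        return f"synonymous in {feature.name}"
    return f"{aa_ref} to {aa_alt} in {feature.name}"


def annotate_variant(
    event: VariantEvent,
    aln: StrainAlignment,
    reference_strain: str,
    table: FeatureTable,
    genome: Mitogenome,
) -> str:
    """Fill the event's position note ("Intergenic", "L to Q in <gene>", ...)."""
    ref_row = aln.row(reference_strain)
    if event.vtype == "SNP" and ref_row[event.msa_start - 1] == "-":
        raise MitokitError(
            "SNP column maps into a reference gap; alignment and reference "
            "are inconsistent"
        )
    g_start = msa_to_reference_coord(aln, reference_strain, event.msa_start)
    g_end = msa_to_reference_coord(aln, reference_strain, event.msa_end)
    g_start = max(g_start, 1)
    g_end = max(g_end, g_start)
    pc = classify_interval(g_start, g_end, table, len(genome))
    if pc.klass == "intergenic":
        note = "Intergenic"
    elif pc.klass == "intronic":
        note = "Intronic"
    else:
        note = ", ".join(pc.genes)
        if event.vtype == "SNP":
            cds_names = {f.name for f in table if f.feature_type == "CDS"}
            for name in pc.genes:
                base = name.removeprefix("(Intron)")
                if base in cds_names and not name.startswith("(Intron)"):
                    effect = _codon_effect(
                        genome, table.by_name(base), g_start, event.carrier_allele
                    )
                    if effect is not None:
                        note = effect
                        break
    event.position_note = note
    return note


def reconstruct_rows(
    consensus: str, events: Sequence[VariantEvent], strain_ids: Sequence[str]
) -> StrainAlignment:
    """Apply events to the consensus to rebuild every strain row.

    Inverse of calling on panels where all carriers of an event share the
    carrier allele (true of the synthetic generator and of clean
    intraspecific panels).
    """
    rows = []
    for sid in strain_ids:
        chars = list(consensus)
        for ev in events:
            if sid not in ev.carriers:
                continue
            if ev.vtype == "deletion":
                repl = "-" * (ev.msa_end - ev.msa_start + 1)
            else:
                repl = ev.carrier_allele
            chars[ev.msa_start - 1:ev.msa_end] = list(repl)
        rows.append("".join(chars))
    return StrainAlignment(strain_ids=list(strain_ids), rows=rows)
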