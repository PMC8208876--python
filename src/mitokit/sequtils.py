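"""Basic sequence utilities: GC content, splicing, mitochondrial translation."""

from __future__ import annotations

from Bio.Data import CodonTable

from .model import FeatureTable, GeneFeature, Mitogenome, MitokitError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(genome: Mitogenome | str) -> float:
    """GC percentage: 100*(G+C)/length.

    N counts in the denominator but never in the numerator. Returns the
    full-precision value; round at the report boundary (the study's tables
    print one decimal).
    """
    seq = genome.sequence if isinstance(genome, Mitogenome) else genome.upper()
    if not seq:
        raise MitokitError("gc_content of empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def summarize_annotation(table: FeatureTable) -> dict[str, int]:
    """Feature counts by type, e.g. {'CDS': 28, 'tRNA': 12, 'rRNA': 2}."""
    if len(table) == 0:
        raise MitokitError("summarize_annotation of empty feature table")
    counts = {"CDS": 0, "tRNA": 0, "rRNA": 0}
    for f in table:
        counts[f.feature_type] += 1
    return counts


def splice_feature(genome: Mitogenome, feature: GeneFeature) -> str:
    """Spliced nucleotide sequence of a feature, 5'->3' in transcript orientation.

    Exon sequences are extracted in genomic order and concatenated;
    reverse-strand features are then reverse-complemented, which is
    equivalent to reading the exons in descending genomic order with each
    complemented. Multi-exon features require exon coordinates.
    """
    if feature.n_exons > 1 and feature.exons is None:
        raise MitokitError(
            f"feature {feature.name!r} has {feature.n_exons} exons but no "
            "exon coordinates; splicing needs them"
        )
    if feature.end > len(genome):
        raise MitokitError(
            f"feature {feature.name!r} extends past genome end "
            f"({feature.end} > {len(genome)}); origin-spanning features are "
            "not supported"
        )
    parts = [genome.sequence[s - 1:e] for (s, e) in feature.exon_intervals()]
    seq = "".join(parts)
    if feature.strand == "reverse":
        seq = reverse_complement(seq)
    return seq


def _build_code(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: The mold/protozoan mitochondrial genetic code (NCBI transl_table 4);
#: notably TGA encodes tryptophan instead of a stop.
MITO_CODE_ID = 4
_MITO_CODE = _build_code(MITO_CODE_ID)


def translate_mito(cds: str, table_id: int = MITO_CODE_ID) -> str:
    """Translate a coding sequence under the mold mitochondrial code.

    Codons containing N (or any non-ACGT base) translate to 'X'; stops
    to '*'. Length must be a multiple of 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise MitokitError(f"CDS length {len(cds)} is not a multiple of 3")
    code = _MITO_CODE if table_id == MITO_CODE_ID else _build_code(table_id)
    return "".join(
        code.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3)
    )
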