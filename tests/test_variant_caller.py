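"""MSA-based SNP/INDEL calling, merging, coverage, and effect annotation."""

import numpy as np
import pytest

import mitokit as mk
from mitokit.model import MitokitError
from mitokit.sequtils import reverse_complement

STRAINS = ["s1", "s2", "s3", "s4", "s5"]


def _aln(rows, ids=None):
    return mk.StrainAlignment(ids or STRAINS[: len(rows)], rows)


# ---------------------------------------------------------------- calling

def test_identical_alignment_yields_nothing():
    aln = _aln(["ACGTACGT"] * 5)
    assert mk.call_variants(aln) == []
    assert mk.indel_column_count(aln) == 0


def test_single_snp_minority_allele():
    aln = _aln(["ACGT", "ACGT", "ACGT", "ACGT", "ACTT"])
    (ev,) = mk.call_variants(aln)
    assert (ev.vtype, ev.msa_start, ev.base_change, set(ev.carriers)) == (
        "SNP", 3, "G to T", {"s5"},
    )


def test_multiallelic_column_emits_one_event_per_allele():
    aln = _aln(["AAAAA", "AAAAA", "AAAAA", "ACAAA", "AGAAA"])
    events = mk.call_variants(aln)
    assert [(e.carrier_allele, set(e.carriers)) for e in events] == [
        ("C", {"s4"}), ("G", {"s5"}),
    ]


def test_insertion_and_deletion_polarity():
    # gap in the minority -> deletion; bases in the minority -> insertion
    deletion = _aln(["ACGT", "ACGT", "AC-T"])
    (ev,) = mk.call_variants(deletion)
    assert (ev.vtype, ev.base_change) == ("deletion", "G to -")
    insertion = _aln(["AC-T", "AC-T", "ACGT"])
    (ev,) = mk.call_variants(insertion)
    assert (ev.vtype, ev.base_change, ev.msa_start) == ("insertion", "- to G", 3)


def test_indel_runs_merge_maximally():
    aln = _aln(["AAATTTCCC", "AAA---CCC", "AAATTTCCC"])
    (ev,) = mk.call_variants(aln)
    assert (ev.vtype, ev.msa_start, ev.msa_end, ev.base_change) == (
        "deletion", 4, 6, "TTT to -",
    )
    # different carriers break the run into two events
    aln2 = _aln(["AAATTTCCC", "AAA--TCCC", "AAATT-CCC"])
    events = mk.call_variants(aln2)
    assert [(e.vtype, e.msa_start, e.msa_end, set(e.carriers)) for e in events] == [
        ("deletion", 4, 5, {"s2"}), ("deletion", 6, 6, {"s3"}),
    ]
    # maximality: no two indel events with identical carriers are adjacent
    for a, b in zip(events, events[1:]):
        assert not (
            a.vtype == b.vtype
            and a.carriers == b.carriers
            and b.msa_start == a.msa_end + 1
        )


def test_n_never_creates_a_snp_and_never_breaks_a_run():
    aln = _aln(["ACGT", "ACGT", "ANGT"])
    assert mk.call_variants(aln) == []
    aln2 = _aln(["ATTTA", "A---A", "ATNTA"])
    (ev,) = mk.call_variants(aln2)
    assert (ev.vtype, ev.msa_start, ev.msa_end) == ("deletion", 2, 4)


def test_row_reorder_invariance():
    genome = mk.generate_genome(3000, seed=42, genome_id="anc")
    specs = mk.random_panel_specs(genome, STRAINS, 6, seed=42)
    aln, _ = mk.derive_strain_panel(genome, specs, STRAINS, seed=42)
    cfg = mk.CallerConfig(reference_strain="s1")
    base = mk.call_variants(aln, cfg)
    order = [3, 0, 4, 1, 2]
    shuffled = mk.StrainAlignment(
        [aln.strain_ids[i] for i in order], [aln.rows[i] for i in order]
    )
    assert mk.call_variants(shuffled, cfg) == base


def test_round_trip_consensus_plus_events_rebuilds_rows():
    genome = mk.generate_genome(4000, seed=7, genome_id="anc")
    specs = mk.random_panel_specs(genome, STRAINS, 8, seed=7)
    aln, _ = mk.derive_strain_panel(genome, specs, STRAINS, seed=7)
    events = mk.call_variants(aln)
    cons = mk.consensus_sequence(aln)
    rebuilt = mk.reconstruct_rows(cons, events, aln.strain_ids)
    assert rebuilt.rows == aln.rows


def test_caller_input_validation():
    with pytest.raises(MitokitError):
        mk.call_variants(_aln(["ACGT"], ids=["only"]))
    with pytest.raises(MitokitError):
        mk.StrainAlignment(["a", "b"], ["ACG", "AC"])


# ---------------------------------------------------------------- summary

def test_indel_column_count_equals_run_length():
    rows = ["A" * 20, "A" * 5 + "-" * 10 + "A" * 5, "A" * 20]
    assert mk.indel_column_count(_aln(rows)) == 10


def test_summary_coverage_uses_alignment_columns():
    genome = mk.generate_genome(2000, seed=3, genome_id="anc")
    specs = mk.random_panel_specs(genome, STRAINS, 5, seed=3)
    aln, manifest = mk.derive_strain_panel(genome, specs, STRAINS, seed=3)
    s = mk.summarize_variation(aln)
    planted_indel_cols = sum(
        e.msa_end - e.msa_start + 1
        for e in manifest.planted_events
        if e.vtype != "SNP"
    )
    assert s.n_indels == planted_indel_cols
    assert s.snp_coverage_pct == pytest.approx(100 * s.n_snps / s.aligned_length)
    assert s.indel_coverage_pct == pytest.approx(100 * s.n_indels / s.aligned_length)


def test_coverage_pct_zero_counts():
    assert mk.coverage_pct(0, 12345) == 0.0
    with pytest.raises(MitokitError):
        mk.coverage_pct(1, 0)


# ---------------------------------------------------------------- annotation

def _effect_panel(genome_seq, spec):
    genome = mk.Mitogenome("anc", genome_seq)
    aln, _ = mk.derive_strain_panel(genome, [spec], STRAINS, seed=0)
    (ev,) = mk.call_variants(aln, mk.CallerConfig(reference_strain="s1"))
    return ev, aln, genome


def test_missense_annotation_forward_strand():
    # codon 2 of a forward CDS is CTA (Leu); A->T... here T->A at its middle
    # turns CTA into CAA (Gln)
    seq = "A" * 100 + "ATG" + "CTA" + "GGT" * 8 + "TAA" + "A" * 100
    table = mk.FeatureTable(
        "anc", [mk.GeneFeature("ATP synthase F0 subunit", "CDS", 101, 133, "forward")]
    )
    spec = mk.VariantSpec("SNP", 105, frozenset({"s3"}), "A", "T")
    ev, aln, genome = _effect_panel(seq, spec)
    note = mk.annotate_variant(ev, aln, "s1", table, genome)
    assert note == "L to Q in ATP synthase F0 subunit"


def test_missense_annotation_reverse_strand():
    transcript = "ATG" + "CTA" + "GGT" * 8 + "TAA"   # 33 nt
    seq = "A" * 100 + reverse_complement(transcript) + "G" * 100
    table = mk.FeatureTable(
        "anc", [mk.GeneFeature("ATP synthase F0 subunit", "CDS", 101, 133, "reverse")]
    )
    # transcript index 4 (middle of codon 2, a T) sits at genome position
    # 133 - 4 = 129 as base A; the L->Q change is A->T in genome space
    spec = mk.VariantSpec("SNP", 129, frozenset({"s3"}), "T", "A")
    ev, aln, genome = _effect_panel(seq, spec)
    note = mk.annotate_variant(ev, aln, "s1", table, genome)
    assert note == "L to Q in ATP synthase F0 subunit"
    assert ev.base_change == "A to T"


def test_synonymous_third_position():
    seq = "A" * 100 + "ATG" + "TTA" + "GGT" * 8 + "TAA" + "A" * 100
    table = mk.FeatureTable("anc", [mk.GeneFeature("NAD2", "CDS", 101, 133, "forward")])
    # TTA -> TTG, both leucine under the mold mitochondrial code
    spec = mk.VariantSpec("SNP", 106, frozenset({"s2"}), "G", "A")
    ev, aln, genome = _effect_panel(seq, spec)
    assert mk.annotate_variant(ev, aln, "s1", table, genome) == "synonymous in NAD2"


def test_intergenic_note():
    seq = "A" * 50 + "CTA" + "A" * 50
    table = mk.FeatureTable("anc", [mk.GeneFeature("NAD2", "CDS", 90, 101, "forward")])
    spec = mk.VariantSpec("SNP", 52, frozenset({"s2"}), "G", "T")
    ev, aln, genome = _effect_panel(seq, spec)
    assert mk.annotate_variant(ev, aln, "s1", table, genome) == "Intergenic"


def test_coordinate_mapping_skips_reference_gaps():
    rows = ["AC--GT", "ACTTGT", "AC--GT"]
    aln = _aln(rows)
    assert mk.msa_to_reference_coord(aln, "s1", 5) == 3
    assert mk.msa_to_reference_coord(aln, "s2", 5) == 5


def test_recovery_on_random_manifests():
    for seed in range(25):
        genome = mk.generate_genome(1500, seed=1000 + seed, genome_id="anc")
        n_events = 2 + seed % 7
        specs = mk.random_panel_specs(genome, STRAINS, n_events, seed=seed)
        aln, manifest = mk.derive_strain_panel(genome, specs, STRAINS, seed=seed)
        called = mk.call_variants(aln, mk.CallerConfig(reference_strain="s1"))
        want = {
            (e.vtype, e.msa_start, e.msa_end, e.carriers, e.base_change)
            for e in manifest.planted_events
        }
        got = {
            (e.vtype, e.msa_start, e.msa_end, e.carriers, e.base_change)
            for e in called
        }
        assert got == want  # precision = recall = 1.0
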