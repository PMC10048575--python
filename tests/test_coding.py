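"""Isoform assembly, three-frame ORF scanning and AS2/NMD classification."""

import copy

import pytest

from exonskip.coding import (
    IsoformVerdict,
    assemble_isoform_sequence,
    classify_event,
    classify_events,
    match_annotated_protein,
    three_frame_orf_scan,
    translate_codons,
)
from exonskip.events import ESEvent
from exonskip.simulate import (
    SyntheticConfig,
    SyntheticGenome,
    expected_event_class,
    generate_gene_models,
    plant_es_truth,
)

from _oracles import has_ptc, revcomp, translate

# ---------------------------------------------------------- assembly -------

GENOME = {"chr1": "ACGTACGTAA" * 20}  # 200 nt

PLUS_EVENT = ESEvent(
    event_id="p",
    gene_id="g",
    chrom="chr1",
    strand="+",
    upstream_exon=(0, 30),
    target_exon=(50, 80),
    downstream_exon=(100, 140),
)

MINUS_EVENT = ESEvent(
    event_id="m",
    gene_id="g",
    chrom="chr1",
    strand="-",
    upstream_exon=(100, 140),
    target_exon=(50, 80),
    downstream_exon=(0, 30),
)


def test_plus_strand_assembly_concatenates_in_genomic_order():
    seq = assemble_isoform_sequence(PLUS_EVENT, GENOME, "included")
    chrom = GENOME["chr1"]
    assert seq == chrom[0:30] + chrom[50:80] + chrom[100:140]


def test_minus_strand_assembly_is_reverse_complement_of_descending_order():
    seq = assemble_isoform_sequence(MINUS_EVENT, GENOME, "included")
    chrom = GENOME["chr1"]
    assert seq == revcomp(chrom[0:30] + chrom[50:80] + chrom[100:140])


def test_skipped_length_identity():
    incl = assemble_isoform_sequence(PLUS_EVENT, GENOME, "included")
    skip = assemble_isoform_sequence(PLUS_EVENT, GENOME, "skipped")
    assert len(skip) == len(incl) - PLUS_EVENT.target_length


def test_assembly_validates_inputs():
    with pytest.raises(ValueError):
        assemble_isoform_sequence(PLUS_EVENT, GENOME, "both")
    bad = ESEvent(
        event_id="b", gene_id="g", chrom="chr1", strand="+",
        upstream_exon=(0, 30), target_exon=(50, 80), downstream_exon=(150, 600),
    )
    with pytest.raises(ValueError):
        assemble_isoform_sequence(bad, GENOME, "included")


# ------------------------------------------------------------- ORF scan ----


def test_scan_clean_frame_zero():
    scans = three_frame_orf_scan("ATGGCCGCC")
    assert scans[0].stop_free and scans[0].peptide == "MAA"


def test_scan_all_stop_sequence_has_no_stop_free_frame():
    # Stops planted at offsets 0, 4 and 8 hit all three frames strictly
    # before their final codons.
    assert not any(s.stop_free for s in three_frame_orf_scan("TAATTAATTAAGGG"))


def test_terminal_stop_does_not_break_stop_free():
    scans = three_frame_orf_scan("ATGGCCTAA")
    assert scans[0].stop_free and scans[0].peptide == "MA"


def test_non_acgt_codons_translate_to_x_never_stop():
    assert translate_codons("TARNNNACG") == "XXT"
    scans = three_frame_orf_scan("TARTAR")
    assert scans[0].stop_free and scans[0].peptide == "XX"


def test_scan_requires_a_codon():
    with pytest.raises(ValueError):
        three_frame_orf_scan("AT")


# ------------------------------------------------------------- matching ----

PROTEINS = {"g": [("g.p1", "MMAAKQWERTY")]}


def test_substring_match_is_coding():
    scans = three_frame_orf_scan("ATGGCCGCCAAA")  # MAAK in frame 0
    verdict = match_annotated_protein(scans, PROTEINS, "g")
    assert verdict.coding and verdict.protein_id == "g.p1" and verdict.frame == 0


def test_stop_free_but_unmatched_is_noncoding():
    scans = three_frame_orf_scan("GGGGGGGGGGGG")
    assert match_annotated_protein(scans, PROTEINS, "g").coding is False


def test_frame_ties_resolve_to_lowest_frame():
    # Frame 0 translates NGRQ, frame 1 MAAK; with both present in the
    # protein, the lowest matching frame index must be reported.
    seq = "AATGGCCGCCAAAA"
    proteins = {"g": [("g.p1", "XNGRQXMAAKX")]}
    verdict = match_annotated_protein(three_frame_orf_scan(seq), proteins, "g")
    assert verdict.frame == 0


def test_missing_gene_is_unevaluable():
    scans = three_frame_orf_scan("ATGGCC")
    assert match_annotated_protein(scans, PROTEINS, "absent").coding is None


# --------------------------------------------------------- classification ----


@pytest.mark.parametrize(
    "incl,skip,cls,nmd",
    [
        (True, True, "AS2", False),
        (True, False, "long_only", True),
        (False, True, "skipped_only", True),
        (False, False, "neither", False),
    ],
)
def test_classification_truth_table(incl, skip, cls, nmd):
    call = classify_event(
        "e", IsoformVerdict(coding=incl), IsoformVerdict(coding=skip)
    )
    assert call.event_class == cls
    assert call.nmd_flag is nmd


def test_classify_event_rejects_unevaluable():
    with pytest.raises(ValueError):
        classify_event("e", IsoformVerdict(coding=None), IsoformVerdict(coding=True))


# --------------------------------------------- synthetic ground truth ------


def test_planted_classes_recovered(small_dataset):
    synth, truth, _ = small_dataset
    calls = classify_events(synth.planted_events(), synth.genome, synth.proteins)
    merged = truth.events.merge(calls, on="event_id")
    assert len(merged) == len(truth.events)
    expected = merged["coding_class"].map(expected_event_class)
    assert (merged["event_class"] == expected).all()


def test_frameshifting_94nt_target_leaves_no_stop_free_duplet_frame():
    # A 94-nt cassette exon (not a multiple of 3) whose skipping frameshifts
    # the downstream exon: the skipped duplet must hit a stop in every frame.
    config = SyntheticConfig(
        n_genes=6,
        exon_length_range=(94, 94),
        frac_as2=0.0,
        frac_nmd_skip=1.0,
        frac_nmd_incl=0.0,
        seed=5,
    )
    synth = generate_gene_models(config)
    truth = plant_es_truth(synth, config)
    assert (truth.events["coding_class"] == "NMD_skipped_noncoding").all()
    for event in synth.planted_events():
        assert event.target_length == 94
        duplet = assemble_isoform_sequence(event, synth.genome, "skipped")
        assert not any(s.stop_free for s in three_frame_orf_scan(duplet))
        triplet = assemble_isoform_sequence(event, synth.genome, "included")
        assert any(s.stop_free for s in three_frame_orf_scan(triplet))


def test_verdicts_agree_with_full_mrna_ptc_oracle(small_dataset):
    # Brute-force oracle: translate the full mRNA with and without the target
    # exon and check for a premature termination codon.
    synth, truth, _ = small_dataset
    calls = classify_events(synth.planted_events(), synth.genome, synth.proteins)
    calls = calls.set_index("gene_id")
    k = synth.config.exons_per_gene // 2
    for draft in synth.drafts:
        mrna = "".join(draft.exon_seqs)
        skipped = "".join(draft.exon_seqs[:k] + draft.exon_seqs[k + 1 :])
        row = calls.loc[draft.gene_id]
        if draft.coding_class in ("AS2", "NMD_skipped_noncoding"):
            assert not has_ptc(mrna) and row["included_coding"]
        else:
            assert has_ptc(mrna) and not row["included_coding"]
        if draft.coding_class in ("AS2", "NMD_included_noncoding"):
            assert not has_ptc(skipped) and row["skipped_coding"]
        if draft.coding_class == "NMD_skipped_noncoding":
            assert not row["skipped_coding"]


def test_strand_mirror_classifies_identically():
    # The same gene draft placed on '+' and '-' must classify the same way.
    config = SyntheticConfig(n_genes=8, seed=21)
    synth = generate_gene_models(config)
    plant_es_truth(synth, config)
    mirrored = copy.deepcopy(synth)
    for draft in mirrored.drafts:
        draft.strand = "+" if draft.strand == "-" else "-"
    mirrored.rebuild()
    calls = classify_events(synth.planted_events(), synth.genome, synth.proteins)
    mcalls = classify_events(mirrored.planted_events(), mirrored.genome, mirrored.proteins)
    assert list(calls["event_class"]) == list(mcalls["event_class"])


def test_minus_strand_protein_matches_translation_oracle():
    config = SyntheticConfig(n_genes=10, seed=3)
    synth = generate_gene_models(config)
    minus = [g for g in synth.genes if g.strand == "-"]
    assert minus, "expected at least one minus-strand gene"
    for gene in minus:
        chrom = synth.genome[gene.chrom]
        mrna = "".join(
            revcomp(chrom[s:e]) for s, e in gene.exons_tx_order
        )
        protein = translate(mrna).rstrip("*")
        assert synth.proteins[gene.gene_id][0][1] == protein
        assert "*" not in protein
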