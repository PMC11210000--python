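"""Lesion detection, the disruption metric D and the four-category rules."""

import pytest

from plastodeg import (
    AlignmentEvidence,
    ThresholdConfig,
    align_gene_to_reference,
    classify_gene,
    classify_plastome,
    compute_disruption,
    load_gene_catalog,
    revcomp,
    transfer_annotations,
)
from plastodeg.degradation_classifier import (
    FUNCTIONAL,
    LOST,
    MODERATE,
    SEVERE,
    CATEGORY_RANK,
)


@pytest.fixture(scope="module")
def ndhb(catalog):
    return catalog.models["ndhB"]


def test_identical_region_is_functional(catalog):
    model = catalog.models["ndhH"]
    ev = align_gene_to_reference(model.reference_seq, model)
    assert ev.coverage == 1.0
    assert ev.identity == 1.0
    assert ev.premature_stops == [] and ev.indels == []
    assert ev.start_codon == "ATG" and ev.terminal_stop_present
    call = classify_gene(ev, model)
    assert call.category == FUNCTIONAL
    assert call.disruption_fraction == 0.0


def test_single_substitution_creates_stop_at_codon_68(ndhb):
    """The classic ndhB exon-1 lesion: one genomic A->C on the minus strand
    (coding T->G), 201 bp into exon 1, reads as a TGA stop at amino acid 68
    and classifies as moderately pseudogenised with D = 3/L."""
    ref = ndhb.reference_seq
    assert ref[201:204] == "TTA"
    mutated = ref[:202] + "G" + ref[203:]          # coding T->G
    # on the genome the gene is minus-strand: the genomic change is A->C
    assert revcomp(ref[202]) == "A" and revcomp(mutated[202]) == "C"
    ev = align_gene_to_reference(mutated, ndhb)
    assert ev.premature_stops == [68]
    assert ev.frame_preserved
    assert ev.coverage == 1.0
    d = compute_disruption(ev, ndhb)
    assert d == pytest.approx(3 / len(ref))
    assert classify_gene(ev, ndhb).category == MODERATE


def test_truncation_half_gene_is_severe(catalog):
    model = catalog.models["ndhC"]
    region = model.reference_seq[: len(model.reference_seq) // 2]
    ev = align_gene_to_reference(region, model)
    assert ev.coverage == pytest.approx(0.5, abs=0.01)
    d = compute_disruption(ev, model)
    assert d == pytest.approx(0.5, abs=0.01)
    assert classify_gene(ev, model).category == SEVERE


def test_twenty_percent_remnant_is_lost(catalog):
    model = catalog.models["ndhG"]
    region = model.reference_seq[: int(0.2 * len(model.reference_seq))]
    ev = align_gene_to_reference(region, model)
    assert ev.coverage == pytest.approx(0.2, abs=0.02)
    assert classify_gene(ev, model).category == LOST


def test_empty_region_gives_coverage_zero_and_lost(catalog):
    model = catalog.models["ndhE"]
    ev = align_gene_to_reference("", model)
    assert ev.coverage == 0.0
    assert classify_gene(ev, model).category == LOST
    assert classify_gene(None, model).category == LOST


def test_small_inframe_deletion_keeps_gene_functional(catalog):
    model = catalog.models["ndhH"]
    ref = model.reference_seq
    region = ref[:300] + ref[309:]          # 9 bp in-frame deletion
    ev = align_gene_to_reference(region, model)
    assert ev.frame_preserved
    assert sum(ln for _, ln, op in ev.indels if op == "del") == 9
    assert classify_gene(ev, model).category == FUNCTIONAL


def test_frameshift_indel_is_moderate(catalog):
    model = catalog.models["ndhJ"]
    ref = model.reference_seq
    region = ref[:200] + ref[202:]          # 2 bp deletion breaks the frame
    ev = align_gene_to_reference(region, model)
    assert not ev.frame_preserved
    call = classify_gene(ev, model)
    assert call.category == MODERATE
    assert call.disruption_fraction == pytest.approx(2 / len(ref))


# ---------------------------------------------------------------------------
# threshold boundaries (exactness) and monotonicity
# ---------------------------------------------------------------------------


def _synthetic_cds_evidence(model, aligned_frac=1.0, stops=(), indels=(),
                            start="ATG", terminal=True):
    L = len(model.reference_seq)
    aligned = int(round(aligned_frac * L))
    return AlignmentEvidence(
        gene_name=model.gene_name, ref_length=L, aligned_ref_bases=aligned,
        matches=aligned, coverage=aligned / L, identity=1.0,
        indels=list(indels), premature_stops=list(stops), start_codon=start,
        terminal_stop_present=terminal,
        frame_preserved=all(ln % 3 == 0 for _, ln, _ in indels),
    )


def test_disruption_exactly_at_threshold_is_severe(catalog):
    model = catalog.models["ndhJ"]          # 480 bp: 10% is exactly 48 bp
    L = len(model.reference_seq)
    # one in-frame insertion of exactly 10% of the reference
    ev = _synthetic_cds_evidence(model, indels=[(150, L // 10, "ins")])
    d = compute_disruption(ev, model)
    assert d == pytest.approx(0.10)
    assert classify_gene(ev, model).category == SEVERE
    # just under the threshold: moderate at worst (here functional: in-frame)
    ev2 = _synthetic_cds_evidence(model, indels=[(150, L // 10 - 3, "ins")])
    assert classify_gene(ev2, model).category == FUNCTIONAL


def test_coverage_exactly_at_lost_threshold_is_not_lost(catalog):
    model = catalog.models["ndhH"]
    ev = _synthetic_cds_evidence(model, aligned_frac=0.30, terminal=False)
    assert classify_gene(ev, model).category != LOST
    ev2 = _synthetic_cds_evidence(model, aligned_frac=0.2999, terminal=False)
    assert classify_gene(ev2, model).category == LOST


def test_category_monotone_under_growing_truncation(catalog):
    model = catalog.models["ndhF"]
    ref = model.reference_seq
    last_rank = -1
    for keep in (1.0, 0.95, 0.8, 0.5, 0.31, 0.2, 0.05):
        region = ref[: int(keep * len(ref))]
        call = classify_gene(align_gene_to_reference(region, model), model)
        rank = CATEGORY_RANK[call.category]
        assert rank >= last_rank, (keep, call.category)
        last_rank = rank
    assert last_rank == CATEGORY_RANK[LOST]


def test_classification_is_deterministic(catalog):
    model = catalog.models["ndhK"]
    region = model.reference_seq[:600]
    calls = {classify_gene(align_gene_to_reference(region, model), model).category
             for _ in range(3)}
    assert len(calls) == 1


# ---------------------------------------------------------------------------
# RNA genes
# ---------------------------------------------------------------------------


def test_rna_gene_rules(catalog):
    model = catalog.models["trnV-GAC"]
    ev = align_gene_to_reference(model.reference_seq, model)
    assert classify_gene(ev, model).category == FUNCTIONAL
    # half the tRNA: severe by coverage
    half = align_gene_to_reference(model.reference_seq[:36], model)
    assert classify_gene(half, model).category in (SEVERE, LOST)
    rrn = catalog.models["rrn23"]
    lost = align_gene_to_reference(rrn.reference_seq[:300], rrn)
    assert classify_gene(lost, rrn).category == LOST


# ---------------------------------------------------------------------------
# whole-plastome classification & annotation transfer
# ---------------------------------------------------------------------------


def test_clean_plastome_classifies_all_functional(clean_record, catalog):
    calls = classify_plastome(clean_record, catalog)
    assert len(calls) == len(catalog)
    assert all(c.category == FUNCTIONAL for c in calls)


def test_unknown_gene_request_raises(clean_record, catalog):
    with pytest.raises(KeyError, match="nonGene"):
        classify_plastome(clean_record, catalog, genes=["nonGene"])


def test_transfer_annotations_places_clean_genes(clean_record, catalog):
    bare = type(clean_record)(
        "bare", clean_record.sequence, True, [], "")
    annotated, unplaced = transfer_annotations(bare, catalog)
    assert unplaced == []
    # duplicated genes get two features, single-copy genes one
    assert len(annotated.features_named("ycf2", kinds=("CDS",))) == 2
    assert len(annotated.features_named("rbcL", kinds=("CDS",))) == 1
    # placements agree with the planted truth
    for gene in ("psbA", "rbcL", "ndhF", "matK"):
        truth = {tuple(p) for f in clean_record.features_named(gene, ("CDS",))
                 for p in f.parts}
        placed = {tuple(p) for f in annotated.features_named(gene, ("CDS",))
                  for p in f.parts}
        assert placed == truth, gene


def test_reference_swap_robustness(clean_record, catalog):
    """Classification is identical whether the record carries the generator's
    planted annotations or annotations recovered by transfer (the classifier
    judges sequence, not annotation)."""
    bare = type(clean_record)("bare", clean_record.sequence, True, [], "")
    annotated, _ = transfer_annotations(bare, catalog)
    c1 = {c.gene_name: c.category
          for c in classify_plastome(clean_record, catalog)}
    c2 = {c.gene_name: c.category for c in classify_plastome(annotated, catalog)}
    assert c1 == c2


def test_threshold_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        ThresholdConfig(disruption_moderate_max=1.5)
    path = tmp_path / "thresholds.yaml"
    path.write_text("disruption_moderate_max: 0.2\nlost_coverage_max: 0.25\n")
    cfg = ThresholdConfig.from_yaml(path)
    assert cfg.disruption_moderate_max == 0.2
    assert cfg.lost_coverage_max == 0.25
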