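"""Generator invariants: determinism, IR mirror, event grammar, margins."""

import copy

import pytest

from plastodeg import (
    DegradationEvent,
    DegradationScenario,
    apply_degradation,
    build_reference_plastome,
    classify_plastome,
    partition_quadripartite,
    revcomp,
)
from plastodeg.degradation_classifier import LOST, MODERATE, SEVERE
from plastodeg.structure_analysis import locate_junctions
from plastodeg.synthetic_plastome import MarginError, dipodium_scenario


def _ir_mirrored(record):
    part = partition_quadripartite(record)
    ira = record.sequence[part.ira[0]:part.ira[0] + part.ira[1]]
    irb = record.sequence[part.irb[0]:part.irb[0] + part.irb[1]]
    return ira == revcomp(irb)


def test_reference_hits_target_length_and_structure(catalog):
    rec = build_reference_plastome(catalog, target_length=150_000, seed=1)
    assert len(rec.sequence) == 150_000
    part = partition_quadripartite(rec)
    assert sum(part.lengths.values()) == 150_000
    assert part.lengths["LSC"] > part.lengths["SSC"]
    assert _ir_mirrored(rec)


def test_same_seed_gives_byte_identical_genomes(catalog):
    a = build_reference_plastome(catalog, 146_000, seed=9)
    b = build_reference_plastome(catalog, 146_000, seed=9)
    assert a.sequence == b.sequence
    assert [f.parts for f in a.features] == [f.parts for f in b.features]
    c = build_reference_plastome(catalog, 146_000, seed=10)
    assert c.sequence != a.sequence


def test_ndh_operon_is_adjacent_in_lsc(clean_record, clean_partition):
    spans = {g: clean_record.features_named(g)[0].span
             for g in ("ndhJ", "ndhK", "ndhC")}
    for g, (s, e) in spans.items():
        assert clean_partition.region_of(s) == "LSC", g
    ordered = sorted(spans.values())
    gaps = [b[0] - a[1] for a, b in zip(ordered, ordered[1:])]
    assert all(0 <= g <= 50 for g in gaps)


def test_point_stop_event_truth_and_sequence(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhB", "point_stop", codon_index=68)], seed=3)
    rec, truth = apply_degradation(clean_copy, scn, catalog, config)
    row = truth[truth.gene == "ndhB"].iloc[0]
    assert row.category == MODERATE
    assert row.disruption == pytest.approx(3 / 1533)
    # both IR copies carry the identical lesion -> mirror intact
    assert _ir_mirrored(rec)
    # a single base changed per copy (TTA -> TGA)
    diffs = sum(a != b for a, b in zip(rec.sequence, clean_copy.sequence))
    assert diffs == 2


def test_degrade_to_fraction_truth_is_lost(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhG", "degrade_to_fraction",
                                 retained_fraction=0.2)], seed=3)
    _, truth = apply_degradation(clean_copy, scn, catalog, config)
    row = truth[truth.gene == "ndhG"].iloc[0]
    assert row.category == LOST
    assert row.coverage == pytest.approx(0.2, abs=0.01)


def test_truncate_half_truth_is_severe(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhC", "truncate_3prime", fraction=0.5)],
        seed=3)
    rec, truth = apply_degradation(clean_copy, scn, catalog, config)
    row = truth[truth.gene == "ndhC"].iloc[0]
    assert row.category == SEVERE
    assert row.disruption == pytest.approx(0.5, abs=0.01)
    feat = rec.features_named("ndhC")[0]
    assert feat.length == pytest.approx(363 - round(363 * 0.5), abs=1)


def test_margin_bands_are_enforced(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhJ", "truncate_3prime", fraction=0.1)],
        seed=3)
    with pytest.raises(MarginError):
        apply_degradation(clean_copy, scn, catalog, config)
    # boundary probe: ndhJ is 480 bp, so a 0.1 truncation is exactly D = 0.10,
    # which sits on the severe side of the threshold
    probe = DegradationScenario(
        events=[DegradationEvent("ndhJ", "truncate_3prime", fraction=0.1,
                                 boundary_probe=True)], seed=3)
    _, truth = apply_degradation(copy.deepcopy(clean_copy), probe, catalog, config)
    assert truth[truth.gene == "ndhJ"].iloc[0].category == SEVERE


def test_unknown_gene_in_event_raises(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("notAGene", "delete_gene")], seed=1)
    with pytest.raises(KeyError):
        apply_degradation(clean_copy, scn, catalog, config)


def test_cds_events_do_not_move_unrelated_genes_between_regions(
        catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhF", "truncate_3prime", fraction=0.4),
                DegradationEvent("ndhK", "point_stop", codon_index=50)],
        seed=3)
    rec, _ = apply_degradation(clean_copy, scn, catalog, config)
    part = partition_quadripartite(rec)
    for gene, region in (("rpl32", "SSC"), ("cssA", "SSC"), ("rbcL", "LSC"),
                         ("psbA", "LSC"), ("rrn16", "IRA")):
        feats = rec.features_named(gene)
        assert any(part.region_of(f.parts[0][0]) == region for f in feats), gene


def test_ndhf_deletion_with_boundary_shift(catalog, clean_copy, config):
    scn = DegradationScenario(
        events=[DegradationEvent("ndhF", "delete_gene")], seed=3,
        shift_ssc_ir_boundary=True)
    rec, truth = apply_degradation(clean_copy, scn, catalog, config)
    assert truth[truth.gene == "ndhF"].iloc[0].category == LOST
    part = partition_quadripartite(rec)
    rep = locate_junctions(rec, part)
    assert rep.boundary_shift
    site = rep.sites["IRB/SSC"]
    assert site.flanking is not None
    assert site.flanking[1].startswith("rpl32")
    assert rep.ycf1_fragment_present


def test_trnv_triplication_breaks_one_ir_only(catalog, clean_copy, config):
    scn = DegradationScenario(events=[], seed=3, triplicate_trna="trnV-GAC")
    rec, _ = apply_degradation(clean_copy, scn, catalog, config)
    from plastodeg import detect_gene_multiplication

    n, placements = detect_gene_multiplication(rec, "trnV-GAC", catalog)
    assert n == 3
    # two copies in close proximity within one IR
    placements = sorted(placements)
    gaps = [b[0] - a[1] for a, b in zip(placements, placements[1:])]
    assert min(gaps) < 100
    # the partition still resolves despite the one-sided insertion
    part = partition_quadripartite(rec)
    assert part.ir_identity < 1.0


def test_dipodium_scenario_keeps_every_ndh_gene_nonfunctional(catalog):
    seen = set()
    for seed in (1, 2, 3):
        scn = dipodium_scenario(catalog, seed=seed)
        hit = {e.gene_name for e in scn.events}
        assert {g for g in hit if g.startswith("ndh")} == set(catalog.ndh_genes)
        seen |= {e.op for e in scn.events}
    assert "delete_gene" in seen or "degrade_to_fraction" in seen


def test_fixture_set_determinism_and_files(catalog, tmp_path):
    from plastodeg import emit_fixture_set

    a = emit_fixture_set(tmp_path / "a", n_samples=2, seed=11, catalog=catalog)
    b = emit_fixture_set(tmp_path / "b", n_samples=2, seed=11, catalog=catalog)
    assert [r.sequence for r in a.samples] == [r.sequence for r in b.samples]
    assert a.truth.equals(b.truth)
    assert (a.out_dir / "reference.gb").exists()
    assert (a.out_dir / "sample_01.fasta").exists()
    assert (a.out_dir / "truth.tsv").exists()
    assert (a.out_dir / "tree.nwk").read_text() == \
        (b.out_dir / "tree.nwk").read_text()


def test_empty_scenario_truth_is_all_functional(catalog, clean_copy, config):
    scn = DegradationScenario(events=[], seed=1)
    rec, truth = apply_degradation(clean_copy, scn, catalog, config)
    assert (truth.category == "functional").all()
    assert rec.sequence == clean_copy.sequence
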