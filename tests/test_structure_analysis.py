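"""Inverted-repeat detection, quadripartite partition, GC and junctions."""

import numpy as np
import pytest

from plastodeg import (
    compute_gc,
    detect_gene_multiplication,
    find_inverted_repeats,
    locate_junctions,
    partition_quadripartite,
    revcomp,
)
from plastodeg.plastome_io import rotate_record, PlastomeRecord
from plastodeg.structure_analysis import (
    AmbiguousStructureError,
    StructureError,
)


def oracle_pairs(s: str, min_len: int):
    """Brute-force maximal inverted repeat pairs on a linear string.

    Dynamic-programming extension table over the sequence and its reverse
    complement; a pair (i, j, L) is reported when seq[i:i+L] equals
    revcomp(seq[j:j+L]), the arms do not overlap, and the match extends
    neither left nor right.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(s)
    S = [c if c in "ACGT" else "!" for c in s.upper()]
    R = [comp.get(c, "#") for c in reversed(s.upper())]
    E = [[0] * (n + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        Ei, Ei1 = E[i], E[i + 1]
        for p in range(n - 1, -1, -1):
            if S[i] == R[p]:
                Ei[p] = Ei1[p + 1] + 1
    out = set()
    for i in range(n):
        for p in range(n):
            L = E[i][p]
            if L < min_len:
                continue
            if i > 0 and p > 0 and S[i - 1] == R[p - 1]:
                continue
            j = n - p - L
            if i + L <= j:
                out.add((i, j, L))
    return sorted(out)


def test_repeat_finder_matches_brute_force_oracle():
    """Seeded randomized equivalence on 200 strings <= 300 bp, a third of
    them with a planted inverted repeat."""
    rng = np.random.default_rng(2024)
    comp = str.maketrans("ACGT", "TGCA")
    for t in range(200):
        n = int(rng.integers(10, 301))
        s = "".join(rng.choice(list("ACGT"), size=n))
        if t % 3 == 0 and n > 40:
            L = int(rng.integers(8, n // 3))
            a = int(rng.integers(0, n - 3 * L))
            b = int(rng.integers(a + L, n - L + 1))
            s = s[:b] + s[a:a + L].translate(comp)[::-1] + s[b + L:]
        min_len = int(rng.integers(4, 12))
        got = sorted((p.a_start, p.b_start, p.a_len)
                     for p in find_inverted_repeats(s, min_len, 0.0,
                                                    circular=False))
        assert got == oracle_pairs(s, min_len), (s, min_len)


def test_planted_toy_repeat_is_found_exactly():
    left = "AAACCCGGGTTTACGATCGT"
    spacer = "TTTTTTTTTT"
    s = "GATC" + left + spacer + revcomp(left) + "CATG"
    (pair,) = find_inverted_repeats(s, min_len=10, circular=False)
    assert (pair.a_start, pair.a_len) == (4, len(left))
    assert (pair.b_start, pair.b_len) == (4 + len(left) + len(spacer), len(left))
    assert pair.identity == 1.0


def test_random_sequence_has_no_long_repeat():
    rng = np.random.default_rng(5)
    s = "".join(rng.choice(list("ACGT"), size=10_000))
    assert find_inverted_repeats(s, min_len=1000, circular=False) == []


def test_ambiguity_bases_never_match_in_repeat_search():
    left = "ACGTACGTACGTACGT"
    s = left + "TTTT" + revcomp(left)
    with_n = left[:8] + "N" + left[9:] + "TTTT" + revcomp(left)
    assert find_inverted_repeats(s, 16, circular=False)
    pairs = find_inverted_repeats(with_n, 16, circular=False)
    assert all(p.a_len < 16 for p in pairs) or pairs == []


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


def test_partition_matches_generator_truth(clean_record, clean_partition):
    part = clean_partition
    n = len(clean_record.sequence)
    assert sum(part.lengths.values()) == n
    assert part.lengths["IRA"] == part.lengths["IRB"]
    assert part.lengths["LSC"] >= part.lengths["SSC"]
    assert part.ir_identity == 1.0
    # normalized orientation: the generator put the LSC at position 0
    assert part.lsc[0] == 0
    ira = clean_record.sequence[part.ira[0]:part.ira[0] + part.ira[1]]
    irb = clean_record.sequence[part.irb[0]:part.irb[0] + part.irb[1]]
    assert ira == revcomp(irb)


def test_partition_invariant_under_rotation(clean_record, clean_partition):
    for offset in (1, 17_000, 90_000, 140_000):
        rotated = rotate_record(clean_record, offset)
        part = partition_quadripartite(rotated)
        assert part.lengths == clean_partition.lengths
        assert part.ir_identity == clean_partition.ir_identity


def test_partition_invariant_under_reverse_complement(clean_record,
                                                      clean_partition):
    rc = PlastomeRecord("rc", revcomp(clean_record.sequence), True, [])
    part = partition_quadripartite(rc)
    # lengths identical; IRA/IRB labels may swap, which they absorb by
    # construction (equal lengths)
    assert part.lengths == clean_partition.lengths


def test_no_ir_raises_structure_error():
    rng = np.random.default_rng(11)
    s = "".join(rng.choice(list("ACGT"), size=60_000))
    with pytest.raises(StructureError, match="no quadripartite"):
        partition_quadripartite(s, min_ir_len=10_000)


def test_two_competing_ir_pairs_raise_ambiguity_error():
    rng = np.random.default_rng(13)
    block_a = "".join(rng.choice(list("ACGT"), size=12_000))
    block_b = "".join(rng.choice(list("ACGT"), size=12_000))
    fill = lambda k: "".join(rng.choice(list("ACGT"), size=k))
    s = (block_a + fill(5_000) + block_b + fill(5_000)
         + revcomp(block_a) + fill(5_000) + revcomp(block_b) + fill(5_000))
    with pytest.raises(AmbiguousStructureError):
        partition_quadripartite(s, min_ir_len=10_000)


# ---------------------------------------------------------------------------
# GC
# ---------------------------------------------------------------------------


def test_gc_report_is_length_weighted_mean_of_regions(clean_record,
                                                      clean_partition):
    rep = compute_gc(clean_record, clean_partition)
    weighted = sum(rep.per_region[r] * clean_partition.lengths[r]
                   for r in rep.per_region) / len(clean_record.sequence)
    assert rep.overall == pytest.approx(weighted, abs=1e-9)
    assert 0.3 < rep.overall < 0.45


# ---------------------------------------------------------------------------
# junctions & multiplication
# ---------------------------------------------------------------------------


def test_clean_junction_report(clean_record, clean_partition):
    rep = locate_junctions(clean_record, clean_partition)
    assert not rep.boundary_shift
    # SSC/IRA junction lies inside the functional ycf1
    assert "ycf1" in rep.sites["SSC/IRA"].containing
    assert rep.ycf1_in_ir_bp == 500
    assert rep.ycf1_fragment_present
    # IRA/LSC junction sits in the spacer next to psbA
    site = rep.sites["IRA/LSC"]
    assert site.flanking is not None and "psbA" in site.flanking
    # IRB/SSC junction is flanked by the ycf1 fragment and ndhF
    site = rep.sites["IRB/SSC"]
    assert site.flanking == ("ycf1 (fragment)", "ndhF")


def test_gene_multiplication_counts(clean_record, catalog):
    n, placements = detect_gene_multiplication(clean_record, "trnV-GAC", catalog)
    assert n == 2 and len(placements) == 2
    n, _ = detect_gene_multiplication(clean_record, "rbcL", catalog)
    assert n == 1
    n, _ = detect_gene_multiplication(clean_record, "ycf2", catalog)
    assert n == 2
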