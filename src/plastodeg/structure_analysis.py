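"""Quadripartite architecture: inverted-repeat detection, region partition,
junction placement, GC and gene-multiplication reports.

The repeat finder is the load-bearing primitive.  Its exact-match core
enumerates maximal inverted repeat pairs — maximal exact matches between the
sequence and its reverse complement — by k-mer seeding with per-diagonal skip,
which makes it equivalent to a brute-force all-pairs oracle (the test suite
checks this on random strings) while scaling to plastome-sized input.
IUPAC ambiguity bases never match.  With a mismatch tolerance, collinear
exact pairs separated by short gaps are chained into composite repeats, which
is what resolves IRs that differ by a small one-sided insertion (e.g. a
duplicated tRNA in only one repeat copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .plastome_io import Feature, PlastomeRecord, GeneCatalog, gc_fraction, revcomp

__all__ = [
    "RepeatPair",
    "QuadripartitePartition",
    "JunctionReport",
    "GcReport",
    "StructureError",
    "AmbiguousStructureError",
    "find_inverted_repeats",
    "partition_quadripartite",
    "compute_gc",
    "locate_junctions",
    "detect_gene_multiplication",
]

DEFAULT_MIN_IR_LEN = 10_000
DEFAULT_MAX_MISMATCH_FRAC = 0.005


class StructureError(ValueError):
    """No quadripartite structure resolvable."""


class AmbiguousStructureError(StructureError):
    """More than one non-nested IR candidate of similar length."""


@dataclass(frozen=True)
class RepeatPair:
    """An inverted repeat pair: two arcs whose sequences are reverse
    complements (up to ``1 - identity`` mismatching/indel bases).

    Arcs are ``(start, length)`` on the circle (start in ``[0, n)``; an arc
    may wrap past the origin). ``matched`` counts exactly matching bases.
    """

    a_start: int
    a_len: int
    b_start: int
    b_len: int
    matched: int

    @property
    def length(self) -> int:
        return max(self.a_len, self.b_len)

    @property
    def identity(self) -> float:
        return self.matched / self.length


def _strict(seq: str) -> str:
    """Uppercase; anything outside ACGT becomes a never-matching sentinel."""
    s = seq.upper()
    return "".join(c if c in "ACGT" else "!" for c in s)


def _strict_rc(seq: str) -> str:
    s = revcomp(seq.upper())
    return "".join(c if c in "ACGT" else "#" for c in s)


def _exact_pairs_linear(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal inverted repeat pairs (i, j, L) on a linear string.

    ``seq[i:i+L] == revcomp(seq[j:j+L])`` with ``i + L <= j``; maximality means
    the underlying match between ``seq`` and its reverse complement cannot be
    extended by sequence (pairs whose arms would overlap are not reported).
    """
    n = len(seq)
    if min_len < 1 or n < 2 * min_len:
        return []
    s = _strict(seq)
    r = _strict_rc(seq)
    k = min(21, min_len)
    index: dict[str, list[int]] = {}
    for p in range(n - k + 1):
        index.setdefault(r[p:p + k], []).append(p)
    seen: set[tuple[int, int]] = set()
    diag_end: dict[int, int] = {}
    out: list[tuple[int, int, int]] = []
    for i in range(n - k + 1):
        hits = index.get(s[i:i + k])
        if not hits:
            continue
        for p in hits:
            d = i - p
            if i < diag_end.get(d, 0):
                continue
            i0, p0 = i, p
            while i0 > 0 and p0 > 0 and s[i0 - 1] == r[p0 - 1]:
                i0 -= 1
                p0 -= 1
            L = k
            while i0 + L < n and p0 + L < n and s[i0 + L] == r[p0 + L]:
                L += 1
            diag_end[d] = i0 + L
            if (i0, p0) in seen:
                continue
            seen.add((i0, p0))
            if L < min_len:
                continue
            j = n - p0 - L
            if i0 + L <= j:
                out.append((i0, j, L))
    return sorted(out, key=lambda t: (-t[2], t[0], t[1]))


def _circular_disjoint(a: int, la: int, b: int, lb: int, n: int) -> bool:
    """Do circular arcs [a, a+la) and [b, b+lb) (mod n) avoid each other?"""
    if la + lb > n:
        return False
    return (b - a) % n >= la and (a - b) % n >= lb


def _exact_pairs_circular(seq: str, min_len: int) -> list[RepeatPair]:
    n = len(seq)
    doubled = seq + seq
    raw = _exact_pairs_linear(doubled, min_len)
    found: dict[frozenset, RepeatPair] = {}
    for i, j, L in raw:
        if L > n:
            continue
        a, b = i % n, j % n
        key = frozenset({(a, L), (b, L)})
        if key in found:
            continue
        if not _circular_disjoint(a, L, b, L, n):
            continue
        found[key] = RepeatPair(a, L, b, L, matched=L)
    return sorted(found.values(), key=lambda rp: (-rp.length, rp.a_start))


def _drop_contained(pairs: list[RepeatPair], n: int) -> list[RepeatPair]:
    """Remove pairs whose both arcs lie within another pair's arcs."""

    def inside(s1, l1, s2, l2):          # arc1 within arc2 (mod n)
        return l1 <= l2 and (s1 - s2) % n + l1 <= l2

    keep = []
    for i, p in enumerate(pairs):
        contained = any(
            i != j
            and ((inside(p.a_start, p.a_len, q.a_start, q.a_len)
                  and inside(p.b_start, p.b_len, q.b_start, q.b_len))
                 or (inside(p.a_start, p.a_len, q.b_start, q.b_len)
                     and inside(p.b_start, p.b_len, q.a_start, q.a_len)))
            for j, q in enumerate(pairs)
            if pairs[j].length > p.length
            or (pairs[j].length == p.length and j < i)
        )
        if not contained:
            keep.append(p)
    return keep


def _signed_gap(frm: int, to: int, n: int) -> int:
    """Circular distance from ``frm`` to ``to``, mapped to (-n/2, n/2]."""
    g = (to - frm) % n
    return g if g <= n // 2 else g - n


def _chain_pairs(pairs: list[RepeatPair], n: int, min_identity: float,
                 max_gap: int = 2000, max_overlap: int = 100) -> list[RepeatPair]:
    """Merge collinear exact pairs separated by short gaps into composite IRs.

    Two pairs chain when arc A2 follows arc A1 and arc B2 precedes arc B1
    (mirrored order, as reverse complement orientation requires) with both
    circular gaps at most ``max_gap`` — a small negative gap (chance matches
    extending into an inserted block) is tolerated — and the merged identity
    stays at or above ``min_identity``.
    """
    merged = _drop_contained(sorted(pairs, key=lambda rp: -rp.length), n)
    changed = True
    while changed:
        changed = False
        for x in range(len(merged)):
            for y in range(len(merged)):
                if x == y:
                    continue
                p, q = merged[x], merged[y]
                ga = _signed_gap(p.a_start + p.a_len, q.a_start, n)
                gb = _signed_gap(q.b_start + q.b_len, p.b_start, n)
                if not (-max_overlap <= ga <= max_gap):
                    continue
                if not (-max_overlap <= gb <= max_gap):
                    continue
                a_len = p.a_len + ga + q.a_len
                b_len = q.b_len + gb + p.b_len
                overlap_penalty = max(0, -ga) + max(0, -gb)
                cand = RepeatPair(p.a_start, a_len, q.b_start, b_len,
                                  matched=p.matched + q.matched - overlap_penalty)
                if cand.identity < min_identity:
                    continue
                if not _circular_disjoint(cand.a_start, cand.a_len,
                                          cand.b_start, cand.b_len, n):
                    continue
                merged = [m for z, m in enumerate(merged) if z not in (x, y)]
                merged.append(cand)
                changed = True
                break
            if changed:
                break
    return sorted(merged, key=lambda rp: (-rp.length, rp.a_start))


def find_inverted_repeats(
    sequence: str,
    min_len: int,
    max_mismatch_frac: float = 0.0,
    circular: bool = True,
) -> list[RepeatPair]:
    """Find maximal inverted repeat pairs with identity >= 1 - max_mismatch_frac.

    With ``max_mismatch_frac == 0`` this is the exact-match core (sorted by
    length, longest first).  With a tolerance, exact pairs down to a smaller
    seed length are chained across short gaps so one-sided insertions inside an
    IR do not split it.  Origin-spanning repeats are handled by doubling the
    circle.  Returns an empty list when nothing qualifies.
    """
    if len(sequence) < 2 * min_len:
        return []
    if max_mismatch_frac <= 0.0:
        if circular:
            return [rp for rp in _exact_pairs_circular(sequence, min_len)]
        return [
            RepeatPair(i, L, j, L, matched=L)
            for i, j, L in _exact_pairs_linear(sequence, min_len)
        ]
    seed_len = max(50, min(min_len, 500))
    if circular:
        seeds = _exact_pairs_circular(sequence, seed_len)
        n = len(sequence)
    else:
        seeds = [RepeatPair(i, L, j, L, matched=L)
                 for i, j, L in _exact_pairs_linear(sequence, seed_len)]
        n = len(sequence)
    chained = _chain_pairs(seeds, n, min_identity=1.0 - max_mismatch_frac)
    return [rp for rp in chained if rp.length >= min_len]


# ---------------------------------------------------------------------------
# quadripartite partition
# ---------------------------------------------------------------------------


@dataclass
class QuadripartitePartition:
    """The four regions of a plastome, as ``(start, length)`` arcs on the
    input circle.  ``normalization_offset`` rotates the LSC start to 0
    (the orientation used by region-ordered reports)."""

    n: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_identity: float

    @property
    def lengths(self) -> dict[str, int]:
        return {"LSC": self.lsc[1], "IRB": self.irb[1],
                "SSC": self.ssc[1], "IRA": self.ira[1]}

    @property
    def ir_length(self) -> int:
        """Length of one repeat copy (IRA hull), Table-2 style."""
        return self.ira[1]

    @property
    def normalization_offset(self) -> int:
        return self.lsc[0]

    @property
    def junctions(self) -> dict[str, int]:
        """Junction positions: the first base of the downstream region."""
        return {
            "LSC/IRB": self.irb[0],
            "IRB/SSC": self.ssc[0],
            "SSC/IRA": self.ira[0],
            "IRA/LSC": self.lsc[0],
        }

    def region_of(self, pos: int) -> str:
        pos %= self.n
        for name, (s, ln) in (("LSC", self.lsc), ("IRB", self.irb),
                              ("SSC", self.ssc), ("IRA", self.ira)):
            if (pos - s) % self.n < ln:
                return name
        raise ValueError(f"position {pos} not covered")  # pragma: no cover

    def validate(self) -> None:
        if sum(self.lengths.values()) != self.n:
            raise StructureError(
                f"region lengths {self.lengths} do not sum to genome length {self.n}"
            )
        if self.lsc[1] < self.ssc[1]:
            raise StructureError("LSC shorter than SSC")


def partition_quadripartite(
    plastome: PlastomeRecord | str,
    min_ir_len: int = DEFAULT_MIN_IR_LEN,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> QuadripartitePartition:
    """Resolve LSC/IRB/SSC/IRA from the dominant inverted repeat pair.

    The SSC is the shorter single-copy arc between the repeat copies; IRA is
    the repeat copy adjacent to the SSC->LSC transition.  Raises
    :class:`StructureError` when no repeat of at least ``min_ir_len`` exists
    and :class:`AmbiguousStructureError` when two disjoint candidates of
    similar length compete.
    """
    seq = plastome.sequence if isinstance(plastome, PlastomeRecord) else plastome
    n = len(seq)
    pairs = find_inverted_repeats(seq, min_ir_len, max_mismatch_frac, circular=True)
    if not pairs:
        raise StructureError("no quadripartite structure: no inverted repeat "
                             f">= {min_ir_len} bp found")
    best = pairs[0]
    rivals = [
        rp for rp in pairs[1:]
        if rp.length >= 0.8 * best.length
        and _circular_disjoint(rp.a_start, rp.a_len, best.a_start, best.a_len, n)
    ]
    if rivals:
        listing = "; ".join(
            f"({rp.a_start},{rp.a_len})/({rp.b_start},{rp.b_len})"
            for rp in [best] + rivals
        )
        raise AmbiguousStructureError(
            f"ambiguous IR: multiple candidates of similar length: {listing}"
        )
    a = (best.a_start, best.a_len)
    b = (best.b_start, best.b_len)
    gap_ab = ((b[0] - (a[0] + a[1])) % n)      # arc between end of A and start of B
    gap_ba = ((a[0] - (b[0] + b[1])) % n)
    arc_ab = ((a[0] + a[1]) % n, gap_ab)
    arc_ba = ((b[0] + b[1]) % n, gap_ba)
    if gap_ab >= gap_ba:
        lsc, ssc = arc_ab, arc_ba
        irb, ira = b, a        # circle order LSC -> IRB -> SSC -> IRA
    else:
        lsc, ssc = arc_ba, arc_ab
        irb, ira = a, b
    part = QuadripartitePartition(n=n, lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                                  ir_identity=best.identity)
    part.validate()
    return part


# ---------------------------------------------------------------------------
# GC
# ---------------------------------------------------------------------------


@dataclass
class GcReport:
    overall: float
    per_region: dict[str, float] = field(default_factory=dict)


def compute_gc(plastome: PlastomeRecord | str,
               partition: QuadripartitePartition | None = None) -> GcReport:
    """GC content overall and (with a partition) per region.

    GC = (G+C)/(A+C+G+T); ambiguity bases and N are excluded from numerator
    and denominator.  An all-ambiguous sequence raises ``ValueError``.
    """
    seq = plastome.sequence if isinstance(plastome, PlastomeRecord) else plastome
    report = GcReport(overall=gc_fraction(seq))
    if partition is not None:
        n = len(seq)
        for name, (s, ln) in (("LSC", partition.lsc), ("IRB", partition.irb),
                              ("SSC", partition.ssc), ("IRA", partition.ira)):
            arc = seq[s:s + ln] if s + ln <= n else seq[s:] + seq[:(s + ln) % n]
            report.per_region[name] = gc_fraction(arc)
    return report


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------


@dataclass
class JunctionSite:
    position: int
    region_before: str
    region_after: str
    containing: list[str] = field(default_factory=list)
    flanking: tuple[str, str] | None = None   # (upstream gene, downstream gene)


@dataclass
class JunctionReport:
    sites: dict[str, JunctionSite]
    ycf1_in_ir_bp: int = 0
    ycf1_fragment_present: bool = False
    boundary_shift: bool = False
    rationale: str = ""
    warnings: list[str] = field(default_factory=list)


def _feature_label(f: Feature) -> str:
    return f.gene_name + (" (fragment)" if f.kind == "pseudogene_mark" else "")


def _flanking(features: list[Feature], pos: int, n: int) -> tuple[str, str] | None:
    """Nearest feature ends upstream/downstream of ``pos`` on the circle."""
    if not features:
        return None
    best_up, d_up = None, None
    best_dn, d_dn = None, None
    for f in features:
        for s, e, _ in f.parts:
            du = (pos - e) % n       # distance from feature end back to pos
            dd = (s - pos) % n       # distance forward to feature start
            if d_up is None or du < d_up:
                best_up, d_up = f, du
            if d_dn is None or dd < d_dn:
                best_dn, d_dn = f, dd
    return (_feature_label(best_up), _feature_label(best_dn))


def locate_junctions(
    plastome: PlastomeRecord,
    partition: QuadripartitePartition,
    calls: dict[str, str] | None = None,
) -> JunctionReport:
    """Report what each of the four junctions falls in, the functional-ycf1
    overlap with the IR, and whether the IRB/SSC boundary has shifted.

    The boundary-shift flag fires when ndhF is absent (no feature, or a
    ``calls`` row classifying it lost), the IRB/SSC junction lies in the
    spacer whose nearest SSC-side gene is rpl32, and a ycf1 fragment sits at
    the IR side of that junction.
    """
    n = len(plastome.sequence)
    feats = [f for f in plastome.features if f.kind in ("CDS", "tRNA", "rRNA",
                                                        "pseudogene_mark")]
    report = JunctionReport(sites={})
    if not feats:
        report.warnings.append("no annotations: junction attribution skipped")
    order = [("LSC/IRB", "LSC", "IRB"), ("IRB/SSC", "IRB", "SSC"),
             ("SSC/IRA", "SSC", "IRA"), ("IRA/LSC", "IRA", "LSC")]
    for name, before, after in order:
        pos = partition.junctions[name]
        containing = [_feature_label(f) for f in feats if f.contains(pos)]
        site = JunctionSite(position=pos, region_before=before,
                            region_after=after, containing=containing)
        if not containing:
            site.flanking = _flanking(feats, pos, n)
        report.sites[name] = site

    # overlap of the functional (full-length, CDS-kind) ycf1 with the IRs
    ycf1_feats = plastome.features_named("ycf1", kinds=("CDS",))
    if ycf1_feats:
        full = max(ycf1_feats, key=lambda f: f.length)
        overlap = 0
        for s, e, _ in full.parts:
            for rs, rl in (partition.ira, partition.irb):
                for pos_s, pos_e in (((s, e),) if e <= n else ((s, n), (0, e - n))):
                    # arc [rs, rs+rl) may wrap
                    for as_, ae in (((rs, rs + rl),) if rs + rl <= n
                                    else ((rs, n), (0, (rs + rl) % n))):
                        overlap += max(0, min(pos_e, ae) - max(pos_s, as_))
        report.ycf1_in_ir_bp = overlap
    report.ycf1_fragment_present = bool(
        plastome.features_named("ycf1", kinds=("pseudogene_mark",))
    ) or report.ycf1_in_ir_bp > 0

    if calls is not None:
        ndhf_absent = calls.get("ndhF", "").lower() in ("lost", "absent")
    else:
        ndhf_absent = not plastome.features_named("ndhF", kinds=("CDS", "pseudogene_mark"))
    site = report.sites["IRB/SSC"]
    in_rpl32_spacer = (
        not site.containing
        and site.flanking is not None
        and site.flanking[1].split(" ")[0] == "rpl32"
    )
    report.boundary_shift = bool(ndhf_absent and in_rpl32_spacer
                                 and report.ycf1_fragment_present)
    if report.boundary_shift:
        report.rationale = (
            "ndhF unlocatable; IRB/SSC junction falls in the rpl32-adjacent "
            "spacer next to a ycf1 fragment"
        )
    elif ndhf_absent:
        report.rationale = "ndhF unlocatable but junction not in rpl32-adjacent spacer"
    return report


def detect_gene_multiplication(
    plastome: PlastomeRecord,
    gene_name: str,
    catalog: GeneCatalog | None = None,
) -> tuple[int, list[tuple[int, int, str]]]:
    """Count annotated copies of a gene and return their placements.

    Only ``CDS``/``tRNA``/``rRNA`` features count (fragments marked as
    pseudogene remnants do not).  When a catalog is given, the expected copy
    number (2 for IR-duplicated genes, else 1) is available for comparison;
    the returned count is the observed one.
    """
    copies = plastome.features_named(gene_name, kinds=("CDS", "tRNA", "rRNA"))
    placements = [(f.span[0], f.span[1], f.strand) for f in copies]
    return len(copies), sorted(placements)


def expected_copy_number(catalog: GeneCatalog, gene_name: str) -> int:
    model = catalog.models.get(gene_name)
    if model is None:
        raise KeyError(gene_name)
    return 2 if model.expected_ir_copy else 1
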