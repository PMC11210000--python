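"""Per-gene homology assessment and four-category degradation classification.

Each plastid gene of a sample is compared against the functional reference
model from the gene catalog and assigned one of four categories:

* ``functional`` — reading frame intact (allowed start codon, no internal
  stop, no uncompensated frameshift, terminal stop present) and less than
  10% of the reading frame disrupted by small in-frame indels;
* ``moderate_pseudogene`` — less than 10% of the reading frame disrupted,
  but by internal stop codons or frame-breaking (non-triplet) indels;
* ``severe_pseudogene`` — at least 10% disrupted (internal stops, large
  deletions/truncations, frameshifts);
* ``lost`` — no locatable homolog, or less than 30% of the reference
  sequence identifiable in the sample (i.e. at least 70% of the gene could
  not be recovered).

The disruption fraction is a lesion-extent metric:

    D = (deleted reference bases + inserted bases + 3 per internal stop)
        / reference length,  capped at 1.

Deleted bases include missing terminal sequence (truncations).  D counts only
directly lesioned bases, not everything downstream of the first lesion: a
gene carrying a single internal stop is moderately — not severely —
pseudogenised.  An alternative downstream-extent metric is available via
``ThresholdConfig.downstream_extent`` but is not the default.

Alignment evidence comes from edlib infix alignments of each reference exon
against the (doubled, both-strand) genome.  Reference bases are counted as
identified when they lie in confident match blocks (runs of >= 12 matching
columns, merged across gaps of <= 30 reference bases); this keeps smeared
junk alignment over deleted regions from inflating coverage, while point
substitutions inside otherwise intact sequence remain identified and are
read as codons (so a single A->C two match-blocks apart is seen as an
internal TGA stop, not as missing sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import yaml

from .plastome_io import (
    Feature,
    GeneCatalog,
    GeneModel,
    PlastomeRecord,
    revcomp,
    stop_codons,
)

__all__ = [
    "Category",
    "CATEGORY_ORDER",
    "ThresholdConfig",
    "AlignmentEvidence",
    "DegradationCall",
    "transfer_annotations",
    "align_gene_to_reference",
    "compute_disruption",
    "classify_gene",
    "classify_plastome",
    "GenomeIndex",
]

# match-block calling: see module docstring
MIN_ANCHOR_RUN = 12
BLOCK_MERGE_GAP = 30
# a hit is discarded as noise when its edit distance exceeds this fraction of
# the query length (absence then feeds the "lost" category)
MAX_EDIT_FRACTION = 0.8


class Category(str):
    pass


FUNCTIONAL = "functional"
MODERATE = "moderate_pseudogene"
SEVERE = "severe_pseudogene"
LOST = "lost"
CATEGORY_ORDER = [FUNCTIONAL, MODERATE, SEVERE, LOST]
CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class ThresholdConfig:
    """Classification thresholds.

    ``disruption_moderate_max``: D below this is at most moderately
    pseudogenised; at or above it, severe.  ``lost_coverage_max``: identifiable
    coverage strictly below this means lost (exactly at it: not lost).
    ``annotation_min_identity`` gates annotation transfer placements.
    """

    disruption_moderate_max: float = 0.10
    lost_coverage_max: float = 0.30
    annotation_min_identity: float = 0.90
    genetic_code: int = 11
    downstream_extent: bool = False

    def __post_init__(self) -> None:
        for name in ("disruption_moderate_max", "lost_coverage_max",
                     "annotation_min_identity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AlignmentEvidence:
    """Per-gene (per-copy) lesion inventory from the reference alignment."""

    gene_name: str
    copy_id: str = "best"
    ref_length: int = 0
    aligned_ref_bases: int = 0
    matches: int = 0
    coverage: float = 0.0
    identity: float = 0.0
    indels: list[tuple[int, int, str]] = field(default_factory=list)
    premature_stops: list[int] = field(default_factory=list)
    start_codon: str | None = None
    terminal_stop_present: bool = False
    frame_preserved: bool = True
    target_interval: tuple[int, int, str] | None = None

    @property
    def inserted_bases(self) -> int:
        return sum(ln for _, ln, op in self.indels if op == "ins")

    @property
    def deleted_bases(self) -> int:
        return self.ref_length - self.aligned_ref_bases


@dataclass
class DegradationCall:
    gene_name: str
    category: str
    disruption_fraction: float | None
    evidence: AlignmentEvidence | None
    notes: str = ""

    @property
    def coverage(self) -> float:
        return self.evidence.coverage if self.evidence is not None else 0.0


# ---------------------------------------------------------------------------
# alignment machinery
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            yield num, ch
            num = 0


@dataclass
class _ExonAlignment:
    """Columns of one exon's alignment, in reference coordinates."""

    ref_offset: int
    ref_len: int
    state: list  # per exon-ref-pos: '=', 'X', 'I' (ref base unaligned) or None
    tbase: list  # per exon-ref-pos: aligned target base or None
    tindex: list  # per exon-ref-pos: target index of the aligned base or None
    insertions: list  # (exon_ref_pos, length): target bases inserted before pos
    target: str | None = None     # the target string tindex refers to
    space: str | None = None      # '+'/'-': strand-space of the hit
    space_start: int = 0
    space_end: int = 0

    @classmethod
    def unaligned(cls, ref_offset: int, ref_len: int) -> "_ExonAlignment":
        return cls(ref_offset, ref_len, [None] * ref_len, [None] * ref_len,
                   [None] * ref_len, [])


def _exon_alignment_from_cigar(cigar: str, target: str, t_start: int,
                               ref_offset: int, ref_len: int) -> _ExonAlignment:
    state = [None] * ref_len
    tbase = [None] * ref_len
    tindex = [None] * ref_len
    insertions: list[tuple[int, int]] = []
    rp, tp = 0, t_start
    for ln, op in _parse_cigar(cigar):
        if op in "=X":
            for _ in range(ln):
                state[rp] = "=" if op == "=" else "X"
                tbase[rp] = target[tp]
                tindex[rp] = tp
                rp += 1
                tp += 1
        elif op == "I":  # edlib: query(ref) bases absent from target
            for _ in range(ln):
                state[rp] = "I"
                rp += 1
        elif op == "D":  # edlib: target bases absent from query(ref)
            insertions.append((rp, ln))
            tp += ln
        else:  # pragma: no cover
            raise ValueError(f"unexpected cigar op {op!r}")
    return _ExonAlignment(ref_offset, ref_len, state, tbase, tindex,
                          insertions, target=target)


class GenomeIndex:
    """Doubled forward/reverse-complement views of a circular genome, shared
    across all per-gene searches."""

    def __init__(self, sequence: str):
        self.n = len(sequence)
        seq = sequence.upper()
        self.fwd = seq + seq
        self.rev = revcomp(self.fwd)

    def space(self, strand: str) -> str:
        return self.fwd if strand == "+" else self.rev

    def genomic_interval(self, strand: str, s: int, e: int) -> tuple[int, int, str]:
        """Map a strand-space interval to genomic (start, end, strand), start
        normalized into [0, n); end may exceed n for origin-spanning hits."""
        if strand == "+":
            g_s, g_e = s, e
        else:
            g_s, g_e = 2 * self.n - e, 2 * self.n - s
        if g_s >= self.n:
            g_s -= self.n
            g_e -= self.n
        return g_s, g_e, strand


def _align_in_space(space_str: str, query: str, lo: int = 0,
                    hi: int | None = None) -> tuple[int, int, int, str] | None:
    """Best infix alignment of query within space_str[lo:hi].

    Returns (edit_distance, start, end, cigar) in space coordinates, half-open.
    """
    hi = len(space_str) if hi is None else min(hi, len(space_str))
    lo = max(0, lo)
    if hi - lo < 1:
        return None
    res = edlib.align(query, space_str[lo:hi], mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    s, e = res["locations"][0]
    return res["editDistance"], lo + s, lo + e + 1, res["cigar"]


def _best_global_hit(idx: GenomeIndex, query: str):
    """Best hit over both strands of the doubled genome."""
    best = None
    for strand in "+-":
        hit = _align_in_space(idx.space(strand), query)
        if hit is None:
            continue
        if best is None or hit[0] < best[1][0]:
            best = (strand, hit)
    return best


def _search_gene(idx: GenomeIndex, model: GeneModel) -> list[_ExonAlignment]:
    """Locate each exon of a gene; returns one alignment per exon.

    The longest exon anchors the search; short exons (< 50 bp) are then
    placed in a window predicted from the catalog's intron-length hints,
    walking outward from the anchor in strand-space (where transcription
    order is always left-to-right).  Exons that cannot be placed, or whose
    best hit is noise (edit distance > MAX_EDIT_FRACTION of the exon), are
    reported unaligned.
    """
    exons = model.exon_sequences()
    introns = list(getattr(model, "intron_hints", []) or [None] * (len(exons) - 1))
    if len(introns) != len(exons) - 1:
        introns = [None] * (len(exons) - 1)
    offsets = []
    off = 0
    for ex in exons:
        offsets.append(off)
        off += len(ex)
    aligns: list[_ExonAlignment | None] = [None] * len(exons)
    spaces: list[tuple[str, int, int] | None] = [None] * len(exons)

    anchor = max(range(len(exons)), key=lambda i: len(exons[i]))
    order = [anchor] + [i for i in range(len(exons)) if i != anchor]
    for i in order:
        ex = exons[i]
        hit = None
        windowed = False
        if i != anchor and len(ex) < 50:
            # predict from the nearest already-placed neighbour
            for j, step in ((i - 1, +1), (i + 1, -1)):
                if 0 <= j < len(exons) and spaces[j] is not None:
                    h = introns[min(i, j)]
                    if h is None or h > 10_000:
                        continue
                    strand, s_j, e_j = spaces[j]
                    pad = max(500, h // 2)
                    if step == +1:   # neighbour j is 5' of exon i
                        exp = e_j + h
                        lo, hi = exp - pad, exp + len(ex) + pad
                    else:            # neighbour j is 3' of exon i
                        exp = s_j - h - len(ex)
                        lo, hi = exp - pad, exp + len(ex) + pad
                    h2 = _align_in_space(idx.space(strand), ex, lo, hi)
                    if h2 is not None:
                        hit = (strand, h2)
                        windowed = True
                    break
        if hit is None and not windowed:
            hit = _best_global_hit(idx, ex)
        if hit is None:
            continue
        strand, (ed, s, e, cigar) = hit
        if ed > MAX_EDIT_FRACTION * len(ex):
            continue
        aligns[i] = _exon_alignment_from_cigar(cigar, idx.space(strand), s,
                                               offsets[i], len(ex))
        aligns[i].space = strand
        aligns[i].space_start, aligns[i].space_end = s, e
        spaces[i] = (strand, s, e)
    out = []
    for i, al in enumerate(aligns):
        out.append(al if al is not None
                   else _ExonAlignment.unaligned(offsets[i], len(exons[i])))
    return out


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------


def _frame_preserved(indels: list[tuple[int, int, str]],
                     cluster_gap: int = 10) -> bool:
    """True when every indel cluster leaves the reading frame intact.

    Indels within ``cluster_gap`` reference bases of each other are one
    event (an aligner may split a single long gap into co-optimal adjacent
    runs); the cluster's net length shift must be a multiple of 3.  Distant
    compensating indels do NOT rescue the frame: the segment between them is
    out of frame.
    """
    clusters: list[int] = []
    last_end = None
    for pos, ln, op in sorted(indels):
        shift = ln if op == "ins" else -ln
        if last_end is not None and pos - last_end <= cluster_gap:
            clusters[-1] += shift
        else:
            clusters.append(shift)
        last_end = pos + (ln if op == "del" else 0)
    return all(c % 3 == 0 for c in clusters)


def _match_blocks(state: list) -> list[tuple[int, int]]:
    """Confident blocks: match runs >= MIN_ANCHOR_RUN merged over small gaps."""
    runs = []
    i, L = 0, len(state)
    while i < L:
        if state[i] == "=":
            j = i
            while j < L and state[j] == "=":
                j += 1
            if j - i >= MIN_ANCHOR_RUN:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= BLOCK_MERGE_GAP:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _evidence_from_alignments(model: GeneModel,
                              exon_aligns: list[_ExonAlignment],
                              genetic_code: int = 11,
                              copy_id: str = "best") -> AlignmentEvidence:
    L = len(model.reference_seq)
    state = [None] * L
    tbase = [None] * L
    tindex = [None] * L
    exon_of = [None] * L
    targets: dict[int, str] = {}
    insertions: list[tuple[int, int]] = []
    for e_id, al in enumerate(exon_aligns):
        targets[e_id] = al.target
        for k in range(al.ref_len):
            state[al.ref_offset + k] = al.state[k]
            tbase[al.ref_offset + k] = al.tbase[k]
            tindex[al.ref_offset + k] = al.tindex[k]
            exon_of[al.ref_offset + k] = e_id
        for pos, ln in al.insertions:
            insertions.append((al.ref_offset + pos, ln))
    blocks = _match_blocks(state)
    in_block = [False] * L
    for s, e in blocks:
        for k in range(s, e):
            in_block[k] = True

    aligned = sum(1 for k in range(L) if in_block[k] and state[k] in ("=", "X"))
    matches = sum(1 for k in range(L) if in_block[k] and state[k] == "=")
    ev = AlignmentEvidence(
        gene_name=model.gene_name,
        copy_id=copy_id,
        ref_length=L,
        aligned_ref_bases=aligned,
        matches=matches,
        coverage=aligned / L if L else 0.0,
        identity=matches / aligned if aligned else 0.0,
    )
    # indels confined to confident blocks; everything else is unidentified mass
    i = 0
    while i < L:
        if in_block[i] and state[i] == "I":
            j = i
            while j < L and in_block[j] and state[j] == "I":
                j += 1
            ev.indels.append((i, j - i, "del"))
            i = j
        else:
            i += 1
    for pos, ln in sorted(insertions):
        if any(s < pos < e for s, e in blocks):
            ev.indels.append((pos, ln, "ins"))
    ev.indels.sort()
    ev.frame_preserved = _frame_preserved(ev.indels)

    if model.kind == "CDS":
        stops = stop_codons(genetic_code)
        n_codons = L // 3

        def read_codon(c: int) -> str | None:
            """Codon of the target in the reference frame, or None.

            Primary route: find aligned anchors flanking the codon whose
            target span is colinear with the reference span (net indel shift
            zero) and read the three physical target bases — this is immune
            to an aligner expressing substitutions as scattered I/X/D combos.
            Fallback at block edges: direct columnwise read.
            """
            k = 3 * c
            if not all(in_block[k + t] for t in range(3)):
                return None
            e_id = exon_of[k]
            if e_id is not None and all(exon_of[k + t] == e_id for t in range(3)):
                window = 12
                a_candidates = [a for a in range(k - 1, max(-1, k - 1 - window), -1)
                                if exon_of[a] == e_id and tindex[a] is not None
                                and in_block[a]]
                b_candidates = [b for b in range(k + 3, min(L, k + 3 + window))
                                if exon_of[b] == e_id and tindex[b] is not None
                                and in_block[b]]
                for a in a_candidates:
                    for b in b_candidates:
                        if tindex[b] - tindex[a] == b - a:
                            t0 = tindex[a] + (k - a)
                            return targets[e_id][t0:t0 + 3]
            if all(state[k + t] in ("=", "X") for t in range(3)):
                return "".join(tbase[k + t] for t in range(3))
            return None

        for c in range(n_codons):
            codon = read_codon(c)
            if codon is None:
                continue
            if c == 0:
                ev.start_codon = codon
            if codon in stops:
                if c == n_codons - 1:
                    ev.terminal_stop_present = True
                else:
                    ev.premature_stops.append(c + 1)
    hit_spaces = [(al.space, al.space_start, al.space_end)
                  for al in exon_aligns if al.space is not None]
    if hit_spaces:
        strand = hit_spaces[0][0]
        ev.target_interval = (min(s for _, s, _ in hit_spaces),
                              max(e for _, _, e in hit_spaces), strand)
    return ev


def align_gene_to_reference(region: str, model: GeneModel,
                            genetic_code: int = 11) -> AlignmentEvidence:
    """Align an extracted (spliced) gene region against its reference model.

    The full reference is aligned infix-style within the region; lesions are
    enumerated in reference coordinates.  An empty region yields coverage-0
    evidence.
    """
    L = len(model.reference_seq)
    if not region:
        return AlignmentEvidence(gene_name=model.gene_name, ref_length=L)
    res = edlib.align(model.reference_seq, region.upper(), mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return AlignmentEvidence(gene_name=model.gene_name, ref_length=L)
    s, e = res["locations"][0]
    al = _exon_alignment_from_cigar(res["cigar"], region.upper(), s, 0, L)
    al.space, al.space_start, al.space_end = "+", s, e + 1
    return _evidence_from_alignments(model, [al], genetic_code)


# ---------------------------------------------------------------------------
# disruption and classification
# ---------------------------------------------------------------------------


def compute_disruption(evidence: AlignmentEvidence, model: GeneModel,
                       config: ThresholdConfig | None = None) -> float:
    """Disruption fraction D (see module docstring), capped at 1."""
    L = len(model.reference_seq)
    if L == 0:
        return 0.0
    if config is not None and config.downstream_extent:
        first = L
        if evidence.premature_stops:
            first = min(first, (evidence.premature_stops[0] - 1) * 3)
        frameshifts = [p for p, ln, _ in evidence.indels if ln % 3 != 0]
        if frameshifts:
            first = min(first, frameshifts[0])
        downstream = L - first
        return min(1.0, (evidence.deleted_bases + downstream) / L)
    d = evidence.deleted_bases + evidence.inserted_bases + 3 * len(evidence.premature_stops)
    return min(1.0, d / L)


def classify_gene(evidence: AlignmentEvidence | None, model: GeneModel,
                  config: ThresholdConfig = ThresholdConfig()) -> DegradationCall:
    """Assign the four-level degradation category for one gene.

    Lost: no evidence, or identifiable coverage strictly below
    ``lost_coverage_max`` (the 70% non-detectability rule).  For a CDS,
    functional requires an allowed start codon, no internal stop, preserved
    frame, a terminal stop, and D below ``disruption_moderate_max``; otherwise
    the D threshold separates moderate from severe (D exactly at the threshold
    is severe).  RNA genes are judged on coverage and identity alone.
    """
    if evidence is None:
        return DegradationCall(model.gene_name, LOST, None, None,
                               notes="no locatable homolog")
    if evidence.coverage < config.lost_coverage_max:
        return DegradationCall(model.gene_name, LOST,
                               compute_disruption(evidence, model, config),
                               evidence,
                               notes=f"coverage {evidence.coverage:.2f} below "
                                     f"{config.lost_coverage_max:.2f}")
    if model.kind == "CDS":
        d = compute_disruption(evidence, model, config)
        intact = (
            evidence.start_codon in model.allowed_starts
            and not evidence.premature_stops
            and evidence.frame_preserved
            and evidence.terminal_stop_present
        )
        if intact and d < config.disruption_moderate_max:
            return DegradationCall(model.gene_name, FUNCTIONAL, d, evidence)
        if d < config.disruption_moderate_max:
            reasons = []
            if evidence.premature_stops:
                reasons.append(f"internal stops at codons {evidence.premature_stops}")
            if not evidence.frame_preserved:
                reasons.append("frameshift indel")
            if evidence.start_codon not in model.allowed_starts:
                reasons.append(f"start codon {evidence.start_codon or 'absent'}")
            if not evidence.terminal_stop_present:
                reasons.append("terminal stop absent")
            return DegradationCall(model.gene_name, MODERATE, d, evidence,
                                   notes="; ".join(reasons))
        return DegradationCall(model.gene_name, SEVERE, d, evidence)
    # RNA genes: coverage/identity rule
    d = 1.0 - evidence.coverage
    if (evidence.coverage >= 1.0 - config.disruption_moderate_max
            and evidence.identity >= config.annotation_min_identity):
        return DegradationCall(model.gene_name, FUNCTIONAL, d, evidence)
    if d < config.disruption_moderate_max:
        return DegradationCall(model.gene_name, MODERATE, d, evidence,
                               notes=f"identity {evidence.identity:.2f}")
    return DegradationCall(model.gene_name, SEVERE, d, evidence)


def classify_plastome(
    plastome: PlastomeRecord,
    catalog: GeneCatalog,
    config: ThresholdConfig = ThresholdConfig(),
    genes: list[str] | None = None,
) -> list[DegradationCall]:
    """Classify every catalog gene of one plastome.

    Evidence for each gene is gathered by aligning the reference model's
    exons against both strands of the doubled genome; for IR-duplicated genes
    the best hit per exon is, by construction, the best-preserved copy, which
    is the copy the sample-level call reports.
    """
    gene_list = list(genes) if genes is not None else list(catalog.models)
    missing = [g for g in gene_list if g not in catalog.models]
    if missing:
        raise KeyError(f"genes not in catalog: {missing}")
    idx = GenomeIndex(plastome.sequence)
    calls = []
    for g in gene_list:
        model = catalog.models[g]
        aligns = _search_gene(idx, model)
        if all(al.space is None for al in aligns):
            calls.append(classify_gene(None, model, config))
            continue
        ev = _evidence_from_alignments(model, aligns, config.genetic_code)
        calls.append(classify_gene(ev, model, config))
    return calls


# ---------------------------------------------------------------------------
# annotation transfer
# ---------------------------------------------------------------------------


def transfer_annotations(
    target: PlastomeRecord,
    reference: PlastomeRecord | GeneCatalog,
    min_identity: float = 0.90,
    config: ThresholdConfig = ThresholdConfig(),
) -> tuple[PlastomeRecord, list[str]]:
    """Annotate a target plastome by homology against reference gene models.

    Each reference gene is aligned (both strands, circle doubled); the best
    non-overlapping hits with block identity >= ``min_identity`` become
    features — up to the expected copy number plus one, so extra copies (a
    triplicated tRNA) are picked up.  Hits recovering less than the lost
    threshold of the reference are annotated as fragments
    (``pseudogene_mark``).  Returns the annotated record and the list of
    genes that could not be placed.
    """
    if isinstance(reference, GeneCatalog):
        catalog = reference
    else:
        from . import plastome_io as _pio
        from ._catalog_defs import group_of

        models: dict[str, GeneModel] = {}
        groups: dict[str, str] = {}
        for f in reference.features:
            if f.kind not in ("CDS", "tRNA", "rRNA") or f.gene_name in models:
                continue
            seq = _pio.spliced_sequence(reference, f)
            hints: list = []
            for (s1, e1, st1), (s2, e2, st2) in zip(f.parts, f.parts[1:]):
                gap = (s2 - e1) if st1 == "+" else (s1 - e2)
                hints.append(gap if (st1 == st2 and 0 <= gap <= 10_000) else None)
            try:
                models[f.gene_name] = GeneModel(
                    f.gene_name, f.kind, seq,
                    [e - s for s, e, _ in f.parts],
                    allowed_starts=frozenset({"ATG", "ACG"})
                    if f.gene_name == "ndhD" else frozenset({"ATG"}),
                    intron_hints=hints,
                )
                groups[f.gene_name] = group_of(f.gene_name)
            except Exception:
                continue  # pseudogenised reference copies are no models
        catalog = GeneCatalog(models, groups)
    n = len(target.sequence)
    unplaced: list[str] = []
    new_feats: list[Feature] = []
    for gname, model in catalog.models.items():
        masked_seq = target.sequence
        expected = 2 if model.expected_ir_copy else 1
        placed = 0
        for copy_i in range(expected + 1):
            idx = GenomeIndex(masked_seq)
            aligns = _search_gene(idx, model)
            if all(al.space is None for al in aligns):
                break
            ev = _evidence_from_alignments(model, aligns, config.genetic_code,
                                           copy_id=f"copy{copy_i + 1}")
            if ev.identity < min_identity or ev.coverage < 0.05:
                break
            parts: list[tuple[int, int, str]] = []
            for al in aligns:
                if al.space is None:
                    continue
                g_s, g_e, strand = idx.genomic_interval(al.space, al.space_start,
                                                        al.space_end)
                if g_e <= n:
                    parts.append((g_s, g_e, strand))
                else:  # origin-spanning: store as two parts
                    hi = (g_s, n, strand)
                    lo = (0, g_e - n, strand)
                    parts.extend([hi, lo] if strand == "+" else [lo, hi])
            if not parts:
                break
            kind = model.kind if ev.coverage >= config.lost_coverage_max \
                else "pseudogene_mark"
            quals = {"identity": f"{ev.identity:.3f}",
                     "coverage": f"{ev.coverage:.3f}"}
            if kind == "pseudogene_mark":
                quals["note"] = "fragment"
            new_feats.append(Feature(gname, kind, parts, quals))
            placed += 1
            # mask all copies of the hit so the next iteration finds the next one
            m = list(masked_seq)
            for s, e, _ in parts:
                for p in range(s, e):
                    m[p % n] = "N"
            masked_seq = "".join(m)
        if placed == 0:
            unplaced.append(gname)
    annotated = PlastomeRecord(target.sample_id, target.sequence,
                               target.is_circular, new_feats, target.source)
    return annotated, unplaced
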