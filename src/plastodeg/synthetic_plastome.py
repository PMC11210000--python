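"""Synthetic plastome generator with ground-truth degradation labels.

Builds reference-grade circular quadripartite genomes from the gene catalog
(LSC / IRB / SSC / IRA, with the IR content, the trans-spliced rps12, the
ndhC–ndhK–ndhJ operon, SSC-resident ndh genes and a ycf1 spanning the
SSC/IRA junction), then applies parameterised degradation events — premature
stops, frame-breaking and in-frame indels, 3' truncations, whole-gene
deletions, partial retention — plus structural operations (deletion-driven
IRB/SSC boundary shift after ndhF loss; one-sided tRNA triplication).

Ground-truth categories are *computed*, not asserted: each gene's event list
is converted to the analytic :class:`AlignmentEvidence` it implies, and the
shared :func:`classify_gene` assigns the truth label with the same threshold
config the classifier uses.  Generator and classifier therefore cannot
silently diverge on the category rules.

Unless an event is flagged as a boundary probe, generated disruption
fractions avoid [0.08, 0.12] and retained coverage avoids [0.25, 0.35],
guaranteeing a margin around the classification thresholds.
"""

from __future__ import annotations

import copy
import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import _catalog_defs as defs
from .degradation_classifier import (
    AlignmentEvidence,
    DegradationCall,
    ThresholdConfig,
    _frame_preserved,
    classify_gene,
)
from .plastome_io import (
    Feature,
    GeneCatalog,
    PlastomeRecord,
    load_gene_catalog,
    revcomp,
    spliced_sequence,
    write_fasta,
    write_genbank,
)
from .structure_analysis import partition_quadripartite

__all__ = [
    "DegradationEvent",
    "DegradationScenario",
    "build_reference_plastome",
    "apply_degradation",
    "emit_fixture_set",
    "FixtureSet",
    "MarginError",
]

EVENT_OPS = ("point_stop", "frameshift_indel", "inframe_del",
             "truncate_3prime", "delete_gene", "degrade_to_fraction")

# margin bands around the classification thresholds (see module docstring)
DISRUPTION_MARGIN = (0.08, 0.12)
COVERAGE_MARGIN = (0.25, 0.35)


class MarginError(ValueError):
    """An event lands inside the threshold margin without boundary_probe."""


@dataclass(frozen=True)
class DegradationEvent:
    """One lesion applied to one gene.

    Parameters are interpreted per op: ``codon_index`` (1-based) for
    point_stop; ``offset``/``length``/``indel_type`` for the indel ops
    (offsets in spliced coordinates); ``fraction`` for truncate_3prime;
    ``retained_fraction`` for degrade_to_fraction.
    """

    gene_name: str
    op: str
    codon_index: int = 0
    offset: int = 0
    length: int = 0
    indel_type: str = "del"
    fraction: float = 0.0
    retained_fraction: float = 1.0
    applies_to_copy: str = "all"   # all | IRA | IRB | single
    boundary_probe: bool = False

    def __post_init__(self) -> None:
        if self.op not in EVENT_OPS:
            raise ValueError(f"unknown degradation op {self.op!r}")
        if self.op == "frameshift_indel" and self.length % 3 == 0:
            raise ValueError("frameshift_indel length must not be a multiple of 3")
        if self.op == "inframe_del" and self.length % 3 != 0:
            raise ValueError("inframe_del length must be a multiple of 3")
        if self.op == "truncate_3prime" and not (0.0 < self.fraction <= 1.0):
            raise ValueError("truncate_3prime fraction must be in (0, 1]")
        if self.op == "degrade_to_fraction" and not (0.0 < self.retained_fraction <= 1.0):
            raise ValueError("degrade_to_fraction retained_fraction must be in (0, 1]")


@dataclass
class DegradationScenario:
    """Events plus optional structural operations; the seed is mandatory."""

    events: list[DegradationEvent]
    seed: int
    shift_ssc_ir_boundary: bool = False
    triplicate_trna: str | None = None
    resize_spacers_total_bp: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("scenario seed is mandatory")


# ---------------------------------------------------------------------------
# reference genome construction
# ---------------------------------------------------------------------------


def _entry_exon_seqs(entry_name: str, catalog: GeneCatalog) -> list[str]:
    base = entry_name.split(":")[0]
    ref = catalog.models[base].reference_seq
    if entry_name == "rps12:exon1":
        return [ref[:114]]
    if entry_name == "rps12:exon23":
        return [ref[114:342], ref[342:366]]
    return catalog.models[base].exon_sequences()


def _gene_block(entry, catalog: GeneCatalog, rng: np.random.Generator):
    """Genomic sequence of one gene entry plus exon intervals.

    Returns (sequence, parts) where parts are (start, end) offsets within the
    block in transcription order, relative to block start, plus the strand.
    """
    name, kind, _exons, strand, introns = entry
    exon_seqs = _entry_exon_seqs(name, catalog)
    sense_pieces: list[tuple[str, bool]] = []
    for i, ex in enumerate(exon_seqs):
        sense_pieces.append((ex, True))
        if i < len(introns):
            sense_pieces.append((defs.random_spacer(rng, introns[i], gc=0.34), False))
    sense = "".join(s for s, _ in sense_pieces)
    span = len(sense)
    # exon offsets on the sense concatenation
    offs, cur = [], 0
    for s, is_exon in sense_pieces:
        if is_exon:
            offs.append((cur, cur + len(s)))
        cur += len(s)
    if strand == "+":
        block = sense
        parts = [(a, b, "+") for a, b in offs]
    else:
        block = revcomp(sense)
        parts = [(span - b, span - a, "-") for a, b in offs]
    return block, parts


def build_reference_plastome(
    catalog: GeneCatalog | None = None,
    target_length: int = 150_000,
    seed: int = 1,
    spacer_gc: float = 0.27,
) -> PlastomeRecord:
    """Generate a clean, fully functional quadripartite plastome.

    The gene order, strands and intron sizes come from the catalog layout
    tables; intergenic spacers are i.i.d. random sequence whose sizes are
    drawn from a seeded lognormal and rescaled so the total genome length
    hits ``target_length`` exactly.  IRB is the exact reverse complement of
    IRA.  Identical seeds give byte-identical genomes.
    """
    catalog = catalog or load_gene_catalog()
    rng = np.random.default_rng(seed)
    k_ir = defs.YCF1_IR_OVERLAP

    # --- gene blocks per region (IRA listed SSC->LSC) -----------------------
    lsc_blocks = [(e, *_gene_block(e, catalog, rng)) for e in defs.LSC_GENES]
    ssc_entries = [e for e in defs.SSC_GENES if e[0] != "ycf1"]
    ssc_blocks = [(e, *_gene_block(e, catalog, rng)) for e in ssc_entries]
    ira_blocks = [(e, *_gene_block(e, catalog, rng)) for e in defs.IRA_GENES]
    ycf1_cds = catalog.models["ycf1"].reference_seq
    ycf1_genomic = revcomp(ycf1_cds)            # minus strand
    ycf1_ssc_len = len(ycf1_cds) - k_ir

    fixed_lsc = sum(len(b) for _, b, _ in lsc_blocks)
    fixed_ssc = sum(len(b) for _, b, _ in ssc_blocks) + ycf1_ssc_len
    fixed_ira = k_ir + sum(len(b) for _, b, _ in ira_blocks)

    # --- spacer slots -------------------------------------------------------
    # LSC: before each gene and one trailing slot; SSC: before each gene and
    # one between rps15 and ycf1; IRA: between the ycf1 IR stub / genes and
    # one trailing slot before the origin.
    operon_after = {"ndhJ", "ndhK"}   # fixed 12 bp spacers inside the operon
    slots: list[dict] = []
    for region, blocks, extra in (("LSC", lsc_blocks, 1),
                                  ("SSC", ssc_blocks, 1),
                                  ("IRA", ira_blocks, 1)):
        prev = None
        for entry, _, _ in blocks:
            fixed = 12 if (prev in operon_after and region == "LSC") else None
            slots.append({"region": region, "fixed": fixed})
            prev = entry[0]
        for _ in range(extra):
            slots.append({"region": region, "fixed": None})
    fixed_spacer = sum(s["fixed"] or 0 for s in slots if s["region"] != "IRA") \
        + 2 * sum(s["fixed"] or 0 for s in slots if s["region"] == "IRA")
    budget = target_length - (fixed_lsc + fixed_ssc + 2 * fixed_ira) - fixed_spacer
    free = [s for s in slots if s["fixed"] is None]
    # region-specific spacer scale: plastome LSCs are spacer-rich while the
    # IRs and SSC are gene-dense
    mean_bp = {"LSC": 420.0, "SSC": 200.0, "IRA": 160.0}
    weight_sum = 0.0
    for s in free:
        s["w"] = float(rng.lognormal(mean=np.log(mean_bp[s["region"]]), sigma=0.6))
        weight_sum += s["w"] * (2.0 if s["region"] == "IRA" else 1.0)
    if budget < 2 * len(free):
        raise ValueError(f"target_length {target_length} infeasible: "
                         f"gene content needs {target_length - budget} bp")
    scale = budget / weight_sum
    assigned = 0
    for s in free:
        s["len"] = max(2, int(round(s["w"] * scale)))
        assigned += s["len"] * (2 if s["region"] == "IRA" else 1)
    # absorb the rounding residual in the trailing LSC slot
    residual = budget - assigned
    trailing_lsc = [s for s in free if s["region"] == "LSC"][-1]
    trailing_lsc["len"] = max(2, trailing_lsc["len"] + residual)
    for s in slots:
        if s["fixed"] is not None:
            s["len"] = s["fixed"]
        s["seq"] = defs.random_spacer(rng, s["len"], gc=spacer_gc)

    slot_iter = iter(slots)

    def region_slots(region, count):
        out = []
        for s in slot_iter:
            if s["region"] != region:  # pragma: no cover - construction order
                raise RuntimeError("slot bookkeeping error")
            out.append(s["seq"])
            if len(out) == count:
                return out
        raise RuntimeError("slot bookkeeping error")  # pragma: no cover

    lsc_sp = region_slots("LSC", len(lsc_blocks) + 1)
    ssc_sp = region_slots("SSC", len(ssc_blocks) + 1)
    ira_sp = region_slots("IRA", len(ira_blocks) + 1)

    # --- assemble IRA (local coordinates) -----------------------------------
    ira_seq_parts = [ycf1_genomic[ycf1_ssc_len:]]       # ycf1 5' stub
    ira_local_feats: list[Feature] = []
    cur = k_ir
    for (entry, block, parts), sp in zip(ira_blocks, ira_sp[:-1]):
        ira_seq_parts.append(sp)
        cur += len(sp)
        ira_seq_parts.append(block)
        abs_parts = [(cur + a, cur + b, st) for a, b, st in parts]
        name, kind = entry[0], entry[1]
        ira_local_feats.append(Feature(name, kind, abs_parts))
        cur += len(block)
    ira_seq_parts.append(ira_sp[-1])
    ira_seq = "".join(ira_seq_parts)
    L_ir = len(ira_seq)

    # --- assemble LSC and SSC ------------------------------------------------
    def assemble(blocks, spacers, offset):
        seq_parts, feats = [], []
        cur = offset
        for (entry, block, parts), sp in zip(blocks, spacers[:-1]):
            seq_parts.append(sp)
            cur += len(sp)
            abs_parts = [(cur + a, cur + b, st) for a, b, st in parts]
            feats.append(Feature(entry[0], entry[1], abs_parts))
            seq_parts.append(block)
            cur += len(block)
        seq_parts.append(spacers[-1])
        return "".join(seq_parts), feats

    lsc_seq, lsc_feats = assemble(lsc_blocks, lsc_sp, 0)
    off_irb = len(lsc_seq)
    off_ssc = off_irb + L_ir
    ssc_core_seq, ssc_feats = assemble(ssc_blocks, ssc_sp, off_ssc)
    ssc_seq = ssc_core_seq + ycf1_genomic[:ycf1_ssc_len]
    off_ira = off_ssc + len(ssc_seq)

    genome = lsc_seq + revcomp(ira_seq) + ssc_seq + ira_seq
    n = len(genome)
    assert n == target_length, (n, target_length)

    # --- features ------------------------------------------------------------
    feats: list[Feature] = list(lsc_feats) + list(ssc_feats)

    def mirror_parts(parts):
        # keep exon order: the mirror of exon i is exon i of the other copy
        out = []
        for a, b, st in parts:
            out.append((off_irb + L_ir - b, off_irb + L_ir - a,
                        "-" if st == "+" else "+"))
        return out

    rps12_lsc = next(f for f in feats if f.gene_name == "rps12:exon1")
    feats.remove(rps12_lsc)
    exon1_part = rps12_lsc.parts[0]

    for f in ira_local_feats:
        abs_parts = [(off_ira + a, off_ira + b, st) for a, b, st in f.parts]
        irb_parts = mirror_parts(f.parts)
        if f.gene_name == "rps12:exon23":
            feats.append(Feature("rps12", "CDS", [exon1_part] + abs_parts,
                                 {"note": "trans-spliced; IRA copy of 3' exons"}))
            feats.append(Feature("rps12", "CDS", [exon1_part] + irb_parts,
                                 {"note": "trans-spliced; IRB copy of 3' exons"}))
        else:
            feats.append(Feature(f.gene_name, f.kind, abs_parts))
            feats.append(Feature(f.gene_name, f.kind, irb_parts))

    # functional ycf1 spanning the SSC/IRA junction, plus its IRB fragment
    y_start = off_ira + k_ir - len(ycf1_cds)
    feats.append(Feature("ycf1", "CDS", [(y_start, off_ira + k_ir, "-")]))
    feats.append(Feature("ycf1", "pseudogene_mark",
                         [(off_irb + L_ir - k_ir, off_irb + L_ir, "+")],
                         {"note": "fragment (IR mirror of the ycf1 5' portion)"}))

    feats.sort(key=lambda f: f.span[0])
    rec = PlastomeRecord("reference", genome, True, feats, source="synthetic")
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------


def _spliced_to_genomic_ranges(feature: Feature, a: int, b: int
                               ) -> list[tuple[int, int]]:
    """Genomic intervals covered by spliced range [a, b) of a feature."""
    out = []
    off = 0
    for s, e, st in feature.parts:
        ln = e - s
        lo, hi = max(a, off), min(b, off + ln)
        if lo < hi:
            if st == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += ln
    return out


def _adjust_pos(p: int, dels: list[tuple[int, int]],
                ins: list[tuple[int, int]]) -> int:
    shift = 0
    for s, e in dels:
        if p >= e:
            shift -= e - s
        elif p > s:
            shift -= p - s
    for pos, ln in ins:
        if p >= pos:
            shift += ln
    return p + shift


class _Editor:
    """Collects substitutions/indels and applies them to a record at once."""

    def __init__(self, record: PlastomeRecord):
        self.record = record
        self.subs: list[tuple[int, str]] = []
        self.dels: list[tuple[int, int]] = []
        self.ins: list[tuple[int, str, bool]] = []   # (pos, text, extend_part)
        self.drop_features: set[int] = set()

    def apply(self) -> PlastomeRecord:
        seq = list(self.record.sequence)
        for p, b in self.subs:
            seq[p] = b
        edits: list[tuple[int, int, str]] = []   # (pos, del_len, ins_text)
        for s, e in self.dels:
            edits.append((s, e - s, ""))
        for p, txt, _ in self.ins:
            edits.append((p, 0, txt))
        for pos, dlen, txt in sorted(edits, key=lambda t: -t[0]):
            seq[pos:pos + dlen] = list(txt)
        new_seq = "".join(seq)
        dels = sorted(self.dels)
        ins_pts = sorted((p, len(t)) for p, t, _ in self.ins)
        extend = {p: len(t) for p, t, ext in self.ins if ext}
        feats = []
        for idx, f in enumerate(self.record.features):
            if idx in self.drop_features:
                continue
            parts = []
            for s, e, st in f.parts:
                # an insertion strictly inside a part extends it: the part end
                # shifts, the part start only shifts for insertions before it
                ns = _adjust_pos(s, dels, [(p, l) for p, l in ins_pts if p <= s])
                ne = _adjust_pos(e, dels, ins_pts)
                if ne > ns:
                    parts.append((ns, ne, st))
            if parts:
                feats.append(Feature(f.gene_name, f.kind, parts, dict(f.qualifiers)))
        rec = PlastomeRecord(self.record.sample_id, new_seq,
                             self.record.is_circular, feats, self.record.source)
        rec.validate()
        return rec


_STOP_PREFERENCE = ("TGA", "TAA", "TAG")


def _select_copies(record: PlastomeRecord, gene: str, which: str) -> list[Feature]:
    copies = record.features_named(gene, kinds=("CDS", "tRNA", "rRNA"))
    if not copies:
        raise KeyError(f"unknown gene {gene!r}")
    if which == "all" or len(copies) == 1:
        return copies if which != "single" else copies[:1]
    if which == "single":
        return copies[:1]
    part = partition_quadripartite(record)
    wanted = []
    for f in copies:
        region = part.region_of(f.parts[0][0])
        if region == which:
            wanted.append(f)
    if not wanted:
        raise ValueError(f"no copy of {gene} in region {which}")
    return wanted


def _apply_event(editor: _Editor, record: PlastomeRecord, ev: DegradationEvent,
                 rng: np.random.Generator) -> None:
    copies = _select_copies(record, ev.gene_name, ev.applies_to_copy)
    ins_txt = "".join(rng.choice(list("ACGT"), size=ev.length)) \
        if ev.op == "frameshift_indel" and ev.indel_type == "ins" else ""
    for feat in copies:
        L = feat.length
        if ev.op == "point_stop":
            a = 3 * (ev.codon_index - 1)
            if a + 3 > L:
                raise ValueError(f"{ev.gene_name}: codon {ev.codon_index} out of range")
            current = spliced_sequence(record, feat)[a:a + 3]
            target = min(_STOP_PREFERENCE,
                         key=lambda s: (sum(x != y for x, y in zip(s, current)),
                                        _STOP_PREFERENCE.index(s)))
            for t in range(3):
                if current[t] == target[t]:
                    continue
                (gs, ge), = _spliced_to_genomic_ranges(feat, a + t, a + t + 1)
                strand = next(st for s, e, st in feat.parts if s <= gs < e)
                base = target[t] if strand == "+" else revcomp(target[t])
                editor.subs.append((gs, base))
        elif ev.op in ("frameshift_indel", "inframe_del"):
            if ev.op == "inframe_del" or ev.indel_type == "del":
                if ev.offset + ev.length > L:
                    raise ValueError(f"{ev.gene_name}: deletion out of range")
                for gs, ge in _spliced_to_genomic_ranges(feat, ev.offset,
                                                         ev.offset + ev.length):
                    editor.dels.append((gs, ge))
            else:
                (gs, _), = _spliced_to_genomic_ranges(feat, ev.offset, ev.offset + 1)
                strand = next(st for s, e, st in feat.parts if s <= gs < e)
                gpos = gs if strand == "+" else gs + 1
                gtxt = ins_txt if strand == "+" else revcomp(ins_txt)
                editor.ins.append((gpos, gtxt, True))
        elif ev.op in ("truncate_3prime", "degrade_to_fraction"):
            if ev.op == "truncate_3prime":
                cut = L - int(round(L * ev.fraction))
            else:
                cut = int(round(L * ev.retained_fraction))
            for gs, ge in _spliced_to_genomic_ranges(feat, cut, L):
                editor.dels.append((gs, ge))
        elif ev.op == "delete_gene":
            for s, e, _ in feat.parts:
                editor.dels.append((s, e))
            editor.drop_features.add(record.features.index(feat))


def _truth_evidence(model, events: list[DegradationEvent]
                    ) -> AlignmentEvidence | None:
    """Analytic evidence implied by a gene's event list (shared thresholds)."""
    L = len(model.reference_seq)
    retained_end = L
    stops: list[int] = []
    indels: list[tuple[int, int, str]] = []
    for ev in events:
        if ev.op == "delete_gene":
            return None
        if ev.op == "degrade_to_fraction":
            retained_end = min(retained_end, int(round(L * ev.retained_fraction)))
        elif ev.op == "truncate_3prime":
            retained_end = min(retained_end, L - int(round(L * ev.fraction)))
        elif ev.op == "point_stop":
            stops.append(ev.codon_index)
        elif ev.op in ("frameshift_indel", "inframe_del"):
            kind = "del" if (ev.op == "inframe_del" or ev.indel_type == "del") else "ins"
            indels.append((ev.offset, ev.length, kind))
    stops = sorted({c for c in stops if 3 * c <= retained_end})
    indels = sorted((o, ln, k) for o, ln, k in indels if o + (ln if k == "del" else 0)
                    <= retained_end)
    deleted_internal = sum(ln for _, ln, k in indels if k == "del")
    aligned = retained_end - deleted_internal
    if aligned < 12:        # below the classifier's anchor-run resolution
        aligned = 0
    ev_ = AlignmentEvidence(
        gene_name=model.gene_name,
        ref_length=L,
        aligned_ref_bases=aligned,
        matches=max(0, aligned - 2 * len(stops)),
        coverage=aligned / L if L else 0.0,
        identity=(max(0, aligned - 2 * len(stops)) / aligned) if aligned else 0.0,
        indels=indels,
        premature_stops=stops,
        start_codon=model.reference_seq[:3] if retained_end >= 3 else None,
        terminal_stop_present=(retained_end == L),
        frame_preserved=_frame_preserved(indels),
    )
    return ev_ if aligned > 0 else None


def apply_degradation(
    plastome: PlastomeRecord,
    scenario: DegradationScenario,
    catalog: GeneCatalog | None = None,
    config: ThresholdConfig = ThresholdConfig(),
    sample_id: str | None = None,
) -> tuple[PlastomeRecord, pd.DataFrame]:
    """Apply a degradation scenario; returns the degraded record plus the
    truth table (one row per catalog gene: expected category, disruption and
    coverage, computed with the classifier's own rules).

    Events are applied in listed order; IR copies are kept identical unless
    ``applies_to_copy`` says otherwise.  Raises :class:`MarginError` when an
    event lands in the threshold margin bands without ``boundary_probe``.
    """
    catalog = catalog or load_gene_catalog()
    rng = np.random.default_rng(scenario.seed)
    by_gene: dict[str, list[DegradationEvent]] = {}
    for ev in scenario.events:
        if ev.gene_name not in catalog.models:
            raise KeyError(f"unknown gene {ev.gene_name!r}")
        by_gene.setdefault(ev.gene_name, []).append(ev)

    # truth first (also validates margins before any editing)
    truth_rows = []
    sid = sample_id or plastome.sample_id
    for gname, model in catalog.models.items():
        evs = by_gene.get(gname, [])
        ev_truth = _truth_evidence(model, evs)
        call: DegradationCall = classify_gene(ev_truth, model, config)
        if evs and not any(e.boundary_probe for e in evs):
            d = call.disruption_fraction
            cov = ev_truth.coverage if ev_truth is not None else 0.0
            if d is not None and DISRUPTION_MARGIN[0] <= d <= DISRUPTION_MARGIN[1]:
                raise MarginError(f"{gname}: disruption {d:.3f} inside margin "
                                  f"{DISRUPTION_MARGIN}")
            if COVERAGE_MARGIN[0] <= cov <= COVERAGE_MARGIN[1]:
                raise MarginError(f"{gname}: coverage {cov:.3f} inside margin "
                                  f"{COVERAGE_MARGIN}")
        truth_rows.append({
            "sample_id": sid,
            "gene": gname,
            "category": call.category,
            "disruption": call.disruption_fraction,
            "coverage": ev_truth.coverage if ev_truth is not None else 0.0,
        })
    truth = pd.DataFrame(truth_rows)

    editor = _Editor(plastome)
    for ev in scenario.events:
        _apply_event(editor, plastome, ev, rng)
    record = editor.apply()
    record.sample_id = sid

    if scenario.triplicate_trna:
        record = _triplicate_trna(record, scenario.triplicate_trna)
    if scenario.shift_ssc_ir_boundary:
        record = _shift_boundary(record)
    record.validate()
    return record, truth


def _triplicate_trna(record: PlastomeRecord, name: str) -> PlastomeRecord:
    """Insert an extra copy of a tRNA next to its IRA copy (one IR only)."""
    copies = record.features_named(name, kinds=("tRNA",))
    if not copies:
        raise KeyError(f"unknown tRNA {name!r}")
    part = partition_quadripartite(record)
    ira_copy = None
    for f in copies:
        if part.region_of(f.parts[0][0]) == "IRA":
            ira_copy = f
            break
    ira_copy = ira_copy or copies[-1]
    s, e, st = ira_copy.parts[0]
    gap = 30
    insert_at = e + gap
    segment = record.sequence[s:e]
    new_seq = record.sequence[:insert_at] + segment + record.sequence[insert_at:]
    feats = []
    for f in record.features:
        parts = [(a + (len(segment) if a >= insert_at else 0),
                  b + (len(segment) if b > insert_at else 0), stt)
                 for a, b, stt in f.parts]
        feats.append(Feature(f.gene_name, f.kind, parts, dict(f.qualifiers)))
    feats.append(Feature(name, "tRNA", [(insert_at, insert_at + len(segment), st)],
                         {"note": "duplicated copy in close proximity"}))
    feats.sort(key=lambda f: f.span[0])
    rec = PlastomeRecord(record.sample_id, new_seq, record.is_circular, feats,
                         record.source)
    rec.validate()
    return rec


def _shift_boundary(record: PlastomeRecord) -> PlastomeRecord:
    """Deletion-driven IRB/SSC boundary shift following complete ndhF loss.

    Removes the residual spacer between the junction and rpl32 (leaving
    ~100 bp) so the junction sits in the rpl32-adjacent spacer right next to
    the ycf1 fragment at the IRB end.
    """
    if record.features_named("ndhF", kinds=("CDS",)):
        raise ValueError("boundary shift requires ndhF to be deleted first")
    part = partition_quadripartite(record)
    ssc_start = part.ssc[0]
    rpl32 = record.features_named("rpl32", kinds=("CDS",))
    if not rpl32:
        raise ValueError("rpl32 not annotated; cannot model boundary shift")
    target = rpl32[0].span[0] - 100
    if target <= ssc_start:
        return record
    editor = _Editor(record)
    editor.dels.append((ssc_start, target))
    rec = editor.apply()
    return rec


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------


@dataclass
class FixtureSet:
    out_dir: Path
    reference: PlastomeRecord
    samples: list[PlastomeRecord]
    scenarios: list[DegradationScenario]
    truth: pd.DataFrame
    tree_path: Path


def _moderate_event(g: str, model, rng) -> DegradationEvent:
    n_codons = model.n_codons
    choice = rng.integers(0, 3)
    if g == "ndhB" and rng.random() < 0.6:
        return DegradationEvent(g, "point_stop", codon_index=68)
    if choice == 0:
        return DegradationEvent(g, "point_stop",
                                codon_index=int(rng.integers(5, n_codons - 8)))
    offset = _safe_offset(model, rng, length=5)
    if choice == 1:
        return DegradationEvent(g, "frameshift_indel", offset=offset,
                                length=int(rng.choice([1, 2, 4])), indel_type="del")
    return DegradationEvent(g, "frameshift_indel", offset=offset,
                            length=int(rng.choice([1, 2, 4])), indel_type="ins")


def _safe_offset(model, rng, length: int) -> int:
    """Spliced offset at least 30 bp inside one exon."""
    exons = model.exon_lengths
    starts, cur = [], 0
    candidates = []
    for ln in exons:
        if ln >= 2 * 30 + length + 2:
            candidates.append((cur, ln))
        cur += ln
    off0, ln = candidates[int(rng.integers(0, len(candidates)))]
    return off0 + int(rng.integers(30, ln - 30 - length))


def _severe_event(g: str, model, rng) -> list[DegradationEvent]:
    f = float(rng.uniform(0.15, 0.55))
    events = [DegradationEvent(g, "truncate_3prime", fraction=f)]
    retained_codons = (model.n_codons * (1 - f))
    if rng.random() < 0.4 and retained_codons > 20:
        events.insert(0, DegradationEvent(
            g, "point_stop", codon_index=int(rng.integers(5, retained_codons - 8))))
    return events


def _lost_event(g: str, rng) -> DegradationEvent:
    if rng.random() < 0.5:
        return DegradationEvent(g, "delete_gene")
    return DegradationEvent(g, "degrade_to_fraction",
                            retained_fraction=float(rng.uniform(0.06, 0.22)))


#: per-gene category weights of the dipodium_like profile:
#: (moderate, severe, lost) — every ndh gene is non-functional in every sample
_DIPODIUM_NDH_WEIGHTS = {
    "ndhA": (0.2, 0.7, 0.1),
    "ndhB": (0.6, 0.4, 0.0),
    "ndhC": (0.1, 0.5, 0.4),
    "ndhD": (0.7, 0.3, 0.0),
    "ndhE": (0.5, 0.3, 0.2),
    "ndhF": (0.0, 0.85, 0.15),
    "ndhG": (0.0, 0.1, 0.9),
    "ndhH": (0.3, 0.6, 0.1),
    "ndhI": (0.5, 0.3, 0.2),
    "ndhJ": (0.5, 0.5, 0.0),
    "ndhK": (0.1, 0.15, 0.75),
}


def dipodium_scenario(catalog: GeneCatalog, seed: int,
                      force_ndhf_loss: bool = False) -> DegradationScenario:
    """A dipodium_like sample: all 11 ndh genes degraded to some degree,
    occasional trnV-GAC triplication, and (when ndhF is fully lost) the
    associated IRB/SSC boundary shift."""
    rng = np.random.default_rng(seed)
    events: list[DegradationEvent] = []
    ndhf_lost = force_ndhf_loss
    for g, (wm, ws, wl) in _DIPODIUM_NDH_WEIGHTS.items():
        model = catalog.models[g]
        if g == "ndhF":
            if not force_ndhf_loss and rng.random() < wl:
                ndhf_lost = True
            if ndhf_lost:
                events.append(DegradationEvent(g, "delete_gene"))
            else:
                events.extend(_severe_event(g, model, rng))
            continue
        r = rng.random()
        if r < wm:
            events.append(_moderate_event(g, model, rng))
        elif r < wm + ws:
            events.extend(_severe_event(g, model, rng))
        else:
            events.append(_lost_event(g, rng))
    return DegradationScenario(
        events=events,
        seed=int(rng.integers(0, 2**31 - 1)),
        shift_ssc_ir_boundary=ndhf_lost,
        triplicate_trna="trnV-GAC" if rng.random() < 0.25 else None,
    )


def emit_fixture_set(
    out_dir: str | Path,
    n_samples: int = 24,
    profile: str = "dipodium_like",
    seed: int = 42,
    catalog: GeneCatalog | None = None,
    target_length: int = 150_000,
    scenarios: list[DegradationScenario] | None = None,
    config: ThresholdConfig = ThresholdConfig(),
) -> FixtureSet:
    """Write a fixture directory: clean reference + n degraded samples
    (GenBank and FASTA), the truth table (TSV) and a random coalescent tree
    over the sample ids (Newick).  Fixed seeds give identical content.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if profile not in ("dipodium_like", "custom"):
        raise ValueError(f"unknown profile {profile!r}")
    if profile == "custom" and scenarios is None:
        raise ValueError("custom profile requires explicit scenarios")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = catalog or load_gene_catalog()
    rng = np.random.default_rng(seed)
    reference = build_reference_plastome(catalog, target_length=target_length,
                                         seed=int(rng.integers(0, 2**31 - 1)))
    if profile == "dipodium_like":
        scenarios = [
            dipodium_scenario(catalog, seed=int(rng.integers(0, 2**31 - 1)),
                              force_ndhf_loss=(i == 0))
            for i in range(n_samples)
        ]
    samples, truths = [], []
    for i, scn in enumerate(scenarios, start=1):
        sid = f"sample_{i:02d}"
        rec, truth = apply_degradation(copy.deepcopy(reference), scn, catalog,
                                       config, sample_id=sid)
        samples.append(rec)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)

    write_genbank([reference], out_dir / "reference.gb")
    write_fasta([("reference", reference.sequence)], out_dir / "reference.fasta")
    for rec in samples:
        write_genbank([rec], out_dir / f"{rec.sample_id}.gb")
        write_fasta([(rec.sample_id, rec.sequence)],
                    out_dir / f"{rec.sample_id}.fasta")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)

    taxa = dendropy.TaxonNamespace([r.sample_id for r in samples])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1,
        rng=_pyrandom.Random(int(rng.integers(0, 2**31 - 1))))
    tree_path = out_dir / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick", unquoted_underscores=True)
    return FixtureSet(out_dir, reference, samples, scenarios, truth, tree_path)
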