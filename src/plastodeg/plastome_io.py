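"""Reading, writing and in-memory containers for plastome data.

The module hosts the shared coordinate conventions of the package:

* intervals are 0-based, half-open, strand in ``{"+", "-"}``;
* GenBank's 1-based inclusive coordinates are converted at the I/O boundary;
* multi-exon (including *trans*-spliced) genes are ordered lists of parts in
  transcription order, so splicing is a plain concatenation;
* circular sequences are stored unwrapped; a feature crossing the origin is
  stored as two parts.

File formats go through Biopython (GenBank, FASTA) and DendroPy (Newick);
the domain types below are what the rest of the package computes on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "PlastomeRecord",
    "GeneModel",
    "GeneCatalog",
    "PlastomeIOError",
    "CatalogError",
    "revcomp",
    "gc_fraction",
    "spliced_sequence",
    "rotate_record",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "load_gene_catalog",
    "stop_codons",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene_mark", "other")


class PlastomeIOError(ValueError):
    """Malformed input file or invalid record."""


class CatalogError(ValueError):
    """A gene catalog entry failed validation."""


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented verbatim."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content as (G+C)/(A+C+G+T); ambiguity bases and N are excluded.

    Raises ``ValueError`` when no unambiguous base is present.
    """
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous A/C/G/T base")
    return (s.count("G") + s.count("C")) / acgt


def stop_codons(table_id: int = 11) -> frozenset[str]:
    """Stop codons of an NCBI translation table (default: bacterial/plastid 11)."""
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """A strand-aware, possibly multi-part gene annotation.

    ``parts`` is an ordered list of ``(start, end, strand)`` tuples in
    transcription order (0-based half-open). For minus-strand genes the parts
    therefore run from high to low coordinates.
    """

    gene_name: str
    kind: str
    parts: list[tuple[int, int, str]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PlastomeIOError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise PlastomeIOError(f"feature {self.gene_name}: empty part list")
        for s, e, strand in self.parts:
            if not (0 <= s < e):
                raise PlastomeIOError(
                    f"feature {self.gene_name}: bad interval ({s}, {e})"
                )
            if strand not in "+-":
                raise PlastomeIOError(f"feature {self.gene_name}: bad strand {strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e, _ in self.parts)

    @property
    def span(self) -> tuple[int, int]:
        """Smallest genomic interval covering all parts (no wrap handling)."""
        return min(s for s, _, _ in self.parts), max(e for _, e, _ in self.parts)

    @property
    def strand(self) -> str:
        return self.parts[0][2]

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.parts)


@dataclass
class PlastomeRecord:
    """A plastome: circular sequence plus features and sample metadata."""

    sample_id: str
    sequence: str
    is_circular: bool = True
    features: list[Feature] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise PlastomeIOError(f"{self.sample_id}: empty sequence")
        if re.search(r"[^ACGTRYSWKMBDHVN]", self.sequence.upper()):
            raise PlastomeIOError(f"{self.sample_id}: non-IUPAC characters in sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e, _ in f.parts:
                if e > n:
                    raise PlastomeIOError(
                        f"{self.sample_id}: feature {f.gene_name} part ({s},{e}) "
                        f"outside sequence of length {n}"
                    )

    def features_named(self, gene_name: str, kinds: Sequence[str] | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.gene_name == gene_name and (kinds is None or f.kind in kinds)
        ]


def spliced_sequence(record: PlastomeRecord, feature: Feature) -> str:
    """Spliced (transcription-order) sequence of a feature."""
    chunks = []
    for s, e, strand in feature.parts:
        seg = record.sequence[s:e]
        chunks.append(revcomp(seg) if strand == "-" else seg)
    return "".join(chunks)


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular record so original position ``offset`` becomes 0.

    Feature parts are shifted modulo the length; a part that ends up crossing
    the new origin is split into two parts kept in transcription order.
    """
    n = len(record.sequence)
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        parts: list[tuple[int, int, str]] = []
        for s, e, strand in f.parts:
            ns = (s - offset) % n
            ne = ns + (e - s)
            if ne <= n:
                parts.append((ns, ne, strand))
            else:
                hi = (ns, n, strand)
                lo = (0, ne - n, strand)
                # transcription order: plus strand reads low->high genomically
                parts.extend([hi, lo] if strand == "+" else [lo, hi])
        feats.append(Feature(f.gene_name, f.kind, parts, dict(f.qualifiers)))
    return PlastomeRecord(record.sample_id, seq, record.is_circular, feats, record.source)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "pseudogene_mark": "misc_feature", "other": "misc_feature"}


def _feature_from_seqfeature(sf: SeqFeature) -> Feature | None:
    name = None
    for key in ("gene", "locus_tag", "product", "note"):
        if key in sf.qualifiers and sf.qualifiers[key]:
            name = str(sf.qualifiers[key][0])
            break
    if name is None:
        return None
    if sf.type in ("CDS", "tRNA", "rRNA"):
        kind = sf.type
    elif sf.type in ("misc_feature", "gene") and "pseudo" in sf.qualifiers:
        kind = "pseudogene_mark"
    elif sf.type == "gene":
        kind = "other"
    else:
        kind = "other"
    parts = []
    for loc in sf.location.parts:
        strand = "-" if loc.strand == -1 else "+"
        parts.append((int(loc.start), int(loc.end), strand))
    quals = {k: str(v[0]) if isinstance(v, list) and v else str(v)
             for k, v in sf.qualifiers.items()}
    return Feature(name, kind, parts, quals)


def read_genbank(path: str | Path) -> list[PlastomeRecord]:
    """Read one or more LOCUS records from a GenBank flat file.

    Coordinates arrive from Biopython already converted to 0-based half-open;
    joins (including ``complement`` and multi-exon locations) are preserved as
    ordered parts. ``CDS``/``tRNA``/``rRNA`` features are preferred; bare
    ``gene`` features are used only for names with no dedicated feature.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise PlastomeIOError(f"{path}: malformed GenBank record: {exc}") from exc
    if not seq_records:
        raise PlastomeIOError(f"{path}: no GenBank records found")
    out = []
    for sr in seq_records:
        topology = sr.annotations.get("topology", "linear")
        sample_id = sr.id if sr.id not in ("", "<unknown id>") else sr.name
        feats: list[Feature] = []
        named_with_type: set[str] = set()
        gene_only: list[Feature] = []
        for sf in sr.features:
            if sf.type == "source":
                q = sf.qualifiers
                if "sample_id" in q:
                    sample_id = str(q["sample_id"][0])
                continue
            f = _feature_from_seqfeature(sf)
            if f is None:
                continue
            if sf.type == "gene" and "pseudo" not in sf.qualifiers:
                gene_only.append(f)
            else:
                feats.append(f)
                named_with_type.add(f.gene_name)
        # spec open question: accept both gene and CDS dialects, prefer CDS
        for f in gene_only:
            if f.gene_name not in named_with_type:
                feats.append(f)
        rec = PlastomeRecord(
            sample_id=sample_id,
            sequence=str(sr.seq).upper(),
            is_circular=(topology == "circular"),
            features=feats,
            source=str(path),
        )
        rec.validate()
        out.append(rec)
    return out


def write_genbank(records: Iterable[PlastomeRecord], path: str | Path) -> Path:
    """Write records as GenBank; round-trip safe with :func:`read_genbank`."""
    path = Path(path)
    seq_records = []
    for rec in records:
        rec.validate()
        name = re.sub(r"[^A-Za-z0-9_.-]", "_", rec.sample_id)[:16] or "plastome"
        sr = SeqRecord(Seq(rec.sequence), id=rec.sample_id, name=name,
                       description=f"{rec.sample_id} plastome")
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.is_circular else "linear"
        src = SeqFeature(SimpleLocation(0, len(rec.sequence), strand=1), type="source")
        src.qualifiers["sample_id"] = [rec.sample_id]
        sr.features.append(src)
        for f in rec.features:
            locs = [SimpleLocation(s, e, strand=(-1 if st == "-" else 1))
                    for s, e, st in f.parts]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            sf = SeqFeature(loc, type=_KIND_TO_GB[f.kind])
            sf.qualifiers["gene"] = [f.gene_name]
            if f.kind == "pseudogene_mark":
                sf.qualifiers["pseudo"] = [""]
            for k, v in f.qualifiers.items():
                if k not in ("gene", "pseudo"):
                    sf.qualifiers[k] = [v]
            sr.features.append(sf)
        seq_records.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-FASTA as ``(id, sequence)`` pairs; uppercased, U->T."""
    path = Path(path)
    pairs = [(r.id, str(r.seq).upper().replace("U", "T"))
             for r in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise PlastomeIOError(f"{path}: empty FASTA file")
    ids = [i for i, _ in pairs]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise PlastomeIOError(f"{path}: duplicate FASTA ids: {', '.join(dupes)}")
    return pairs


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree; leaf labels are sample ids."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise PlastomeIOError(f"{path}: could not parse Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
    return path


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Reference model of one plastid gene.

    ``reference_seq`` is the spliced sequence (for a CDS: start codon through
    stop codon); ``exon_lengths`` partitions it. ``allowed_starts`` defaults to
    {ATG}; genes with a validated alternative start (ndhD: ACG) are flagged in
    the catalog.
    """

    gene_name: str
    kind: str
    reference_seq: str
    exon_lengths: list[int]
    allowed_starts: frozenset[str] = frozenset({"ATG"})
    expected_ir_copy: bool = False
    junction_spanning: bool = False
    notes: str = ""
    #: approximate intron length between consecutive exons (None where the
    #: exons are unlinked, e.g. across the trans-splice of rps12); used to
    #: predict where short exons sit relative to the longest one
    intron_hints: list | None = None

    def __post_init__(self) -> None:
        if sum(self.exon_lengths) != len(self.reference_seq):
            raise CatalogError(
                f"{self.gene_name}: exon lengths {self.exon_lengths} do not sum "
                f"to reference length {len(self.reference_seq)}"
            )
        if self.kind == "CDS":
            self._validate_cds()

    def _validate_cds(self) -> None:
        seq = self.reference_seq
        if len(seq) % 3 != 0:
            raise CatalogError(f"{self.gene_name}: CDS length {len(seq)} not divisible by 3")
        stops = stop_codons()
        if seq[-3:] not in stops:
            raise CatalogError(f"{self.gene_name}: CDS does not end with a stop codon")
        for i in range(0, len(seq) - 3, 3):
            if seq[i:i + 3] in stops:
                raise CatalogError(
                    f"{self.gene_name}: internal stop codon {seq[i:i+3]} at codon {i//3 + 1}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.reference_seq) // 3

    def exon_sequences(self) -> list[str]:
        out, off = [], 0
        for ln in self.exon_lengths:
            out.append(self.reference_seq[off:off + ln])
            off += ln
        return out


@dataclass
class GeneCatalog:
    """Catalog of functional plastid gene models with functional grouping."""

    models: dict[str, GeneModel]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [g for g in self.models if g not in self.groups]
        if missing:
            raise CatalogError(f"genes without functional group: {missing}")
        ndh = [g for g in self.models if g.startswith("ndh")]
        if len(ndh) != 11:
            raise CatalogError(f"expected the 11 ndh genes, found {len(ndh)}: {sorted(ndh)}")

    def __len__(self) -> int:
        return len(self.models)

    def genes_of_kind(self, kind: str) -> list[str]:
        return [g for g, m in self.models.items() if m.kind == kind]

    @property
    def ndh_genes(self) -> list[str]:
        return [g for g in self.models if g.startswith("ndh")]


def load_gene_catalog(source: str | Path | None = None) -> GeneCatalog:
    """Load the gene catalog.

    With no argument, returns the built-in synthetic catalog covering the full
    functional plastid gene complement (79 CDS, 30 tRNA, 4 rRNA, including all
    11 ndh genes, the trans-spliced rps12 and intron-bearing ndhA/ndhB).
    With a path, builds models from an annotated GenBank file of a functional
    plastome: each CDS/tRNA/rRNA feature becomes a model and CDS models are
    validated (length divisible by 3, terminal stop, no internal stop).
    """
    if source is None:
        from . import _catalog_defs

        return _catalog_defs.builtin_catalog()
    records = read_genbank(source)
    models: dict[str, GeneModel] = {}
    groups: dict[str, str] = {}
    from ._catalog_defs import group_of

    for rec in records:
        for f in rec.features:
            if f.kind not in ("CDS", "tRNA", "rRNA") or f.gene_name in models:
                continue
            seq = spliced_sequence(rec, f)
            hints: list = []
            for (s1, e1, st1), (s2, e2, st2) in zip(f.parts, f.parts[1:]):
                gap = (s2 - e1) if st1 == "+" else (s1 - e2)
                hints.append(gap if (st1 == st2 and 0 <= gap <= 10_000) else None)
            models[f.gene_name] = GeneModel(
                gene_name=f.gene_name,
                kind=f.kind,
                reference_seq=seq,
                exon_lengths=[e - s for s, e, _ in f.parts],
                allowed_starts=frozenset({"ATG", "ACG"}) if f.gene_name == "ndhD"
                else frozenset({"ATG"}),
                junction_spanning=(f.gene_name == "ycf1"),
                intron_hints=hints,
            )
            groups[f.gene_name] = group_of(f.gene_name)
    return GeneCatalog(models, groups)
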