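"""Built-in synthetic gene catalog and canonical plastome layout.

The table below encodes the functional plastid gene complement of a
photosynthetic orchid-type plastome — 79 protein-coding genes, 30 tRNAs and
4 rRNAs — together with the canonical quadripartite layout used by the
synthetic generator: gene order per region, strands, exon structure, intron
sizes and which genes live (duplicated) in the inverted repeat.

Reference sequences are synthetic: deterministic pseudo-random sequences with
realistic lengths and base composition, generated from a fixed internal seed
so the catalog is identical across runs and platforms.  They are stand-ins
for real functional gene sequences (e.g. from a fully photosynthetic
outgroup) and carry no real homology; every pipeline stage that consumes the
catalog treats it exactly as it would a catalog built from an annotated
GenBank reference via ``load_gene_catalog(path)``.

Two deliberate sequence pins:

* ``ndhB`` codon 68 is ``TTA`` and the gene is placed on the minus strand, so
  a single genomic A->C substitution (coding T->G) converts it to the ``TGA``
  stop — the classic exon-1 lesion observed in mycoheterotrophic orchids
  (stop at amino-acid position 68, 201 bp into exon 1).
* ``ndhD`` starts with the alternative start codon ``ACG`` and is flagged
  accordingly.
"""

from __future__ import annotations

import numpy as np

from .plastome_io import GeneCatalog, GeneModel, stop_codons

_CATALOG_SEED = 715_182_3
#: bases of functional ycf1 placed inside the IR (5' portion; SSC/IRA junction)
YCF1_IR_OVERLAP = 500

# (name, kind, exon_lengths, strand, intron_lengths)
# Regions list genes in genomic order.  LSC starts at the IRA/LSC junction
# (position 0 of the normalized circle); IRA is listed from its SSC end to its
# LSC end; IRB is the mirror of IRA and is not listed.
LSC_GENES: list[tuple[str, str, list[int], str, list[int]]] = [
    ("psbA", "CDS", [1062], "-", []),
    ("trnK-UUU", "tRNA", [37, 35], "-", [310]),
    ("matK", "CDS", [1530], "-", []),
    ("rps16", "CDS", [42, 225], "-", [860]),
    ("trnQ-UUG", "tRNA", [72], "-", []),
    ("psbK", "CDS", [186], "+", []),
    ("psbI", "CDS", [111], "+", []),
    ("trnS-GCU", "tRNA", [88], "-", []),
    ("trnG-UCC", "tRNA", [23, 48], "+", [690]),
    ("trnR-UCU", "tRNA", [72], "+", []),
    ("atpA", "CDS", [1524], "-", []),
    ("atpF", "CDS", [144, 411], "-", [700]),
    ("atpH", "CDS", [246], "-", []),
    ("atpI", "CDS", [744], "-", []),
    ("rps2", "CDS", [711], "-", []),
    ("rpoC2", "CDS", [4140], "-", []),
    ("rpoC1", "CDS", [432, 1641], "-", [740]),
    ("rpoB", "CDS", [3213], "-", []),
    ("trnC-GCA", "tRNA", [71], "+", []),
    ("petN", "CDS", [90], "+", []),
    ("psbM", "CDS", [105], "-", []),
    ("trnD-GUC", "tRNA", [74], "-", []),
    ("trnY-GUA", "tRNA", [84], "-", []),
    ("trnE-UUC", "tRNA", [73], "-", []),
    ("trnT-GGU", "tRNA", [72], "+", []),
    ("psbD", "CDS", [1062], "+", []),
    ("psbC", "CDS", [1386], "+", []),
    ("trnS-UGA", "tRNA", [93], "-", []),
    ("psbZ", "CDS", [189], "+", []),
    ("trnG-GCC", "tRNA", [71], "+", []),
    ("trnfM-CAU", "tRNA", [74], "-", []),
    ("rps14", "CDS", [303], "-", []),
    ("psaB", "CDS", [2205], "-", []),
    ("psaA", "CDS", [2253], "-", []),
    ("ycf3", "CDS", [126, 228, 153], "-", [730, 780]),
    ("trnS-GGA", "tRNA", [87], "-", []),
    ("rps4", "CDS", [606], "-", []),
    ("trnT-UGU", "tRNA", [73], "-", []),
    ("trnL-UAA", "tRNA", [35, 50], "+", [500]),
    ("trnF-GAA", "tRNA", [73], "+", []),
    # the ndh operon: ndhJ/ndhK/ndhC adjacent, small spacers
    ("ndhJ", "CDS", [480], "-", []),
    ("ndhK", "CDS", [849], "-", []),
    ("ndhC", "CDS", [363], "-", []),
    ("trnV-UAC", "tRNA", [39, 35], "-", [580]),
    ("trnM-CAU", "tRNA", [73], "+", []),
    ("atpE", "CDS", [402], "-", []),
    ("atpB", "CDS", [1497], "-", []),
    ("rbcL", "CDS", [1428], "+", []),
    ("accD", "CDS", [1464], "+", []),
    ("psaI", "CDS", [111], "+", []),
    ("ycf4", "CDS", [555], "+", []),
    ("cemA", "CDS", [690], "+", []),
    ("petA", "CDS", [963], "+", []),
    ("psbJ", "CDS", [123], "-", []),
    ("psbL", "CDS", [117], "-", []),
    ("psbF", "CDS", [120], "-", []),
    ("psbE", "CDS", [252], "-", []),
    ("petL", "CDS", [96], "+", []),
    ("petG", "CDS", [114], "+", []),
    ("trnW-CCA", "tRNA", [74], "-", []),
    ("trnP-UGG", "tRNA", [74], "-", []),
    ("psaJ", "CDS", [135], "+", []),
    ("rpl33", "CDS", [201], "+", []),
    ("rps18", "CDS", [306], "+", []),
    ("rpl20", "CDS", [354], "-", []),
    ("rps12:exon1", "CDS", [114], "-", []),  # trans-spliced 5' exon
    ("clpP", "CDS", [72, 294, 228], "-", [790, 640]),
    ("psbB", "CDS", [1527], "+", []),
    ("psbT", "CDS", [102], "+", []),
    ("psbN", "CDS", [132], "-", []),
    ("psbH", "CDS", [222], "+", []),
    ("petB", "CDS", [6, 642], "+", [760]),
    ("petD", "CDS", [9, 474], "+", [720]),
    ("rpoA", "CDS", [1014], "-", []),
    ("rps11", "CDS", [417], "-", []),
    ("rpl36", "CDS", [114], "-", []),
    ("infA", "CDS", [234], "-", []),
    ("rps8", "CDS", [405], "-", []),
    ("rpl14", "CDS", [369], "-", []),
    ("rpl16", "CDS", [9, 399], "-", [1020]),
    ("rps3", "CDS", [657], "-", []),
    ("rpl22", "CDS", [420], "-", []),
]

SSC_GENES: list[tuple[str, str, list[int], str, list[int]]] = [
    ("ndhF", "CDS", [2241], "-", []),
    ("rpl32", "CDS", [174], "+", []),
    ("trnL-UAG", "tRNA", [80], "+", []),
    ("cssA", "CDS", [966], "+", []),
    ("ndhD", "CDS", [1503], "-", []),
    ("psaC", "CDS", [246], "-", []),
    ("ndhE", "CDS", [306], "-", []),
    ("ndhG", "CDS", [531], "-", []),
    ("ndhI", "CDS", [543], "-", []),
    ("ndhA", "CDS", [552, 540], "-", [1080]),
    ("ndhH", "CDS", [1182], "-", []),
    ("rps15", "CDS", [273], "-", []),
    # ycf1 is appended by the generator: its 5' portion extends into IRA
    ("ycf1", "CDS", [5313], "-", []),
]

IRA_GENES: list[tuple[str, str, list[int], str, list[int]]] = [
    # listed from the SSC/IRA junction toward the IRA/LSC junction
    ("trnN-GUU", "tRNA", [72], "-", []),
    ("trnR-ACG", "tRNA", [74], "-", []),
    ("rrn5", "rRNA", [121], "-", []),
    ("rrn4.5", "rRNA", [103], "-", []),
    ("rrn23", "rRNA", [2810], "-", []),
    ("trnA-UGC", "tRNA", [38, 35], "-", [810]),
    ("trnI-GAU", "tRNA", [37, 35], "-", [940]),
    ("rrn16", "rRNA", [1491], "-", []),
    ("trnV-GAC", "tRNA", [72], "-", []),
    ("rps12:exon23", "CDS", [228, 24], "-", [540]),  # trans-spliced 3' exons
    ("rps7", "CDS", [468], "-", []),
    ("ndhB", "CDS", [777, 756], "-", [680]),
    ("trnL-CAA", "tRNA", [81], "-", []),
    ("ycf2", "CDS", [6837], "+", []),
    ("trnI-CAU", "tRNA", [74], "+", []),
    ("rpl23", "CDS", [282], "+", []),
    ("rpl2", "CDS", [393, 435], "+", [660]),
    ("rps19", "CDS", [279], "+", []),
    ("trnH-GUG", "tRNA", [75], "-", []),
]

#: genes with one copy in each inverted repeat (Table-3 style duplication)
IR_DUPLICATED = frozenset(
    name for name, *_ in IRA_GENES if not name.startswith("rps12:")
) | {"rps12"}

NDH_GENES = ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE",
             "ndhF", "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK"]

_GROUP_PREFIXES = [
    ("trn", "transfer RNA"),
    ("rrn", "ribosomal RNA"),
    ("rps", "small subunit of ribosome"),
    ("rpl", "large subunit of ribosome"),
    ("rpo", "DNA-dependent RNA polymerase"),
    ("psa", "photosystem I"),
    ("psb", "photosystem II"),
    ("pet", "cytochrome b6f"),
    ("atp", "ATP synthase"),
    ("ndh", "NADH dehydrogenase-like (NDH)"),
    ("ycf", "ycf"),
]
_GROUP_EXACT = {
    "rbcL": "RubisCO large subunit",
    "matK": "maturase",
    "cemA": "envelope membrane protein",
    "accD": "acetyl-CoA carboxylase",
    "cssA": "c-type cytochrome synthesis",
    "clpP": "protease",
    "infA": "translation initiation",
}


def group_of(gene_name: str) -> str:
    if gene_name in _GROUP_EXACT:
        return _GROUP_EXACT[gene_name]
    for prefix, grp in _GROUP_PREFIXES:
        if gene_name.startswith(prefix):
            return grp
    return "other"


def all_gene_entries() -> list[tuple[str, str, list[int], str, list[int], str]]:
    """All placement entries: (name, kind, exons, strand, introns, region)."""
    out = []
    for region, table in (("LSC", LSC_GENES), ("SSC", SSC_GENES), ("IRA", IRA_GENES)):
        for name, kind, exons, strand, introns in table:
            out.append((name, kind, exons, strand, introns, region))
    return out


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at]))


def random_spacer(rng: np.random.Generator, n: int, gc: float = 0.32) -> str:
    return _random_bases(rng, n, gc)


def _random_cds(rng: np.random.Generator, length: int, gc: float = 0.38,
                start: str = "ATG") -> str:
    """Random CDS: given start codon, terminal TAA, no internal stop."""
    seq = list(_random_bases(rng, length, gc))
    seq[0:3] = start
    seq[-3:] = "TAA"
    stops = stop_codons()
    for i in range(3, length - 3, 3):
        if "".join(seq[i:i + 3]) in stops:
            seq[i] = "C"  # every stop codon starts with T
    return "".join(seq)


def builtin_catalog() -> GeneCatalog:
    """Build the deterministic synthetic catalog (fixed internal seed)."""
    rng = np.random.default_rng(_CATALOG_SEED)
    models: dict[str, GeneModel] = {}
    groups: dict[str, str] = {}
    # rps12 pieces are merged into one trans-spliced model
    rps12_exons: dict[str, list[int]] = {}
    for name, kind, exons, strand, introns, region in all_gene_entries():
        base = name.split(":")[0]
        if name.startswith("rps12:"):
            rps12_exons[name] = exons
            continue
        total = sum(exons)
        if kind == "CDS":
            start = "ACG" if base == "ndhD" else "ATG"
            seq = _random_cds(rng, total, start=start)
        else:
            seq = _random_bases(rng, total, gc=0.52)
        if base == "ndhB":
            # pin codon 68 to TTA: one genomic A->C (coding T->G) makes TGA
            seq = seq[:201] + "TTA" + seq[204:]
        models[base] = GeneModel(
            gene_name=base,
            kind=kind,
            reference_seq=seq,
            exon_lengths=list(exons),
            allowed_starts=frozenset({"ATG", "ACG"}) if base == "ndhD"
            else frozenset({"ATG"}),
            expected_ir_copy=base in IR_DUPLICATED,
            junction_spanning=(base == "ycf1"),
            notes="spans the SSC/IRA junction" if base == "ycf1" else "",
            intron_hints=list(introns),
        )
        groups[base] = group_of(base)
    # trans-spliced rps12: 5' exon in LSC, 3' exons duplicated in the IRs
    exons = rps12_exons["rps12:exon1"] + rps12_exons["rps12:exon23"]
    models["rps12"] = GeneModel(
        gene_name="rps12",
        kind="CDS",
        reference_seq=_random_cds(rng, sum(exons)),
        exon_lengths=exons,
        expected_ir_copy=True,
        notes="trans-spliced: 5' exon in LSC, 3' exons in the IRs",
        intron_hints=[None, 540],
    )
    groups["rps12"] = group_of("rps12")
    return GeneCatalog(models, groups)
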