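"""Cross-sample aggregation: degradation matrices, feature summaries and the
matrix-versus-tree rendering.

The canonical rendering surface is a plain-text, tab-separated grid with one
row per sample (ordered by a ladderized post-order traversal of the tree
when one is given) and one single-letter-coded cell per gene:
``F`` functional, ``P~`` moderately pseudogenised, ``P!`` severely
pseudogenised, ``L`` lost.  The grid parses back losslessly, which is what
the round-trip tests rely on; an image rendering is optional sugar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from ._catalog_defs import NDH_GENES
from .degradation_classifier import DegradationCall, FUNCTIONAL, LOST
from .plastome_io import GeneCatalog, PlastomeRecord
from .structure_analysis import GcReport, QuadripartitePartition

__all__ = [
    "DegradationMatrix",
    "build_matrix",
    "summarize_counts",
    "render_matrix_vs_tree",
    "parse_matrix_text",
    "diff_matrices",
]

CATEGORY_CODE = {
    FUNCTIONAL: "F",
    "moderate_pseudogene": "P~",
    "severe_pseudogene": "P!",
    LOST: "L",
}
CODE_CATEGORY = {v: k for k, v in CATEGORY_CODE.items()}


@dataclass
class DegradationMatrix:
    """Samples x genes category table."""

    samples: list[str]
    genes: list[str]
    cells: pd.DataFrame  # index samples, columns genes, values category strings

    def __post_init__(self) -> None:
        if self.cells.isna().any().any():
            missing = [(s, g) for s in self.samples for g in self.genes
                       if pd.isna(self.cells.at[s, g])]
            raise ValueError(f"incomplete matrix: missing cells {missing[:5]}")
        bad = set(self.cells.values.ravel()) - set(CATEGORY_CODE)
        if bad:
            raise ValueError(f"unknown categories in matrix: {sorted(bad)}")

    def category(self, sample: str, gene: str) -> str:
        return self.cells.at[sample, gene]

    def __eq__(self, other) -> bool:  # order-insensitive on samples
        if not isinstance(other, DegradationMatrix):
            return NotImplemented
        if set(self.samples) != set(other.samples) or self.genes != other.genes:
            return False
        return self.cells.loc[sorted(self.samples)].equals(
            other.cells.loc[sorted(self.samples)])


def build_matrix(
    calls: dict[str, list[DegradationCall]],
    gene_subset: list[str] | None = None,
    tree: dendropy.Tree | None = None,
) -> DegradationMatrix:
    """Assemble the cross-sample degradation matrix.

    ``calls`` maps sample id to the per-gene call list of
    :func:`classify_plastome`.  The default gene subset is the 11 ndh genes
    in catalog order.  With a tree, samples are ordered by ladderized
    post-order leaf order; otherwise input order is kept.
    """
    genes = list(gene_subset) if gene_subset is not None else list(NDH_GENES)
    samples = list(calls)
    if tree is not None:
        order = _ladder_order(tree)
        missing = [s for s in samples if s not in order]
        if missing:
            raise ValueError(f"samples absent from tree: {missing}")
        samples = [s for s in order if s in calls]
    table = {}
    for s in samples:
        by_gene = {c.gene_name: c.category for c in calls[s]}
        row = {}
        for g in genes:
            if g not in by_gene:
                raise ValueError(f"sample {s!r} has no call for gene {g!r}")
            row[g] = by_gene[g]
        table[s] = row
    cells = pd.DataFrame.from_dict(table, orient="index").loc[samples, genes]
    return DegradationMatrix(samples, genes, cells)


# ---------------------------------------------------------------------------
# Table-2 style summary counts
# ---------------------------------------------------------------------------


def _copy_counts(record: PlastomeRecord | None, kind: str) -> dict[str, int]:
    if record is None:
        return {}
    counts: dict[str, int] = {}
    for f in record.features:
        if f.kind == kind:
            counts[f.gene_name] = counts.get(f.gene_name, 0) + 1
    return counts


def summarize_counts(
    calls: dict[str, list[DegradationCall]],
    catalog: GeneCatalog,
    records: dict[str, PlastomeRecord] | None = None,
    partitions: dict[str, QuadripartitePartition] | None = None,
    gc_reports: dict[str, GcReport] | None = None,
) -> pd.DataFrame:
    """Per-sample plastome feature summary.

    Totals count IR copies (a gene duplicated in the IRs contributes two; a
    triplicated tRNA three); unique counts collapse each expected IR pair to
    one.  Functional/pseudogene/lost partition the catalog:
    ``unique CDS + unique tRNA + unique rRNA + pseudogenes + lost`` equals
    the catalog size.  Region columns are filled when partitions (and GC
    reports) are available, left missing otherwise.
    """
    rows = []
    for sample, sample_calls in calls.items():
        rec = (records or {}).get(sample)
        part = (partitions or {}).get(sample)
        gc = (gc_reports or {}).get(sample)
        by_kind_copy = {k: _copy_counts(rec, k) for k in ("CDS", "tRNA", "rRNA")}
        row: dict = {"sample": sample}
        if rec is not None:
            row["plastome_length_bp"] = len(rec.sequence)
        if part is not None:
            row["ssc_bp"] = part.lengths["SSC"]
            row["ir_bp"] = part.ir_length
            row["lsc_bp"] = part.lengths["LSC"]
        if gc is not None:
            row["gc_percent"] = round(100 * gc.overall, 1)
        n_pseudo = n_lost = n_func = 0
        totals = {"CDS": 0, "tRNA": 0, "rRNA": 0}
        uniques = {"CDS": 0, "tRNA": 0, "rRNA": 0}
        for call in sample_calls:
            model = catalog.models.get(call.gene_name)
            if model is None:
                raise KeyError(f"call for gene {call.gene_name!r} not in catalog")
            if call.category == FUNCTIONAL:
                n_func += 1
                observed = by_kind_copy[model.kind].get(call.gene_name)
                copies = observed if observed else (2 if model.expected_ir_copy else 1)
                totals[model.kind] += copies
                # each expected IR pair collapses to one; a copy beyond the
                # pair (triplicated tRNA) still counts as an extra unique gene
                uniques[model.kind] += copies - (1 if copies >= 2 else 0)
            elif call.category == LOST:
                n_lost += 1
            else:
                n_pseudo += 1
        row.update({
            "total_cds": totals["CDS"], "unique_cds": uniques["CDS"],
            "total_trna": totals["tRNA"], "unique_trna": uniques["tRNA"],
            "total_rrna": totals["rRNA"], "unique_rrna": uniques["rRNA"],
            "total_pseudogenes": n_pseudo,
            "total_lost": n_lost,
            "total_functional": totals["CDS"] + totals["tRNA"] + totals["rRNA"],
            # distinct functional gene names: with pseudogenes and lost genes
            # this partitions the catalog exactly (the unique_* columns follow
            # the Table-2 convention, where an extra copy beyond the IR pair
            # still counts)
            "functional_genes": n_func,
        })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ladder_order(tree: dendropy.Tree) -> list[str]:
    t = tree.clone(depth=1)
    t.ladderize(ascending=True)
    return [lf.taxon.label for lf in t.leaf_node_iter() if lf.taxon is not None]


def render_matrix_vs_tree(
    matrix: DegradationMatrix,
    tree: dendropy.Tree | None = None,
    out: str | Path | None = None,
    image: str | Path | None = None,
) -> str:
    """Render the matrix as the canonical text grid (optionally to file) and,
    if ``image`` is given, as a colored matplotlib figure next to the tree
    order.  Tree leaves must cover all matrix samples."""
    samples = matrix.samples
    if tree is not None:
        order = _ladder_order(tree)
        missing = [s for s in samples if s not in order]
        if missing:
            raise ValueError(f"matrix samples absent from tree: {missing}")
        samples = [s for s in order if s in matrix.samples]
    lines = ["# gene degradation: F functional, P~ moderate, P! severe, L lost",
             "sample\t" + "\t".join(matrix.genes)]
    for s in samples:
        codes = [CATEGORY_CODE[matrix.cells.at[s, g]] for g in matrix.genes]
        lines.append(s + "\t" + "\t".join(codes))
    text = "\n".join(lines) + "\n"
    if out is not None:
        Path(out).write_text(text)
    if image is not None:
        _render_image(matrix, samples, Path(image))
    return text


def _render_image(matrix: DegradationMatrix, samples: list[str],
                  path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    palette = {"F": "#2c7fb8", "P~": "#fec44f", "P!": "#d95f0e", "L": "#636363"}
    codes = ["F", "P~", "P!", "L"]
    data = [[codes.index(CATEGORY_CODE[matrix.cells.at[s, g]])
             for g in matrix.genes] for s in samples]
    fig, ax = plt.subplots(
        figsize=(0.5 * len(matrix.genes) + 2, 0.3 * len(samples) + 1.5))
    ax.imshow(data, cmap=ListedColormap([palette[c] for c in codes]),
              vmin=0, vmax=3, aspect="auto")
    ax.set_xticks(range(len(matrix.genes)), matrix.genes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(samples)), samples, fontsize=7)
    ax.legend(handles=[Patch(color=palette[c], label=lab) for c, lab in
                       zip(codes, ("functional", "moderate ps.", "severe ps.",
                                   "lost"))],
              loc="upper left", bbox_to_anchor=(1.02, 1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def parse_matrix_text(text: str) -> DegradationMatrix:
    """Inverse of :func:`render_matrix_vs_tree`'s text grid."""
    rows = {}
    genes: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if genes is None:
            genes = fields[1:]
            continue
        rows[fields[0]] = {g: CODE_CATEGORY[c] for g, c in zip(genes, fields[1:])}
    if genes is None or not rows:
        raise ValueError("no matrix content found")
    samples = list(rows)
    cells = pd.DataFrame.from_dict(rows, orient="index").loc[samples, genes]
    return DegradationMatrix(samples, genes, cells)


def diff_matrices(a: DegradationMatrix, b: DegradationMatrix
                  ) -> list[tuple[str, str, str, str]]:
    """Sorted list of (sample, gene, a_category, b_category) disagreements."""
    if a.genes != b.genes:
        raise ValueError(f"gene sets differ: {a.genes} vs {b.genes}")
    if set(a.samples) != set(b.samples):
        raise ValueError("sample sets differ")
    out = []
    for s in sorted(a.samples):
        for g in a.genes:
            ca, cb = a.cells.at[s, g], b.cells.at[s, g]
            if ca != cb:
                out.append((s, g, ca, cb))
    return out
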