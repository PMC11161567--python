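"""Alignment hygiene and gene triage for molecular dating.

Two cleaning rules operate on multiple-sequence alignments: stripping
columns that are gaps in at least a given fraction of the taxa, and dropping
whole alignments whose taxon occupancy falls below a fraction of the total
sample. A third utility ranks genes for dating by (i) bipartition
concordance with the species tree, (ii) tree length (informativeness) and
(iii) root-to-tip variance (clock-likeness), in that lexicographic order.

Gap characters are ``-`` and ``?``; ``N`` is an observed-but-ambiguous base
and is *not* a gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeError, prune_to_taxa

__all__ = [
    "Alignment",
    "GeneRankRecord",
    "strip_gappy_columns",
    "filter_by_occupancy",
    "bipartition_concordance",
    "root_to_tip_variance",
    "rank_genes",
]

GAP_CHARS = frozenset("-?")


@dataclass
class Alignment:
    """Equal-length sequence rows over {A,C,G,T,N,-,?} (case-insensitive)."""
    names: list[str]
    rows: list[str]
    name: str | None = None  # gene/locus id

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def occupancy(self) -> int:
        """Number of rows holding at least one non-gap character."""
        return sum(1 for r in self.rows if any(c not in GAP_CHARS for c in r))

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "Alignment":
        from Bio import SeqIO
        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq))
        return cls(names, rows, name=name)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, r in zip(self.names, self.rows):
                fh.write(f">{n}\n{r}\n")


def strip_gappy_columns(aln: Alignment, max_gap_fraction: float = 0.7) -> Alignment:
    """Remove columns whose gap fraction is ``>= max_gap_fraction``.

    Every retained column has gap fraction strictly below the threshold; row
    order and names are preserved (rows may become all-gap and are kept).
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    if aln.n_rows == 0 or aln.n_columns == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in aln.rows])
    gap_frac = np.isin(mat, list(GAP_CHARS)).mean(axis=0)
    keep = gap_frac < max_gap_fraction
    rows = ["".join(row) for row in mat[:, keep]]
    return Alignment(list(aln.names), rows, name=aln.name)


def filter_by_occupancy(
    alignments: Sequence[Alignment],
    total_samples: int,
    min_fraction: float = 0.4,
) -> tuple[list[Alignment], pd.DataFrame]:
    """Keep alignments with at least ``ceil(min_fraction * total_samples)``
    occupied rows; return the kept list and a per-alignment report.

    The report records the computed integer threshold so that any
    discrepancy with an externally quoted row count is visible.
    """
    if total_samples < 1:
        raise ValueError("total_samples must be >= 1")
    threshold = math.ceil(min_fraction * total_samples)
    kept, rows = [], []
    for i, aln in enumerate(alignments):
        occ = aln.occupancy()
        ok = occ >= threshold
        if ok:
            kept.append(aln)
        rows.append((aln.name or f"aln{i}", occ, threshold, ok))
    report = pd.DataFrame(rows, columns=["gene", "occupancy", "threshold", "kept"])
    return kept, report


def read_gene_trees(path, gene_ids: Sequence[str] | None = None) -> dict[str, Phylogeny]:
    """Read a multi-Newick file (one tree per line); gene ids come from the
    sidecar list, or default to ``gene1..geneN`` in file order."""
    from .trees import read_tree
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_tree(line))
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(len(trees))]
    if len(gene_ids) != len(trees):
        raise ValueError(f"{len(gene_ids)} gene ids for {len(trees)} trees")
    return dict(zip(gene_ids, trees))


# ---------------------------------------------------------------------------
# Gene ranking for dating
# ---------------------------------------------------------------------------

def _nontrivial_splits(tree: Phylogeny) -> set[frozenset[str]]:
    """Internal bipartitions as canonical tip sets (side not containing a
    fixed reference tip), excluding trivial splits."""
    all_tips = frozenset(tree.tip_labels)
    ref = min(all_tips)
    splits: set[frozenset[str]] = set()
    for n in tree.internal_nodes():
        if n is tree.root:
            continue
        side = tree.leaf_set(n)
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        canon = side if ref not in side else all_tips - side
        splits.add(canon)
    return splits


def bipartition_concordance(gene_tree: Phylogeny, species_tree: Phylogeny) -> float:
    """Fraction of the gene tree's internal bipartitions present in the
    species tree restricted to the shared tips; 0.0 for a star gene tree."""
    shared = set(gene_tree.tip_labels) & set(species_tree.tip_labels)
    missing = set(gene_tree.tip_labels) - shared
    if missing:
        raise TreeError(f"gene-tree tips absent from species tree: {sorted(missing)[:5]}")
    if len(shared) < 4:
        raise TreeError("fewer than 4 shared tips: no informative bipartitions")
    sp = prune_to_taxa(species_tree, shared)
    gene_splits = _nontrivial_splits(gene_tree)
    if not gene_splits:
        return 0.0
    sp_splits = _nontrivial_splits(sp)
    return sum(1 for s in gene_splits if s in sp_splits) / len(gene_splits)


def root_to_tip_variance(tree: Phylogeny) -> float:
    """Population variance (divide by n) of root-to-tip path lengths — a
    proxy for clock-likeness; exactly 0 on an ultrametric tree."""
    depth = tree.depths()
    d = np.array([depth[t] for t in tree.tip_labels])
    return float(np.var(d))  # population convention


def tree_length(tree: Phylogeny) -> float:
    """Sum of all branch lengths (phylogenetic informativeness proxy)."""
    total = 0.0
    for n in tree.preorder():
        if n is tree.root:
            continue
        if n.length is None:
            raise TreeError(f"missing branch length above node {n.id}")
        total += n.length
    return total


@dataclass(frozen=True)
class GeneRankRecord:
    gene: str
    concordance: float
    tree_length: float
    root_tip_variance: float

    def __post_init__(self) -> None:
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must be in [0, 1]")
        if self.tree_length < 0 or self.root_tip_variance < 0:
            raise ValueError("tree length and variance must be >= 0")

    @classmethod
    def from_trees(cls, gene: str, gene_tree: Phylogeny,
                   species_tree: Phylogeny) -> "GeneRankRecord":
        return cls(gene,
                   bipartition_concordance(gene_tree, species_tree),
                   tree_length(gene_tree),
                   root_to_tip_variance(gene_tree))


def rank_genes(
    records: Sequence[GeneRankRecord],
    top_n: int = 30,
    must_include: Iterable[str] = (),
) -> list[str]:
    """Stable lexicographic ranking: concordance desc, then tree length desc,
    then root-to-tip variance asc. The first ``top_n`` genes are returned;
    genes on ``must_include`` are appended if not already selected (e.g. to
    retain the only locus covering an otherwise-missing taxon)."""
    if not records:
        raise ValueError("no gene records supplied")
    ranked = sorted(
        records,
        key=lambda r: (-r.concordance, -r.tree_length, r.root_tip_variance),
    )
    selected = [r.gene for r in ranked[:top_n]]
    for gene in must_include:
        if gene not in selected:
            selected.append(gene)
    return selected


def ranking_report(records: Sequence[GeneRankRecord],
                   top_n: int = 30,
                   must_include: Iterable[str] = ()) -> pd.DataFrame:
    selected = rank_genes(records, top_n, must_include)
    order = {g: i + 1 for i, g in enumerate(selected)}
    rows = [(r.gene, r.concordance, r.tree_length, r.root_tip_variance,
             order.get(r.gene)) for r in records]
    return (pd.DataFrame(rows, columns=["gene", "concordance", "tree_length",
                                        "root_tip_variance", "rank"])
            .sort_values(["rank", "gene"], na_position="last")
            .reset_index(drop=True))
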