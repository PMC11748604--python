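"""Evaluation statistics: parsimony-informative sites, branch-support
summaries, Robinson–Foulds distances, and the mean normalised RF congruence
statistic used to compare a reference tree against a set of other trees."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import dendropy
from dendropy.calculate import treecompare

from coretree.align import LocusAlignment, Supermatrix
from coretree.trees import PhylogeneticTree


@dataclass(frozen=True)
class SupportSummary:
    mean_support: float  # in [0, 1]
    fraction_max: float  # percentage of internal edges with support == 1.0
    n_internal: int


@dataclass(frozen=True)
class RFResult:
    rf: int
    max_rf: int
    normalized: float


def count_informative_sites(alignment: Supermatrix | LocusAlignment) -> int:
    """Number of parsimony-informative columns: at least two distinct
    non-gap, non-X residues each occurring in at least two rows."""
    rows = [alignment.rows[k] for k in sorted(alignment.rows)]
    n_sites = 0
    for column in zip(*rows):
        counts = Counter(c for c in column if c not in "-X")
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n_sites += 1
    return n_sites


def summarize_support(tree: PhylogeneticTree) -> SupportSummary:
    """Mean support and percentage of internal edges at maximum support.

    Supports that look like percentages (> 1) are rescaled to [0, 1]."""
    supports = tree.internal_supports()
    if not supports:
        raise ValueError(
            "tree carries no support values; use a support-emitting backend "
            "(e.g. fasttree or iqtree)"
        )
    mean = sum(supports) / len(supports)
    fraction_max = 100.0 * sum(1 for s in supports if s == 1.0) / len(supports)
    return SupportSummary(
        mean_support=mean, fraction_max=fraction_max, n_internal=len(supports)
    )


def _restricted_pair(
    a: PhylogeneticTree, b: PhylogeneticTree
) -> tuple[dendropy.Tree, dendropy.Tree, int]:
    namespace = dendropy.TaxonNamespace()
    tree_a = dendropy.Tree.get(
        data=a.newick, schema="newick", taxon_namespace=namespace
    )
    tree_b = dendropy.Tree.get(
        data=b.newick, schema="newick", taxon_namespace=namespace
    )
    tips_a = {leaf.taxon.label for leaf in tree_a.leaf_node_iter()}
    tips_b = {leaf.taxon.label for leaf in tree_b.leaf_node_iter()}
    shared = tips_a & tips_b
    if len(shared) < 4:
        raise ValueError(
            f"Robinson-Foulds undefined: only {len(shared)} shared tips"
        )
    if shared != tips_a or shared != tips_b:
        keep = [t for t in namespace if t.label in shared]
        tree_a.retain_taxa(keep)
        tree_b.retain_taxa(keep)
    return tree_a, tree_b, len(shared)


def robinson_foulds(a: PhylogeneticTree, b: PhylogeneticTree) -> RFResult:
    """Symmetric-difference (RF) distance on the shared-tip restriction of
    two trees, with the usual 2(n-3) normalisation."""
    tree_a, tree_b, n = _restricted_pair(a, b)
    tree_a.encode_bipartitions()
    tree_b.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(tree_a, tree_b))
    max_rf = 2 * (n - 3)
    normalized = rf / max_rf if max_rf else 0.0
    return RFResult(rf=rf, max_rf=max_rf, normalized=normalized)


def nsumrf(trees: list[PhylogeneticTree], reference_index: int = 0) -> float:
    """Normalised sum of RF distances from one reference tree to all other
    trees: the mean of the pairwise normalized RF values."""
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    reference = trees[reference_index]
    others = [t for i, t in enumerate(trees) if i != reference_index]
    total = sum(robinson_foulds(reference, t).normalized for t in others)
    return total / len(others)


def congruence_report(
    combined: PhylogeneticTree,
    locus_trees: dict[str, PhylogeneticTree],
    path: str | Path,
) -> Path:
    """TSV of per-locus-tree congruence with the combined tree
    (normalized RF per locus)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write("locus\trf\tmax_rf\tnormalized_rf\n")
        for locus in sorted(locus_trees):
            try:
                result = robinson_foulds(combined, locus_trees[locus])
            except ValueError:
                handle.write(f"{locus}\tNA\tNA\tNA\n")
                continue
            handle.write(
                f"{locus}\t{result.rf}\t{result.max_rf}\t{result.normalized:.6f}\n"
            )
    return path
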