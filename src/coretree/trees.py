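"""Tree inference from the combined alignment (and per-locus trees).

External maximum-likelihood backends (FastTree-style stdin->stdout and
IQ-TREE-style ``-s``) are invoked through adapters on the written
alignment.  The internal fallback is neighbour joining on Poisson-corrected
pairwise mismatch distances; it is fully deterministic (same alignment ->
identical newick bytes) and emits no support values rather than fabricating
them.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from coretree._errors import ConfigurationError, ExternalToolError
from coretree.align import LocusAlignment, Supermatrix
from coretree.screen import LocusSelection

logger = logging.getLogger(__name__)

# distances are clamped where the mismatch fraction saturates
MAX_MISMATCH = 0.95
MAX_DISTANCE = -math.log(1.0 - MAX_MISMATCH)


@dataclass
class PhylogeneticTree:
    """Unrooted tree over genome-id tips, stored as a newick string."""

    newick: str
    source: str = ""

    def _dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def tips(self) -> set[str]:
        return {leaf.taxon.label for leaf in self._dendropy().leaf_node_iter()}

    def internal_supports(self) -> list[float]:
        """Support values attached to internal edges, rescaled to [0, 1]
        when they look like percentages (any value > 1)."""
        tree = self._dendropy()
        values = []
        for node in tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            label = node.label
            if label is None:
                continue
            try:
                values.append(float(label))
            except ValueError:
                continue
        if any(v > 1.0 for v in values):
            values = [v / 100.0 for v in values]
        return values

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            handle.write(self.newick.rstrip("\n") + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path, source: str = "") -> "PhylogeneticTree":
        with open(path) as handle:
            return cls(newick=handle.read().strip(), source=source or str(path))


# --- internal neighbour joining -------------------------------------------


def pairwise_distances(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected mismatch distances over mutually ungapped columns.

    ``d = -ln(1 - p)`` with the mismatch fraction ``p`` clamped at
    ``MAX_MISMATCH`` so saturated pairs get a finite ceiling.
    """
    labels = sorted(rows)
    for label in labels:
        if set(rows[label]) <= {"-"}:
            raise ValueError(f"all-gap alignment row for genome {label!r}")
    arrays = {
        label: np.frombuffer(rows[label].encode(), dtype=np.uint8)
        for label in labels
    }
    gap = ord("-")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[labels[i]], arrays[labels[j]]
            valid = (a != gap) & (b != gap)
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no overlapping columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((a[valid] != b[valid]).sum()) / n_valid
            d = MAX_DISTANCE if p >= MAX_MISMATCH else -math.log(1.0 - p)
            dist[i, j] = dist[j, i] = d
    return labels, dist


class _Node:
    __slots__ = ("name", "children", "min_tip")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)
        self.min_tip = name if name else min(c.min_tip for c, _ in self.children)

    def newick(self) -> str:
        if not self.children:
            return self.name
        parts = sorted(self.children, key=lambda cb: cb[0].min_tip)
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in parts)
        return f"({inner})"


def neighbor_joining(labels: list[str], dist: np.ndarray) -> str:
    """Deterministic neighbour joining; returns a newick string with an
    unrooted (trifurcating) basal node.  Ties in the Q criterion are broken
    toward the lexicographically smallest pair of subtree labels; negative
    branch-length estimates are clamped to zero."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [_Node(name=label) for label in labels]
    d = dist.astype(float).copy()
    if n == 2:
        half = max(d[0, 1] / 2.0, 0.0)
        return f"({nodes[0].name}:{half:.6f},{nodes[1].name}:{half:.6f});"

    active = list(range(n))
    next_rows: dict[int, _Node] = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((next_rows[i].min_tip, next_rows[j].min_tip)))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = _Node(children=[(next_rows[i], vi), (next_rows[j], vj)])
        # reuse row i for the merged node
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = max(dk, 0.0)
        active.remove(j)
        next_rows[i] = parent
        del next_rows[j]

    a, b, c = active
    va = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    vb = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    vc = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    children = sorted(
        [(next_rows[a], va), (next_rows[b], vb), (next_rows[c], vc)],
        key=lambda cb: cb[0].min_tip,
    )
    inner = ",".join(f"{node.newick()}:{bl:.6f}" for node, bl in children)
    return f"({inner});"


# --- backends --------------------------------------------------------------


def _build_internal_nj(rows: dict[str, str], source: str) -> PhylogeneticTree:
    labels, dist = pairwise_distances(rows)
    return PhylogeneticTree(newick=neighbor_joining(labels, dist), source=source)


def _write_fasta(rows: dict[str, str], path: Path) -> None:
    with open(path, "w") as handle:
        for label in sorted(rows):
            handle.write(f">{label}\n{rows[label]}\n")


def _build_fasttree(
    rows: dict[str, str], source: str, executable: str = "fasttree"
) -> PhylogeneticTree:
    if shutil.which(executable) is None:
        raise ConfigurationError(f"tree tool {executable!r} not found on PATH")
    fasta = "".join(f">{label}\n{rows[label]}\n" for label in sorted(rows))
    cmd = [executable]  # protein model by default, stdin -> stdout
    logger.info("running: %s (alignment on stdin)", " ".join(cmd))
    proc = subprocess.run(cmd, input=fasta, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError("fasttree failed", proc.stderr)
    return PhylogeneticTree(newick=proc.stdout.strip(), source=source)


def _build_iqtree(
    rows: dict[str, str],
    source: str,
    partition_file: str | Path | None = None,
    executable: str | None = None,
) -> PhylogeneticTree:
    executable = executable or next(
        (exe for exe in ("iqtree2", "iqtree") if shutil.which(exe)), None
    )
    if executable is None:
        raise ConfigurationError("no iqtree/iqtree2 executable found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "alignment.fasta"
        _write_fasta(rows, fasta)
        cmd = [executable, "-s", str(fasta), "-nt", "1", "--quiet"]
        if partition_file is not None:
            cmd += ["-p", str(partition_file)]
        logger.info("running: %s", " ".join(cmd))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError("iqtree failed", proc.stderr)
        treefile = (
            Path(str(partition_file) + ".treefile")
            if partition_file is not None
            else fasta.with_suffix(".fasta.treefile")
        )
        if not treefile.exists():
            candidates = list(Path(tmp).glob("*.treefile"))
            if not candidates:
                raise ExternalToolError("iqtree produced no treefile", proc.stderr)
            treefile = candidates[0]
        newick = treefile.read_text().strip()
    return PhylogeneticTree(newick=newick, source=source)


METHODS = ("internal-nj", "fasttree", "iqtree")


def build_tree(
    alignment: Supermatrix | LocusAlignment,
    method: str = "internal-nj",
    source: str = "",
    partition_file: str | Path | None = None,
) -> PhylogeneticTree:
    """Infer a tree from a supermatrix or a single locus alignment."""
    rows = alignment.rows
    if len(rows) < 3:
        raise ValueError("need at least 3 taxa for an unrooted topology")
    for label, row in rows.items():
        if set(row) <= {"-"}:
            raise ValueError(f"all-gap alignment row for genome {label!r}")
    if not source:
        source = getattr(alignment, "locus_id", "") or "combined"
    if method == "internal-nj":
        return _build_internal_nj(rows, source)
    if method == "fasttree":
        return _build_fasttree(rows, source)
    if method == "iqtree":
        return _build_iqtree(rows, source, partition_file=partition_file)
    raise ConfigurationError(f"unknown tree method {method!r}; choose from {METHODS}")


def build_all_trees(
    selection: LocusSelection,
    alignments: dict[str, LocusAlignment],
    method: str = "internal-nj",
    out_dir: str | Path | None = None,
) -> dict[str, PhylogeneticTree]:
    """One tree per selected locus; loci with fewer than 3 taxa are skipped
    with a warning and one locus failing does not abort the rest."""
    result: dict[str, PhylogeneticTree] = {}
    for locus in selection.loci:
        alignment = alignments[locus]
        if len(alignment.rows) < 3:
            logger.warning("locus %s has < 3 taxa; skipped", locus)
            continue
        try:
            tree = build_tree(alignment, method=method, source=locus)
        except ExternalToolError as exc:
            logger.error("tree inference failed for locus %s: %s", locus, exc)
            continue
        result[locus] = tree
        if out_dir is not None:
            tree.write(Path(out_dir) / f"{locus.replace('|', '_')}.nwk")
    return result
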