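"""Independent oracles used by the test suite.

These deliberately re-derive results through different code paths than the
package: a hand-written (numba-accelerated) Smith-Waterman dynamic program
with Karlin-Altschul statistics, a tiny pure-Python SW used to cross-check
the numba one, a from-scratch newick parser with brute-force bipartition
enumeration for Robinson-Foulds distances, and a four-point-condition
topology search for neighbour joining.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

# scoring convention under test: BLOSUM62, gap of length k costs 11 + k
GAP_OPEN_TOTAL = 12.0  # first gapped position
GAP_EXTEND = 1.0
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM = substitution_matrices.load("BLOSUM62")
ALPHABET = str(_BLOSUM.alphabet)
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
MATRIX = np.array(_BLOSUM, dtype=np.float64)


def encode(seq: str) -> np.ndarray:
    return np.array([_INDEX[c] for c in seq], dtype=np.int64)


@njit(cache=True)
def _sw_score_numba(a, b, matrix, gap_open_total, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    h_prev = np.zeros(m + 1)
    f_prev = np.full(m + 1, -1e18)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1)
        f_cur = np.full(m + 1, -1e18)
        e = -1e18
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - gap_open_total, e - gap_extend)
            f_cur[j] = max(h_prev[j] - gap_open_total, f_prev[j] - gap_extend)
            diag = h_prev[j - 1] + matrix[a[i - 1], b[j - 1]]
            h = max(0.0, diag, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        f_prev = f_cur
    return best


def sw_score(a: str, b: str) -> float:
    """Optimal Smith-Waterman local alignment score."""
    return _sw_score_numba(
        encode(a), encode(b), MATRIX, GAP_OPEN_TOTAL, GAP_EXTEND
    )


def sw_score_pure_python(a: str, b: str) -> float:
    """Slow reference for the numba implementation (tiny inputs only)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[NEG] * (m + 1) for _ in range(n + 1)]
    f = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - GAP_OPEN_TOTAL, e[i][j - 1] - GAP_EXTEND)
            f[i][j] = max(h[i - 1][j] - GAP_OPEN_TOTAL, f[i - 1][j] - GAP_EXTEND)
            diag = h[i - 1][j - 1] + MATRIX[_INDEX[a[i - 1]], _INDEX[b[j - 1]]]
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def singletons_by_exhaustive_search(
    proteins: dict[str, str], max_evalue: float
) -> set[str]:
    """All-pairs SW within one genome; a locus is a singleton when no other
    locus hits it at the threshold (the self-hit is always counted)."""
    loci = sorted(proteins)
    counts = {locus: 1 for locus in loci}
    for a, b in combinations(loci, 2):
        score = sw_score(proteins[a], proteins[b])
        if evalue(score, len(proteins[a]), len(proteins[b])) <= max_evalue:
            counts[a] += 1
            counts[b] += 1
    return {locus for locus, n in counts.items() if n == 1}


def hit_set_by_exhaustive_search(
    query: str, proteins: dict[str, str], max_evalue: float,
    self_id: str | None = None,
) -> set[str]:
    hits = set()
    for locus, subject in proteins.items():
        score = sw_score(query, subject)
        if evalue(score, len(query), len(subject)) <= max_evalue:
            hits.add(locus)
    if self_id is not None:
        hits.add(self_id)
    return hits


# --- newick / Robinson-Foulds ---------------------------------------------


def parse_newick(text: str):
    """Minimal recursive-descent newick parser -> nested tuples of labels
    (branch lengths and internal labels discarded)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_clade():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse_clade()]
            while text[pos] == ",":
                pos += 1
                children.append(parse_clade())
            assert text[pos] == ")", f"expected ')' at {pos}"
            pos += 1
            _read_label()  # internal label / support
            _read_branch_length()
            return tuple(children)
        label = _read_label()
        _read_branch_length()
        return label

    def _read_label():
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        return text[start:pos]

    def _read_branch_length():
        nonlocal pos
        if pos < len(text) and text[pos] == ":":
            pos += 1
            _read_label()

    tree = parse_clade()
    assert pos == len(text), f"trailing characters at {pos}: {text[pos:]!r}"
    return tree


def _tips(clade) -> frozenset:
    if isinstance(clade, str):
        return frozenset([clade])
    return frozenset().union(*(_tips(c) for c in clade))


def bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted tree, each encoded as a
    frozenset of both sides (rooting-invariant)."""
    tree = parse_newick(newick)
    all_tips = _tips(tree)
    splits: set[frozenset] = set()

    def walk(clade):
        if isinstance(clade, str):
            return
        side = _tips(clade)
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(frozenset([side, all_tips - side]))
        for child in clade:
            walk(child)

    for child in tree:
        walk(child)
    return splits


def rf_by_enumeration(newick_a: str, newick_b: str) -> tuple[int, int]:
    """(rf, max_rf) via explicit bipartition set symmetric difference."""
    tips_a, tips_b = _tips(parse_newick(newick_a)), _tips(parse_newick(newick_b))
    assert tips_a == tips_b, "oracle requires identical tip sets"
    ba, bb = bipartitions(newick_a), bipartitions(newick_b)
    return len(ba ^ bb), 2 * (len(tips_a) - 3)


# --- topology enumeration / four-point condition ---------------------------


def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies over the labels, as bipartition sets
    paired with a representative newick string."""
    assert 4 <= len(labels) <= 7, "enumeration only sane for small n"

    def grow(newicks, label):
        out = []
        for nwk in newicks:
            tree = parse_newick(nwk + ";")
            edges = []

            def collect(clade, path):
                edges.append(path)
                if isinstance(clade, str):
                    return
                for i, child in enumerate(clade):
                    collect(child, path + (i,))

            for i, child in enumerate(tree):
                collect(child, (i,))

            def attach(clade, path):
                if not path:
                    return (clade, label)
                i = path[0]
                return tuple(
                    attach(c, path[1:]) if j == i else c
                    for j, c in enumerate(clade)
                )

            def to_newick(clade):
                if isinstance(clade, str):
                    return clade
                return "(" + ",".join(to_newick(c) for c in clade) + ")"

            for path in edges:
                out.append(to_newick(attach(tree, path)))
        return out

    trees = [f"({labels[0]},{labels[1]},{labels[2]})"]
    for label in labels[3:]:
        trees = grow(trees, label)
    return [(t + ";", bipartitions(t + ";")) for t in trees]


def quartet_split_from_bipartitions(splits: set[frozenset], quartet):
    """Which pairing of the quartet the topology induces, or None."""
    a, b, c, d = quartet
    for split in splits:
        side1, side2 = tuple(split)
        for x, y in ((a, b), (a, c), (a, d)):
            rest = [t for t in quartet if t not in (x, y)]
            if ({x, y} <= side1 and set(rest) <= side2) or (
                {x, y} <= side2 and set(rest) <= side1
            ):
                return frozenset([frozenset([x, y]), frozenset(rest)])
    return None


def topology_by_four_point_condition(labels: list[str], dist) -> set[frozenset]:
    """The unique enumerated topology whose every induced quartet matches
    the four-point condition of the (additive) distance matrix."""
    index = {label: i for i, label in enumerate(labels)}

    def fpc_split(quartet):
        a, b, c, d = quartet
        pairings = [
            (frozenset([frozenset([a, b]), frozenset([c, d])]),
             dist[index[a]][index[b]] + dist[index[c]][index[d]]),
            (frozenset([frozenset([a, c]), frozenset([b, d])]),
             dist[index[a]][index[c]] + dist[index[b]][index[d]]),
            (frozenset([frozenset([a, d]), frozenset([b, c])]),
             dist[index[a]][index[d]] + dist[index[b]][index[c]]),
        ]
        pairings.sort(key=lambda p: p[1])
        if pairings[0][1] == pairings[1][1]:
            return None  # degenerate quartet
        return pairings[0][0]

    matches = []
    for newick, splits in enumerate_unrooted_topologies(labels):
        ok = True
        for quartet in combinations(labels, 4):
            wanted = fpc_split(quartet)
            if wanted is None:
                continue
            if quartet_split_from_bipartitions(splits, quartet) != wanted:
                ok = False
                break
        if ok:
            matches.append(splits)
    assert len(matches) == 1, f"expected unique topology, got {len(matches)}"
    return matches[0]
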