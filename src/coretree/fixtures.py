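"""Synthetic genome sets with planted orthologue structure.

Every generated gene is labelled CORE (single-copy in all genomes, evolved
from one root sequence along a known tree), DUP (a family with copy number
>= 2 in at least one genome), or ACCESSORY (present in a strict subset of
genomes), so screening, alignment, tree inference and metrics can all be
tested offline against known truth.  Output is byte-deterministic for a
given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from coretree.align import LocusAlignment
from coretree.extract import STANDARD_AA, CodingSequence, GenomeRecord
from coretree.trees import PhylogeneticTree

_AA = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
N_AA = len(STANDARD_AA)

# one unambiguous codon per residue, used when emitting GenBank nucleotide
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}


@dataclass
class SyntheticGenomeSpec:
    n_genomes: int = 4
    n_core: int = 5
    n_dup_families: int = 2
    n_accessory: int = 3
    protein_length: int = 80
    tree: PhylogeneticTree | None = None  # generated from rng_seed when None
    subst_rate_scale: float = 1.0
    indel_rate: float = 0.0
    dup_divergence: float = 0.05  # substitutions between family copies
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if min(self.n_core, self.n_dup_families, self.n_accessory) < 0:
            raise ValueError("counts must be non-negative")
        if self.protein_length < 10:
            raise ValueError("protein_length must be >= 10")
        if self.n_accessory and self.n_genomes < 2:
            raise ValueError("accessory genes need a strict, non-empty genome subset")


@dataclass(frozen=True)
class TruthRow:
    genome_id: str
    locus_id: str
    category: str  # CORE | DUP | ACCESSORY
    family: str


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def core_loci(self, genome_id: str) -> set[str]:
        """Qualified ids of CORE genes in one genome."""
        return {
            f"{r.genome_id}|{r.locus_id}"
            for r in self.rows
            if r.category == "CORE" and r.genome_id == genome_id
        }

    def category(self, genome_id: str, locus_id: str) -> str:
        for r in self.rows:
            if r.genome_id == genome_id and r.locus_id == locus_id:
                return r.category
        raise KeyError((genome_id, locus_id))

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            handle.write("genome\tlocus\tcategory\tfamily\n")
            for r in self.rows:
                handle.write(f"{r.genome_id}\t{r.locus_id}\t{r.category}\t{r.family}\n")
        return path


# --- sequence evolution ----------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, N_AA, size=length)


def _evolve(
    seq: np.ndarray,
    branch_length: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> np.ndarray:
    """Per site, substitute with probability ``1 - exp(-branch_length)`` to
    a uniformly chosen *different* residue; optional per-site indels."""
    out = seq.copy()
    if branch_length > 0:
        p = 1.0 - np.exp(-branch_length)
        mask = rng.random(out.size) < p
        shifts = rng.integers(1, N_AA, size=out.size)
        out[mask] = (out[mask] + shifts[mask]) % N_AA
    if indel_rate > 0:
        keep = rng.random(out.size) >= indel_rate / 2.0
        out = out[keep]
        insert_mask = rng.random(out.size + 1) < indel_rate / 2.0
        if insert_mask.any():
            pieces = []
            for i in range(out.size + 1):
                if insert_mask[i]:
                    pieces.append(rng.integers(0, N_AA, size=1))
                if i < out.size:
                    pieces.append(out[i:i + 1])
            out = np.concatenate(pieces)
        if out.size < 1:  # never let a gene vanish entirely
            out = _random_protein(rng, 10)
    return out


def _decode(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode()


def _evolve_along_tree(
    tree: dendropy.Tree,
    root_seq: np.ndarray,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
    indel_rate: float = 0.0,
) -> dict[str, np.ndarray]:
    """Evolve a root sequence down a tree; returns tip-label -> sequence.

    Children are visited in sorted tip-label order so the RNG stream, and
    hence the output, is independent of newick rotation."""
    sequences: dict[str, np.ndarray] = {}

    def min_tip(node):
        if node.is_leaf():
            return node.taxon.label
        return min(min_tip(c) for c in node.child_nodes())

    def visit(node, seq):
        for child in sorted(node.child_nodes(), key=min_tip):
            bl = (child.edge.length or 0.0) * rate_scale
            child_seq = _evolve(seq, bl, rng, indel_rate)
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                visit(child, child_seq)

    visit(tree.seed_node, root_seq)
    if tree.seed_node.is_leaf():
        sequences[tree.seed_node.taxon.label] = root_seq
    return sequences


def expected_tip_mismatch(tree: PhylogeneticTree, tip_a: str, tip_b: str,
                          rate_scale: float = 1.0) -> float:
    """Exact expected per-site mismatch fraction between two tips under the
    substitution process above: the per-branch identity eigenvalue is
    ``(N e^{-b} - 1) / (N - 1)`` and multiplies along the connecting path."""
    dtree = dendropy.Tree.get(data=tree.newick, schema="newick")
    node_a = dtree.find_node_with_taxon_label(tip_a)
    node_b = dtree.find_node_with_taxon_label(tip_b)

    def to_root(node):
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    path_a, path_b = to_root(node_a), to_root(node_b)
    shared = {id(n) for n in path_a} & {id(n) for n in path_b}
    product = 1.0
    for node in path_a + path_b:
        if id(node) in shared:
            continue
        b = (node.edge.length or 0.0) * rate_scale
        product *= (N_AA * np.exp(-b) - 1.0) / (N_AA - 1.0)
    identity = 1.0 / N_AA + (1.0 - 1.0 / N_AA) * product
    return 1.0 - identity


# --- tree generation -------------------------------------------------------


def random_tree(
    n_tips: int,
    rng_seed: int,
    internal_range: tuple[float, float] = (0.05, 0.15),
    pendant_range: tuple[float, float] = (0.02, 0.10),
    labels: list[str] | None = None,
) -> PhylogeneticTree:
    """Random binary topology (sequential random joins) with branch lengths
    drawn uniformly from the given ranges."""
    rng = np.random.default_rng(rng_seed)
    if labels is None:
        labels = [f"g{i:02d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    nodes = [(label, True) for label in labels]  # (newick fragment, is_leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (frag_j, leaf_j) = nodes.pop(j)
        (frag_i, leaf_i) = nodes.pop(i)
        bl_i = rng.uniform(*(pendant_range if leaf_i else internal_range))
        bl_j = rng.uniform(*(pendant_range if leaf_j else internal_range))
        nodes.append((f"({frag_i}:{bl_i:.6f},{frag_j}:{bl_j:.6f})", False))
    return PhylogeneticTree(newick=nodes[0][0] + ";", source="random_tree")


def caterpillar_tree(
    n_tips: int,
    internal_length: float = 0.3,
    pendant_length: float = 0.1,
    labels: list[str] | None = None,
) -> PhylogeneticTree:
    """Fully pectinate (ladder) topology with uniform branch lengths."""
    if labels is None:
        labels = [f"g{i:02d}" for i in range(n_tips)]
    newick = f"({labels[0]}:{pendant_length},{labels[1]}:{pendant_length})"
    for label in labels[2:]:
        newick = f"({newick}:{internal_length},{label}:{pendant_length})"
    return PhylogeneticTree(newick=newick + ";", source="caterpillar")


# --- fixture generation ----------------------------------------------------


def simulate_alignment(
    tree: PhylogeneticTree, length: int, rng_seed: int
) -> LocusAlignment:
    """Gap-free alignment simulated along ``tree``: uniform root sequence,
    per-branch per-site substitution with probability ``1 - exp(-b)``."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(rng_seed)
    dtree = dendropy.Tree.get(data=tree.newick, schema="newick")
    root = _random_protein(rng, length)
    tips = _evolve_along_tree(dtree, root, rng)
    return LocusAlignment(
        locus_id="simulated", rows={k: _decode(v) for k, v in tips.items()}
    )


def generate_genomes(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, GenomeRecord], TruthTable]:
    """Generate one :class:`GenomeRecord` per genome plus the truth table.

    Accessory sequences come from an independent RNG stream so they share no
    detectable similarity with core or duplicated families.
    """
    rng = np.random.default_rng(spec.rng_seed)
    accessory_rng = np.random.default_rng((spec.rng_seed + 1) * 2_000_003)
    tree = spec.tree or random_tree(spec.n_genomes, rng_seed=spec.rng_seed + 17)
    dtree = dendropy.Tree.get(data=tree.newick, schema="newick")
    genome_ids = sorted(
        leaf.taxon.label for leaf in dtree.leaf_node_iter()
    )
    if len(genome_ids) != spec.n_genomes:
        raise ValueError(
            f"tree has {len(genome_ids)} tips but spec.n_genomes={spec.n_genomes}"
        )

    genes: dict[str, list[CodingSequence]] = {g: [] for g in genome_ids}
    truth = TruthTable()

    def add(genome_id: str, locus_id: str, seq: np.ndarray, category: str,
            family: str):
        genes[genome_id].append(
            CodingSequence(genome_id, locus_id, _decode(seq))
        )
        truth.rows.append(TruthRow(genome_id, locus_id, category, family))

    for f in range(spec.n_core):
        family = f"CORE{f:04d}"
        root = _random_protein(rng, spec.protein_length)
        tips = _evolve_along_tree(
            dtree, root, rng, spec.subst_rate_scale, spec.indel_rate
        )
        for genome_id in genome_ids:
            add(genome_id, family, tips[genome_id], "CORE", family)

    for f in range(spec.n_dup_families):
        family = f"DUPF{f:04d}"
        root = _random_protein(rng, spec.protein_length)
        tips = _evolve_along_tree(
            dtree, root, rng, spec.subst_rate_scale, spec.indel_rate
        )
        # the duplicated copy lands in a designated (non-first) genome
        designated = genome_ids[1 + f % (spec.n_genomes - 1)]
        for genome_id in genome_ids:
            add(genome_id, f"{family}A", tips[genome_id], "DUP", family)
            if genome_id == designated:
                extra = _evolve(
                    tips[genome_id], -np.log(1.0 - spec.dup_divergence), rng
                )
                add(genome_id, f"{family}B", extra, "DUP", family)

    subset_size = max(1, spec.n_genomes // 2)
    for f in range(spec.n_accessory):
        family = f"ACCS{f:04d}"
        root = _random_protein(accessory_rng, spec.protein_length)
        start = f % spec.n_genomes
        subset = [genome_ids[(start + k) % spec.n_genomes] for k in range(subset_size)]
        for genome_id in sorted(subset):
            variant = _evolve(root, 0.05, accessory_rng)
            add(genome_id, family, variant, "ACCESSORY", family)

    records = {
        g: GenomeRecord(genome_id=g, sequences=genes[g]) for g in genome_ids
    }
    return records, truth


# --- serialization ---------------------------------------------------------


def write_genbank(genome: GenomeRecord, out_dir: str | Path) -> Path:
    """Emit a minimal valid GenBank flat file: back-translated nucleotide
    sequence with one CDS feature (locus_tag + translation) per gene."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacer = "TTAATTAATT"
    chunks: list[str] = []
    features: list[SeqFeature] = []
    cursor = 0
    for cds in genome.sequences:
        nt = "".join(_CODON[aa] for aa in cds.protein.replace("*", "X")) + "TAA"
        chunks.append(nt)
        features.append(
            SeqFeature(
                FeatureLocation(cursor, cursor + len(nt), strand=1),
                type="CDS",
                qualifiers={
                    "locus_tag": [cds.locus_id],
                    "translation": [cds.protein],
                    "transl_table": ["11"],
                },
            )
        )
        cursor += len(nt)
        chunks.append(spacer)
        cursor += len(spacer)
    record = SeqRecord(
        Seq("".join(chunks)),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description="synthetic genome",
        features=features,
        annotations={"molecule_type": "DNA"},
    )
    path = out_dir / f"{genome.genome_id}.gbk"
    SeqIO.write(record, str(path), "genbank")
    return path


def write_genome_set(
    genomes: dict[str, GenomeRecord],
    out_dir: str | Path,
    fmt: str = "genbank",
) -> list[Path]:
    out_dir = Path(out_dir)
    paths = []
    for genome_id in sorted(genomes):
        if fmt == "genbank":
            paths.append(write_genbank(genomes[genome_id], out_dir))
        elif fmt == "fasta":
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{genome_id}.fasta"
            with open(path, "w") as handle:
                for cds in genomes[genome_id].sequences:
                    handle.write(f">{cds.locus_id}\n{cds.protein}\n")
            paths.append(path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return paths
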