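"""Per-locus alignment and supermatrix concatenation.

Each selected locus is gathered across genomes (records labeled by genome
id, so downstream tree tips are genomes), aligned independently, and the
alignments are concatenated in lexicographic locus order into a single
partitioned supermatrix.  Genomes missing a locus (presence < 100 runs)
receive a gap run of that locus's aligned length.

The internal aligner is a deterministic progressive scheme (global
Needleman–Wunsch of each next sequence against the growing profile,
BLOSUM62, gap open 10 / extend 1, guide order = lexicographic genome id);
it exists so the full pipeline runs binary-free.  MUSCLE (v3 ``-in/-out``
and v5 ``-align/-output`` conventions) is available behind an adapter for
production runs.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from coretree._errors import ConfigurationError, ExternalToolError, IntegrityError
from coretree.extract import GenomeRecord
from coretree.screen import LocusSelection

logger = logging.getLogger(__name__)

GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM.alphabet)
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_MATRIX = np.array(_BLOSUM, dtype=float)


@dataclass
class LocusAlignment:
    """One locus aligned across genomes; rows keyed by genome id."""

    locus_id: str
    rows: dict[str, str]

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def __post_init__(self):
        lengths = {len(seq) for seq in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment for locus {self.locus_id}")
        if self.length < 1:
            raise ValueError(f"zero-length alignment for locus {self.locus_id}")

    def ungapped(self, genome_id: str) -> str:
        return self.rows[genome_id].replace("-", "")

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            for genome_id in sorted(self.rows):
                handle.write(f">{genome_id}\n{self.rows[genome_id]}\n")
        return path


@dataclass
class Supermatrix:
    """Concatenated per-locus alignments plus the partition map
    (1-based inclusive column intervals that tile [1, length])."""

    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # ordered: insertion = locus order

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def slice(self, genome_id: str, locus_id: str) -> str:
        start, end = self.partitions[locus_id]
        return self.rows[genome_id][start - 1:end]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            for genome_id in sorted(self.rows):
                handle.write(f">{genome_id}\n{self.rows[genome_id]}\n")
        return path

    def write_partitions_raxml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            for locus_id, (start, end) in self.partitions.items():
                handle.write(f"PROT, {locus_id} = {start}-{end}\n")
        return path

    def write_partitions_nexus(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            handle.write("#nexus\nbegin sets;\n")
            for locus_id, (start, end) in self.partitions.items():
                handle.write(f"    charset {locus_id} = {start}-{end};\n")
            handle.write("end;\n")
        return path


def gather_locus(
    selection: LocusSelection,
    locus: str,
    genomes: dict[str, GenomeRecord],
) -> list[tuple[str, str]]:
    """(genome_id, protein) pairs for every genome where ``locus`` is a
    singleton, sorted by genome id."""
    if locus not in selection.members:
        raise KeyError(f"locus {locus!r} not in selection")
    out = []
    for genome_id in sorted(selection.members[locus]):
        member_locus = selection.members[locus][genome_id]
        if genome_id not in genomes:
            raise IntegrityError(f"genome {genome_id!r} missing from parsed genomes")
        cds = genomes[genome_id].get(member_locus)
        if cds is None:
            raise IntegrityError(
                f"locus {locus}: member {member_locus!r} missing from genome "
                f"{genome_id!r}"
            )
        out.append((genome_id, cds.protein))
    return out


def write_locus_fasta(
    seqs: list[tuple[str, str]], locus: str, out_dir: str | Path
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe = locus.replace("|", "_")
    path = out_dir / f"{safe}.fasta"
    with open(path, "w") as handle:
        for genome_id, protein in seqs:
            handle.write(f">{genome_id}\n{protein}\n")
    return path


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _nw_profile(profile: np.ndarray, seq: np.ndarray) -> tuple[list[int], list[int]]:
    """Global alignment of a profile (columns x rows of residue indices,
    -1 = gap) against one sequence.

    Returns two lists of column operations: positions where a gap column is
    inserted into the profile, and positions where the sequence takes a gap.
    Deterministic tie-break: diagonal > profile-gap > sequence-gap.
    """
    n_cols = profile.shape[0]
    n_seq = seq.shape[0]
    # mean substitution score of each profile column vs each alphabet letter
    col_scores = np.zeros((n_cols, len(_ALPHABET)))
    for c in range(n_cols):
        residues = profile[c][profile[c] >= 0]
        if residues.size:
            col_scores[c] = _MATRIX[residues].mean(axis=0)
    NEG = -1e12
    # affine gaps, gap of length k costs GAP_OPEN + k * GAP_EXTEND
    open_cost = GAP_OPEN + GAP_EXTEND
    m = np.full((n_cols + 1, n_seq + 1), NEG)
    ix = np.full((n_cols + 1, n_seq + 1), NEG)  # gap in sequence (consume column)
    iy = np.full((n_cols + 1, n_seq + 1), NEG)  # gap in profile (consume residue)
    m[0, 0] = 0.0
    for i in range(1, n_cols + 1):
        ix[i, 0] = -open_cost - (i - 1) * GAP_EXTEND
    for j in range(1, n_seq + 1):
        iy[0, j] = -open_cost - (j - 1) * GAP_EXTEND
    for i in range(1, n_cols + 1):
        score_row = col_scores[i - 1]
        for j in range(1, n_seq + 1):
            best_prev = max(m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            m[i, j] = best_prev + score_row[seq[j - 1]]
            ix[i, j] = max(
                max(m[i - 1, j], iy[i - 1, j]) - open_cost,
                ix[i - 1, j] - GAP_EXTEND,
            )
            iy[i, j] = max(
                max(m[i, j - 1], ix[i, j - 1]) - open_cost,
                iy[i, j - 1] - GAP_EXTEND,
            )
    # traceback
    i, j = n_cols, n_seq
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("D")
            prev = [m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append("C")  # consume column, gap in sequence
            choices = [
                m[i - 1, j] - open_cost,
                ix[i - 1, j] - GAP_EXTEND,
                iy[i - 1, j] - open_cost,
            ]
            state = int(np.argmax([choices[0], choices[1], choices[2]]))
            i -= 1
        elif state == 2 and j > 0:
            ops.append("R")  # consume residue, gap column in profile
            choices = [
                m[i, j - 1] - open_cost,
                ix[i, j - 1] - open_cost,
                iy[i, j - 1] - GAP_EXTEND,
            ]
            state = int(np.argmax([choices[0], choices[1], choices[2]]))
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    ops.reverse()
    seq_gap_cols = []  # indices (in final coordinates) where sequence is gapped
    profile_gap_cols = []  # indices where a gap column enters the profile
    for pos, op in enumerate(ops):
        if op == "C":
            seq_gap_cols.append(pos)
        elif op == "R":
            profile_gap_cols.append(pos)
    return profile_gap_cols, seq_gap_cols


def _align_internal(seqs: list[tuple[str, str]]) -> LocusAlignment:
    ordered = sorted(seqs)
    rows: list[str] = [ordered[0][1]]
    for _, seq in ordered[1:]:
        profile = np.array(
            [[_INDEX[c] if c != "-" else -1 for c in row] for row in rows]
        ).T  # columns x rows
        profile_gap_cols, seq_gap_cols = _nw_profile(profile, _encode(seq))
        total = len(rows[0]) + len(profile_gap_cols)
        gap_set = set(profile_gap_cols)
        new_rows = []
        for row in rows:
            it = iter(row)
            new_rows.append(
                "".join("-" if c in gap_set else next(it) for c in range(total))
            )
        seq_gaps = set(seq_gap_cols)
        it = iter(seq)
        new_seq = "".join("-" if c in seq_gaps else next(it) for c in range(total))
        rows = new_rows + [new_seq]
    return LocusAlignment(
        locus_id="", rows={gid: row for (gid, _), row in zip(ordered, rows)}
    )


def _align_muscle(
    seqs: list[tuple[str, str]], executable: str = "muscle"
) -> LocusAlignment:
    if shutil.which(executable) is None:
        raise ConfigurationError(f"aligner {executable!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "in.fasta"
        out_path = Path(tmp) / "out.fasta"
        with open(in_path, "w") as handle:
            for genome_id, protein in sorted(seqs):
                handle.write(f">{genome_id}\n{protein}\n")
        version = subprocess.run(
            [executable, "-version"], capture_output=True, text=True
        ).stdout
        if "muscle 5" in version.lower() or "muscle v5" in version.lower():
            cmd = [executable, "-align", str(in_path), "-output", str(out_path)]
        else:
            cmd = [executable, "-in", str(in_path), "-out", str(out_path)]
        logger.info("running: %s", " ".join(cmd))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError("muscle failed", proc.stderr)
        rows = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(out_path), "fasta")
        }
    return LocusAlignment(locus_id="", rows=rows)


def align_locus(
    seqs: list[tuple[str, str]],
    aligner: str = "internal",
    locus_id: str = "",
) -> LocusAlignment:
    """Align one locus's sequences; ``aligner`` is ``internal`` or
    ``muscle``.  Ungapping any output row reproduces its input exactly."""
    if len(seqs) < 2:
        raise ValueError("cannot align fewer than 2 sequences")
    if aligner == "internal":
        alignment = _align_internal(seqs)
    elif aligner == "muscle":
        alignment = _align_muscle(seqs)
    else:
        raise ConfigurationError(f"unknown aligner {aligner!r}")
    alignment.locus_id = locus_id
    for genome_id, protein in seqs:
        if alignment.ungapped(genome_id) != protein:
            raise IntegrityError(
                f"aligner corrupted sequence for genome {genome_id!r}"
            )
    return alignment


def concatenate(
    alignments: list[LocusAlignment], all_genomes: list[str]
) -> Supermatrix:
    """Concatenate per-locus alignments (must be pre-sorted by locus id)
    over ``all_genomes``; absent genomes are gap-filled per locus."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    locus_ids = [a.locus_id for a in alignments]
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus ids in concatenation")
    if locus_ids != sorted(locus_ids):
        raise ValueError("alignments must be sorted lexicographically by locus id")
    genomes = sorted(all_genomes)
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    partitions: dict[str, tuple[int, int]] = {}
    cursor = 1
    for alignment in alignments:
        width = alignment.length
        for genome in genomes:
            parts[genome].append(alignment.rows.get(genome, "-" * width))
        partitions[alignment.locus_id] = (cursor, cursor + width - 1)
        cursor += width
    return Supermatrix(
        rows={g: "".join(chunks) for g, chunks in parts.items()},
        partitions=partitions,
    )
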