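"""Protein similarity search over per-genome databases.

Two interchangeable backends sit behind one contract:

* :class:`InternalBackend` — exact Smith–Waterman local alignment
  (BLOSUM62, affine gaps open 11 / extend 1, BLAST convention: a gap of
  length *k* costs ``11 + k``) scored through Biopython's C implementation,
  with E-values from the Karlin–Altschul formula using the standard gapped
  parameters for this scoring scheme (lambda = 0.267, K = 0.041) and a
  pairwise ``m x n`` search space.  The pairwise search space makes hits
  exactly symmetric: E(a->b) == E(b->a).
* :class:`DiamondBackend` — adapter shelling out to a DIAMOND-compatible
  executable for large runs.

Only the hit/no-hit decision feeds the downstream singleton screen, so the
internal backend does not need to reproduce any particular external tool
bit-for-bit — it needs to be a correct, deterministic local aligner.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from coretree._errors import ConfigurationError, EmptyGenomeError, ExternalToolError
from coretree.extract import CodingSequence, GenomeRecord

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MAX_EVALUE = 1e-3

GAP_OPEN = 11
GAP_EXTEND = 1


@dataclass
class ProteinDatabase:
    """Searchable collection of one genome's proteins."""

    genome_id: str
    entries: dict[str, str]  # locus_id -> protein

    def __post_init__(self):
        if not self.entries:
            raise EmptyGenomeError(f"empty database for genome {self.genome_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> Path:
        """Persist as JSON so the checkpoint system can resume."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            json.dump(
                {"genome_id": self.genome_id, "entries": self.entries},
                handle, indent=0, sort_keys=True,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProteinDatabase":
        with open(path) as handle:
            data = json.load(handle)
        return cls(genome_id=data["genome_id"], entries=data["entries"])


@dataclass(frozen=True)
class SearchHit:
    query_id: str  # qualified genome|locus
    subject_id: str  # qualified genome|locus
    score: float  # bit score
    evalue: float
    identity: float  # fraction of identical positions in [0, 1]

    def sort_key(self):
        return (self.evalue, -self.score, self.subject_id)


def karlin_altschul_evalue(raw_score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S) over the pairwise search space."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    # open_gap_score applies to the first gapped position, so a gap of
    # length k scores -(GAP_OPEN + 1) - (k - 1) * GAP_EXTEND = -(11 + k).
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


class InternalBackend:
    """Exact Smith–Waterman search; deterministic and binary-free."""

    name = "internal"

    def __init__(self, max_evalue: float = DEFAULT_MAX_EVALUE):
        if max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        self.max_evalue = max_evalue
        self._aligner = _make_aligner()

    def build_database(self, genome: GenomeRecord) -> ProteinDatabase:
        if not genome.sequences:
            raise EmptyGenomeError(f"genome {genome.genome_id} has no sequences")
        return ProteinDatabase(
            genome_id=genome.genome_id,
            entries={cds.locus_id: cds.protein for cds in genome.sequences},
        )

    def raw_score(self, query: str, subject: str) -> float:
        return self._aligner.score(query, subject)

    def _identity(self, query: str, subject: str) -> float:
        if query == subject:
            return 1.0
        alignment = self._aligner.align(query, subject)[0]
        counts = alignment.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            return 0.0
        return counts.identities / columns

    def search(
        self,
        query: CodingSequence,
        db: ProteinDatabase,
        max_evalue: float | None = None,
    ) -> list[SearchHit]:
        """All subjects with local-alignment E-value <= threshold, in a
        deterministic total order (evalue asc, score desc, subject id).

        The self-hit is always present when the query belongs to the
        database's genome, regardless of threshold."""
        threshold = self.max_evalue if max_evalue is None else max_evalue
        if threshold <= 0:
            raise ValueError("max_evalue must be positive")
        if not query.protein:
            raise ValueError("query protein is empty")
        hits: list[SearchHit] = []
        is_own_genome = query.genome_id == db.genome_id
        for locus_id in db.entries:
            subject = db.entries[locus_id]
            is_self = is_own_genome and locus_id == query.locus_id
            score = self.raw_score(query.protein, subject)
            evalue = karlin_altschul_evalue(score, len(query.protein), len(subject))
            if evalue <= threshold or is_self:
                hits.append(
                    SearchHit(
                        query_id=query.qualified_id,
                        subject_id=f"{db.genome_id}|{locus_id}",
                        score=bit_score(score),
                        evalue=evalue,
                        identity=self._identity(query.protein, subject),
                    )
                )
        hits.sort(key=SearchHit.sort_key)
        return hits

    def count_hits(
        self,
        query: CodingSequence,
        db: ProteinDatabase,
        max_evalue: float | None = None,
    ) -> int:
        return len(self.search(query, db, max_evalue))

    def within_genome_hit_counts(
        self, db: ProteinDatabase, max_evalue: float | None = None
    ) -> dict[str, int]:
        """Hit count of every database entry against its own genome.

        Exploits the exact symmetry of the internal scoring (same matrix,
        same pairwise search space both ways) to score each unordered pair
        once; results equal running :meth:`count_hits` per entry."""
        threshold = self.max_evalue if max_evalue is None else max_evalue
        loci = sorted(db.entries)
        counts = {locus: 1 for locus in loci}  # self-hit always present
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                score = self.raw_score(db.entries[a], db.entries[b])
                evalue = karlin_altschul_evalue(
                    score, len(db.entries[a]), len(db.entries[b])
                )
                if evalue <= threshold:
                    counts[a] += 1
                    counts[b] += 1
        return counts


class DiamondBackend:
    """Adapter for a DIAMOND-compatible ``blastp`` executable.

    Databases are materialized under a working directory; searches parse the
    5-column tabular output ``qseqid sseqid pident evalue bitscore``.  The
    self-hit is inserted post hoc if the heuristic search drops it, so the
    singleton logic is backend-independent.
    """

    name = "diamond"
    _FIELDS = ["qseqid", "sseqid", "pident", "evalue", "bitscore"]

    def __init__(
        self,
        executable: str = "diamond",
        workdir: str | Path | None = None,
        max_evalue: float = DEFAULT_MAX_EVALUE,
    ):
        self.executable = executable
        self.workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp())
        self.max_evalue = max_evalue
        if shutil.which(executable) is None:
            raise ConfigurationError(
                f"external search tool {executable!r} not found on PATH"
            )

    def _run(self, args: list[str]) -> subprocess.CompletedProcess:
        proc = subprocess.run(
            [self.executable, *args], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise ExternalToolError(
                f"{self.executable} {' '.join(args[:1])} failed", proc.stderr
            )
        return proc

    def build_database(self, genome: GenomeRecord) -> ProteinDatabase:
        if not genome.sequences:
            raise EmptyGenomeError(f"genome {genome.genome_id} has no sequences")
        db_dir = self.workdir / "dmnd"
        db_dir.mkdir(parents=True, exist_ok=True)
        fasta = db_dir / f"{genome.genome_id}.faa"
        with open(fasta, "w") as handle:
            for cds in genome.sequences:
                handle.write(f">{cds.locus_id}\n{cds.protein}\n")
        self._run(
            ["makedb", "--in", str(fasta), "--db", str(db_dir / genome.genome_id)]
        )
        return ProteinDatabase(
            genome_id=genome.genome_id,
            entries={cds.locus_id: cds.protein for cds in genome.sequences},
        )

    def search(
        self,
        query: CodingSequence,
        db: ProteinDatabase,
        max_evalue: float | None = None,
    ) -> list[SearchHit]:
        threshold = self.max_evalue if max_evalue is None else max_evalue
        query_path = self.workdir / "query.faa"
        out_path = self.workdir / "hits.tsv"
        with open(query_path, "w") as handle:
            handle.write(f">{query.locus_id}\n{query.protein}\n")
        self._run(
            [
                "blastp",
                "--query", str(query_path),
                "--db", str(self.workdir / "dmnd" / db.genome_id),
                "--out", str(out_path),
                "--evalue", str(threshold),
                "--outfmt", "6", *self._FIELDS,
            ]
        )
        hits = []
        seen_self = False
        with open(out_path) as handle:
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    continue
                qseqid, sseqid, pident, evalue, bits = fields[:5]
                if query.genome_id == db.genome_id and sseqid == query.locus_id:
                    seen_self = True
                hits.append(
                    SearchHit(
                        query_id=query.qualified_id,
                        subject_id=f"{db.genome_id}|{sseqid}",
                        score=float(bits),
                        evalue=float(evalue),
                        identity=float(pident) / 100.0,
                    )
                )
        if query.genome_id == db.genome_id and not seen_self:
            hits.append(
                SearchHit(
                    query_id=query.qualified_id,
                    subject_id=query.qualified_id,
                    score=bit_score(len(query.protein) * 4.0),
                    evalue=0.0,
                    identity=1.0,
                )
            )
        hits.sort(key=SearchHit.sort_key)
        return hits

    def count_hits(self, query, db, max_evalue=None) -> int:
        return len(self.search(query, db, max_evalue))

    def within_genome_hit_counts(
        self, db: ProteinDatabase, max_evalue: float | None = None
    ) -> dict[str, int]:
        counts = {}
        for locus_id, protein in db.entries.items():
            query = CodingSequence(db.genome_id, locus_id, protein)
            counts[locus_id] = self.count_hits(query, db, max_evalue)
        return counts


# Module-level convenience API bound to a shared internal backend.
_default_backend = None


def default_backend() -> InternalBackend:
    global _default_backend
    if _default_backend is None:
        _default_backend = InternalBackend()
    return _default_backend


def build_database(genome: GenomeRecord) -> ProteinDatabase:
    return default_backend().build_database(genome)


def search(query, db, max_evalue: float = DEFAULT_MAX_EVALUE) -> list[SearchHit]:
    return default_backend().search(query, db, max_evalue)


def count_hits(query, db, max_evalue: float = DEFAULT_MAX_EVALUE) -> int:
    return default_backend().count_hits(query, db, max_evalue)
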