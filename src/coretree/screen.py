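"""Singleton identification and orthologous-locus selection.

A locus qualifies for tree building only if it is a singleton (exactly one
within-genome hit: itself) in the seed genome and is present as a singleton
in enough of the other genomes.  Any genome where the locus has two or more
hits (MULTI) disqualifies the locus outright — paralogue contamination is
the failure mode this screen exists to avoid.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from coretree._errors import ConfigurationError, NoLociError
from coretree.extract import CodingSequence, GenomeRecord
from coretree.search_backend import InternalBackend, ProteinDatabase

logger = logging.getLogger(__name__)


class Status(str, Enum):
    SINGLETON = "S"
    MULTI = "M"
    ABSENT = "A"


@dataclass
class PresenceMatrix:
    """Per (locus, genome) copy-number status for the seed genome's
    singletons screened against every genome."""

    loci: list[str]  # qualified seed-genome locus ids, sorted
    genomes: list[str]  # genome ids, sorted
    status: dict[tuple[str, str], Status]
    best_match: dict[tuple[str, str], str] = field(default_factory=dict)
    seed_genome: str = ""

    def singleton_count(self, locus: str) -> int:
        return sum(
            1 for g in self.genomes if self.status[(locus, g)] is Status.SINGLETON
        )

    def has_multi(self, locus: str) -> bool:
        return any(self.status[(locus, g)] is Status.MULTI for g in self.genomes)

    def to_tsv(self, path: str | Path) -> Path:
        """Audit report: rows = loci, columns = genomes, cells = S/M/A with
        the best-match locus id appended for singleton cells."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            handle.write("locus\t" + "\t".join(self.genomes) + "\n")
            for locus in self.loci:
                cells = []
                for genome in self.genomes:
                    status = self.status[(locus, genome)]
                    cell = status.value
                    if status is Status.SINGLETON:
                        cell += ":" + self.best_match[(locus, genome)]
                    cells.append(cell)
                handle.write(locus + "\t" + "\t".join(cells) + "\n")
        return path


@dataclass
class LocusSelection:
    """The loci that survived the screen, with per-genome members."""

    loci: list[str]
    members: dict[str, dict[str, str]]  # locus -> genome_id -> subject locus_id
    presence_threshold: float
    maxloci: int | None
    seed_genome: str

    def __len__(self) -> int:
        return len(self.loci)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            for locus in self.loci:
                handle.write(locus + "\n")
        return path


def find_singletons(
    db: ProteinDatabase,
    max_evalue: float | None = None,
    backend: InternalBackend | None = None,
) -> set[str]:
    """Loci of ``db``'s genome whose within-genome hit count is exactly one
    (the guaranteed self-hit).  Returns qualified ``genome|locus`` ids."""
    backend = backend or InternalBackend()
    counts = backend.within_genome_hit_counts(db, max_evalue)
    return {
        f"{db.genome_id}|{locus}" for locus, n in counts.items() if n == 1
    }


def screen_loci(
    singletons: set[str],
    genomes: dict[str, GenomeRecord],
    dbs: dict[str, ProteinDatabase],
    max_evalue: float | None = None,
    backend: InternalBackend | None = None,
    seed_genome: str | None = None,
) -> PresenceMatrix:
    """Query every seed singleton against every genome and record its
    copy-number status: 0 hits -> ABSENT, 1 -> SINGLETON, >=2 -> MULTI."""
    backend = backend or InternalBackend()
    if not singletons:
        raise NoLociError("seed genome yielded no singletons")
    seed = seed_genome or sorted(singletons)[0].split("|", 1)[0]
    if seed not in dbs:
        raise ConfigurationError(f"seed genome {seed!r} has no database")
    missing = sorted(set(genomes) ^ set(dbs))
    if missing:
        raise ConfigurationError(f"genomes without databases (or vice versa): {missing}")

    loci = sorted(singletons)
    genome_ids = sorted(genomes)
    status: dict[tuple[str, str], Status] = {}
    best_match: dict[tuple[str, str], str] = {}
    for locus in loci:
        genome_id, locus_id = locus.split("|", 1)
        protein = dbs[genome_id].entries[locus_id]
        query = CodingSequence(genome_id, locus_id, protein)
        for target in genome_ids:
            hits = backend.search(query, dbs[target], max_evalue)
            key = (locus, target)
            if len(hits) == 0:
                status[key] = Status.ABSENT
            elif len(hits) == 1:
                status[key] = Status.SINGLETON
                best_match[key] = hits[0].subject_id.split("|", 1)[1]
            else:
                status[key] = Status.MULTI
    return PresenceMatrix(
        loci=loci, genomes=genome_ids, status=status,
        best_match=best_match, seed_genome=seed,
    )


def select_loci(
    matrix: PresenceMatrix,
    presence_threshold: float = 100.0,
    maxloci: int | None = None,
    rng_seed: int | None = None,
) -> LocusSelection:
    """Keep loci with no MULTI cell anywhere and a singleton count of at
    least ``ceil(presence_threshold / 100 * n_genomes)``.

    If more than ``maxloci`` survive, the first ``maxloci`` in lexicographic
    order are kept, or a seeded uniform sample when ``rng_seed`` is given.
    Zero surviving loci is a hard error.
    """
    if not 0 < presence_threshold <= 100:
        raise ValueError("presence_threshold must be in (0, 100]")
    if maxloci is not None and maxloci < 1:
        raise ValueError("maxloci must be a positive integer")
    required = math.ceil(presence_threshold / 100.0 * len(matrix.genomes))
    survivors = [
        locus
        for locus in sorted(matrix.loci)
        if not matrix.has_multi(locus) and matrix.singleton_count(locus) >= required
    ]
    if not survivors:
        raise NoLociError(
            "no loci passed the screen; lower --presence or try a different "
            "seed genome"
        )
    if maxloci is not None and len(survivors) > maxloci:
        if rng_seed is not None:
            survivors = sorted(random.Random(rng_seed).sample(survivors, maxloci))
        else:
            survivors = survivors[:maxloci]
    members = {
        locus: {
            genome: matrix.best_match[(locus, genome)]
            for genome in matrix.genomes
            if matrix.status[(locus, genome)] is Status.SINGLETON
        }
        for locus in survivors
    }
    logger.info(
        "selected %d loci (presence >= %s%%, required singletons %d/%d)",
        len(survivors), presence_threshold, required, len(matrix.genomes),
    )
    return LocusSelection(
        loci=survivors,
        members=members,
        presence_threshold=presence_threshold,
        maxloci=maxloci,
        seed_genome=matrix.seed_genome,
    )
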