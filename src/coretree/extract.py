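"""GenBank / proteome parsing: one protein collection per input genome.

Each input file becomes one :class:`GenomeRecord`; its ``genome_id`` is the
file name with the final extension stripped and later becomes a tree tip
label.  CDS features are keyed by a configurable qualifier (``locus_tag``
by default, switchable to e.g. ``protein_id``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from coretree._errors import EmptyGenomeError, ParseError

logger = logging.getLogger(__name__)

# 20 standard residues; X is the ambiguity catch-all, * an internal stop.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_AA = STANDARD_AA + "X*"
_NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}


def sanitize_protein(raw: str) -> str:
    """Normalize a protein string: upper-case, strip one trailing stop,
    map non-standard residues (B/Z/U/O/J) to X.

    Raises ``ValueError`` on characters outside the IUPAC alphabet or on an
    empty result.
    """
    seq = raw.strip().upper().replace(" ", "").replace("\n", "")
    if seq.endswith("*"):
        seq = seq[:-1]
    seq = "".join(_NONSTANDARD.get(c, c) for c in seq)
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(ALLOWED_AA)
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in protein sequence")
    return seq


@dataclass(frozen=True)
class CodingSequence:
    """A single protein-coding gene."""

    genome_id: str
    locus_id: str
    protein: str
    source_tag: str = "locus_tag"

    @property
    def qualified_id(self) -> str:
        """Globally unique id: ``genome_id|locus_id``."""
        return f"{self.genome_id}|{self.locus_id}"


@dataclass
class GenomeRecord:
    """All coding sequences extracted from one input file, in file order."""

    genome_id: str
    sequences: list[CodingSequence] = field(default_factory=list)
    source_path: Path | None = None
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def get(self, locus_id: str) -> CodingSequence | None:
        for cds in self.sequences:
            if cds.locus_id == locus_id:
                return cds
        return None


def genome_id_from_path(path: str | Path) -> str:
    return Path(path).name.rsplit(".", 1)[0]


def _conceptual_translation(feature, parent_seq: Seq) -> str | None:
    """Translate a CDS feature's spliced span; None when the span is not a
    multiple of three."""
    sub = feature.location.extract(parent_seq)
    if len(sub) % 3 != 0:
        return None
    table = feature.qualifiers.get("transl_table", ["1"])[0]
    protein = str(sub.translate(table=int(table)))
    return protein


def parse_genbank(path: str | Path, tag: str = "locus_tag") -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    One :class:`CodingSequence` is produced per CDS feature that yields both
    an identifier (from ``tag``) and a protein (from the ``translation``
    qualifier, or by conceptual translation of the spliced nucleotide span).
    Features missing the tag, failing translation, or duplicating an earlier
    locus id are skipped with a logged warning and counted in ``n_skipped``.
    """
    if not tag:
        raise ValueError("tag must be a non-empty qualifier name")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    genome_id = genome_id_from_path(path)
    record = GenomeRecord(genome_id=genome_id, source_path=path)
    seen: set[str] = set()
    n_cds = 0
    try:
        contigs = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # malformed flat file
        raise ParseError(f"could not parse GenBank file {path}: {exc}") from exc
    if not contigs:
        raise ParseError(f"no GenBank records found in {path}")
    for contig in contigs:
        for feature in contig.features:
            if feature.type != "CDS":
                continue
            n_cds += 1
            values = feature.qualifiers.get(tag)
            if not values:
                logger.warning(
                    "%s: CDS at %s lacks qualifier %r; skipped",
                    path.name, feature.location, tag,
                )
                record.n_skipped += 1
                continue
            locus_id = str(values[0]).strip()
            if locus_id in seen:
                logger.warning(
                    "%s: duplicate locus id %r; keeping first occurrence",
                    path.name, locus_id,
                )
                record.n_skipped += 1
                continue
            raw = feature.qualifiers.get("translation", [None])[0]
            if raw is None:
                raw = _conceptual_translation(feature, contig.seq)
                if raw is None:
                    logger.warning(
                        "%s: CDS %s span not a multiple of 3; skipped",
                        path.name, locus_id,
                    )
                    record.n_skipped += 1
                    continue
            try:
                protein = sanitize_protein(raw)
            except ValueError as exc:
                logger.warning("%s: CDS %s: %s; skipped", path.name, locus_id, exc)
                record.n_skipped += 1
                continue
            seen.add(locus_id)
            record.sequences.append(
                CodingSequence(genome_id, locus_id, protein, source_tag=tag)
            )
    if not record.sequences:
        raise EmptyGenomeError(
            f"{path}: no usable CDS features (out of {n_cds}) with qualifier {tag!r}"
        )
    return record


def write_proteome_fasta(genome: GenomeRecord, out_dir: str | Path) -> Path:
    """Write one protein FASTA per genome (header = locus_id)."""
    if not genome.sequences:
        raise EmptyGenomeError(f"genome {genome.genome_id} has no sequences")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / f"{genome.genome_id}.fasta"
    with open(out_path, "w") as handle:
        for cds in genome.sequences:
            handle.write(f">{cds.locus_id}\n{cds.protein}\n")
    return out_path


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a protein FASTA as one genome; locus id = first header token.

    Raises :class:`ParseError` listing any duplicated identifiers.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = genome_id_from_path(path)
    record = GenomeRecord(genome_id=genome_id, source_path=path)
    seen: set[str] = set()
    duplicates: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        locus_id = entry.id
        if locus_id in seen:
            duplicates.append(locus_id)
            continue
        seen.add(locus_id)
        record.sequences.append(
            CodingSequence(genome_id, locus_id, sanitize_protein(str(entry.seq)),
                           source_tag="fasta_header")
        )
    if duplicates:
        raise ParseError(f"{path}: duplicate identifiers: {sorted(set(duplicates))}")
    if not record.sequences:
        raise EmptyGenomeError(f"{path}: no FASTA records")
    return record


def load_genomes(
    paths: Iterable[str | Path], tag: str = "locus_tag"
) -> dict[str, GenomeRecord]:
    """Parse many input files (GenBank by extension, FASTA otherwise) into a
    mapping keyed by genome id.  Colliding genome ids are a hard error since
    they become tree tip labels."""
    genomes: dict[str, GenomeRecord] = {}
    for path in sorted(Path(p) for p in paths):
        if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}:
            record = parse_genbank(path, tag=tag)
        else:
            record = read_proteome_fasta(path)
        if record.genome_id in genomes:
            raise ParseError(
                f"genome id {record.genome_id!r} derived from more than one input file"
            )
        genomes[record.genome_id] = record
    return genomes
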