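"""FASTA input/output and DNA record handling.

Records keep their residues exactly as read (uppercased); characters outside
the unambiguous alphabet ``{A, C, G, T}`` are retained and reported, never
silently dropped — the k-mer encoder decides how to treat them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ncdna")

#: Unambiguous DNA alphabet; everything else counts as ambiguous.
DNA_ALPHABET = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA content (e.g. empty record body)."""


@dataclass(frozen=True)
class Sequence:
    """One DNA record: identifier, residue string, optional full header.

    ``id`` is the FASTA header token up to the first whitespace; the full
    header line (sans ``>``) is preserved in ``description``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence body")

    @property
    def length(self) -> int:
        """Number of residues (L)."""
        return len(self.residues)

    def normalized(self) -> "Sequence":
        """Uppercase copy; idempotent."""
        return Sequence(self.id, self.residues.upper(), self.description)


@dataclass(frozen=True)
class AmbiguityReport:
    """Positions (1-based) of residues outside {A,C,G,T} in one record."""

    record_id: str
    positions: tuple[int, ...] = field(default=())

    @property
    def count(self) -> int:
        return len(self.positions)


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read all records from a FASTA file (plain or gzip), order preserved.

    Residues are normalized to uppercase. Duplicate identifiers are permitted
    but logged. A record with an empty body raises :class:`FastaFormatError`
    naming the record.
    """
    path = Path(path)
    records: list[Sequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            body = str(rec.seq).upper()
            if not body:
                raise FastaFormatError(f"record {rec.id!r} has an empty sequence body")
            if rec.id in seen:
                logger.warning("duplicate FASTA identifier %r in %s", rec.id, path)
            seen.add(rec.id)
            desc = "" if rec.description == rec.id else rec.description
            records.append(Sequence(rec.id, body, desc))
    return records


def write_fasta(
    records: Iterable[Sequence], path: str | Path, line_width: int = 60
) -> Path:
    """Write records as FASTA with headers ``>id`` (description appended when
    it adds information) and bodies wrapped at ``line_width`` columns.
    """
    path = Path(path)
    with _open_text(path, "wt") as handle:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc_tail = rec.description
                if desc_tail.startswith(rec.id):
                    header = desc_tail
                else:
                    header = f"{rec.id} {desc_tail}"
            handle.write(f">{header}\n")
            body = rec.residues
            for start in range(0, len(body), line_width):
                handle.write(body[start : start + line_width] + "\n")
    return path


def ambiguity_report(record: Sequence) -> AmbiguityReport:
    """Locate residues outside {A,C,G,T}; positions are 1-based."""
    positions = tuple(
        i + 1 for i, base in enumerate(record.residues) if base not in DNA_ALPHABET
    )
    return AmbiguityReport(record.id, positions)


def to_seqrecords(records: TypingSequence[Sequence]) -> list[SeqRecord]:
    """Convert to Biopython records (interop convenience)."""
    return [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
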