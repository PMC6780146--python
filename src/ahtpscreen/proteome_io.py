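"""Species proteome FASTA I/O with validation.

Protein sequences are uppercased and stripped of stop characters ('*') on
read; ambiguity characters (B, J, O, U, X, Z) are retained — they never
match a canonical-alphabet peptide, so they act as match breakers rather
than wildcards. No redundancy collapsing is performed: every record counts
toward the species' total protein number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id (first header token), description (header remainder),
    sanitized uppercase sequence."""

    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if "*" in self.sequence or any(c.isspace() for c in self.sequence):
            raise ValueError(f"{self.protein_id}: unsanitized sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Proteome:
    """One species' ordered protein set with unique identifiers."""

    species: str
    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        ids = set()
        for r in self.records:
            if r.protein_id in ids:
                raise IntegrityError(
                    f"duplicate protein_id {r.protein_id!r} in {self.species}"
                )
            ids.add(r.protein_id)

    @property
    def total_protein_count(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def get(self, protein_id: str) -> Optional[ProteinRecord]:
        # linear fallback is avoided via the cached index
        return self._index().get(protein_id)

    def _index(self) -> dict[str, ProteinRecord]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {r.protein_id: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx


def read_proteome_fasta(path: str | Path, species: str) -> Proteome:
    """Read one species' proteome from protein FASTA.

    Sequences are uppercased; '*' characters (translated stop codons) are
    removed with a logged count; records whose sequence is empty after
    sanitation are dropped with a logged count. Duplicate identifiers raise
    :class:`IntegrityError`; non-FASTA content raises :class:`FormatError`
    with the offending line number.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header starting "
                        f"with '>', got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FormatError(f"{path}: empty file, no FASTA records")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    stops_removed = 0
    dropped_empty = 0
    with path.open(encoding="utf-8") as fh:
        for title, raw_seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: record with empty header")
            pid = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if pid in seen:
                raise IntegrityError(f"{path}: duplicate protein_id {pid!r}")
            seen.add(pid)
            seq = "".join(raw_seq.split()).upper()
            n_stops = seq.count("*")
            if n_stops:
                stops_removed += n_stops
                seq = seq.replace("*", "")
            if not seq:
                dropped_empty += 1
                continue
            records.append(ProteinRecord(pid, desc, seq))

    logger.info(
        "stage=read_proteome species=%s records=%d stops_removed=%d empty_dropped=%d",
        species, len(records), stops_removed, dropped_empty,
    )
    return Proteome(species, tuple(records))


def write_proteome_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write 60-column wrapped protein FASTA; read(write(p)) == p field-for-field."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in proteome.records:
            header = f">{rec.protein_id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
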