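"""Curated antihypertensive-peptide (AHTP) library: loading, validation,
top-N activity selection and descriptive statistics.

An AHTP here is a short peptide (dipeptide to ~11 residues) with verified
ACE-inhibitory activity, recorded as an IC50-style concentration in
micromolar — lower means more active. The screening panel is usually the
top 50 most active entries of the library.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import EmptyDatabaseError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

_MISSING_TOKENS = frozenset({"", "-", "NA", "N/A", "NONE", "NULL", "."})


@dataclass(frozen=True)
class AhtpPeptide:
    """One curated AHTP entry.

    ``activity`` is the inhibitory concentration in micromolar (IC50
    convention: lower = more active); ``source`` is the protein or food of
    origin. Both are optional.
    """

    peptide_id: str
    sequence: str
    activity: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"{self.peptide_id}: sequence shorter than 2 residues")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"{self.peptide_id}: non-canonical residue(s) {sorted(bad)} in "
                f"{self.sequence!r}"
            )
        if self.activity is not None and not self.activity > 0:
            raise ValueError(f"{self.peptide_id}: activity must be > 0")


@dataclass(frozen=True)
class RejectedRow:
    """A database row that failed validation, reported by file line number."""

    line: int
    reason: str


@dataclass(frozen=True)
class AhtpDatabase:
    """Ordered collection of :class:`AhtpPeptide` with unique ids.

    ``rejected`` carries the validation report from :func:`load_ahtp_db`
    (line numbers of dropped rows); it does not participate in equality.
    """

    entries: tuple[AhtpPeptide, ...]
    name: str = "ahtp-db"
    rejected: tuple[RejectedRow, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        ids = [e.peptide_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate peptide_id values: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AhtpPeptide]:
        return iter(self.entries)

    def unique_sequences(self) -> tuple[str, ...]:
        """Sequences for mapping: duplicates collapsed, first-seen order.

        Duplicate sequences across entries are kept as entries but collapse
        to one search pattern; hits are attributed to the sequence.
        """
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.sequence, None)
        return tuple(seen)


def _parse_activity(raw: Optional[str]) -> Optional[float]:
    if raw is None or raw.strip().upper() in _MISSING_TOKENS:
        return None
    return float(raw)


def load_ahtp_db(path: str | Path, fmt: str = "tsv") -> AhtpDatabase:
    """Load and validate an AHTP library from a TSV/CSV file.

    The file must have a header row with at least ``peptide_id`` and
    ``sequence`` columns; ``activity_um`` (micromolar) and ``source`` are
    optional. Sequences are uppercased before validation. Rows violating the
    peptide invariants are rejected and reported (with their 1-based file
    line numbers) on the returned database's ``rejected`` attribute and via
    the module logger.
    """
    path = Path(path)
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    delim = "\t" if fmt == "tsv" else ","
    if not path.exists():
        raise FileNotFoundError(path)

    entries: list[AhtpPeptide] = []
    rejected: list[RejectedRow] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        missing = {"peptide_id", "sequence"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        for row in reader:
            line = reader.line_num
            pid = (row.get("peptide_id") or "").strip()
            seq = (row.get("sequence") or "").strip().upper()
            try:
                if not pid:
                    raise ValueError("empty peptide_id")
                if pid in seen_ids:
                    raise ValueError(f"duplicate peptide_id {pid!r}")
                activity = _parse_activity(row.get("activity_um"))
                src = (row.get("source") or "").strip() or None
                entries.append(AhtpPeptide(pid, seq, activity, src))
                seen_ids.add(pid)
            except ValueError as exc:
                rejected.append(RejectedRow(line, str(exc)))
                logger.warning("%s line %d rejected: %s", path.name, line, exc)

    if not entries:
        raise EmptyDatabaseError(f"{path}: zero valid rows")
    logger.info(
        "stage=load_ahtp_db file=%s entries=%d rejected=%d",
        path.name, len(entries), len(rejected),
    )
    return AhtpDatabase(tuple(entries), name=path.stem, rejected=tuple(rejected))


def write_ahtp_db(db: AhtpDatabase, path: str | Path, fmt: str = "tsv") -> None:
    """Write the library back out in the same TSV/CSV dialect (round-trip safe)."""
    delim = "\t" if fmt == "tsv" else ","
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["peptide_id", "sequence", "activity_um", "source"])
        for e in db.entries:
            writer.writerow([
                e.peptide_id,
                e.sequence,
                "" if e.activity is None else repr(e.activity),
                e.source or "",
            ])


def load_reference_db() -> AhtpDatabase:
    """Load the packaged literature-style AHTP panel.

    This is a synthetic stand-in assembled from well-known ACE-inhibitory
    peptide sequences with plausible IC50-scale activities; it is a fixture
    for running the pipeline, not a curated ground-truth resource.
    """
    ref = resources.files("ahtpscreen.data") / "ahtp_reference_synthetic.tsv"
    with resources.as_file(ref) as p:
        return load_ahtp_db(p, "tsv")


def select_top_active(db: AhtpDatabase, n: int) -> AhtpDatabase:
    """Pick the ``n`` most active entries (lowest IC50) as the screening panel.

    Entries without an activity value are excluded before ranking. The result
    is ordered by ascending activity, ties broken by sequence lexicographic
    order. If fewer than ``n`` ranked entries exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = [e for e in db.entries if e.activity is not None]
    if not ranked:
        raise EmptyDatabaseError(
            "no entry carries an activity value; pass the panel explicitly "
            "instead of ranking by activity"
        )
    ranked.sort(key=lambda e: (e.activity, e.sequence))
    return AhtpDatabase(tuple(ranked[:n]), name=f"{db.name}-top{n}")


def length_distribution(db: AhtpDatabase | Iterable[AhtpPeptide]) -> dict[int, int]:
    """Peptide length histogram of the library (lengths with zero count omitted)."""
    counts = Counter(len(e.sequence) for e in db)
    return dict(sorted(counts.items()))


def write_length_distribution(dist: dict[int, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("length\tcount\n")
        for length, count in sorted(dist.items()):
            fh.write(f"{length}\t{count}\n")
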