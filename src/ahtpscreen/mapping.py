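"""In-situ mapping: exhaustive exact localization of panel peptides in proteomes.

Every occurrence of every panel peptide in every protein is reported —
including overlapping occurrences of one peptide and co-located occurrences
of different peptides — with 0-based half-open coordinates internally and
1-based inclusive coordinates in exported tables.

The main path is an Aho-Corasick automaton built over the panel with a
failure-resolved dense transition table, so each residue costs one state
transition regardless of panel size. ``naive_scan`` is the independent
correctness oracle: a per-peptide sliding-window comparison with no indexing
structure. The two are contract-equivalent by construction and verified
exhaustively in the test suite.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .ahtp_db import CANONICAL_AA
from .proteome_io import Proteome

logger = logging.getLogger(__name__)

_CANONICAL_SET = frozenset(CANONICAL_AA)


@dataclass(frozen=True, order=True)
class PeptideHit:
    """One localized occurrence: proteome[protein_id][start:end] == peptide_sequence.

    Coordinates are 0-based, end-exclusive.
    """

    protein_id: str
    start: int
    end: int
    peptide_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.end - self.start != len(self.peptide_sequence):
            raise ValueError("interval length does not match peptide length")


@dataclass(frozen=True)
class HitTable:
    """All occurrences for one species, ordered by (protein input order,
    start ascending, peptide sequence ascending)."""

    species: str
    hits: tuple[PeptideHit, ...]
    panel: frozenset[str]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[PeptideHit]:
        return iter(self.hits)


def _validate_panel(panel: Iterable[str]) -> tuple[str, ...]:
    patterns = tuple(dict.fromkeys(panel))  # dedupe, keep order
    if not patterns:
        raise ValueError("panel must contain at least one peptide")
    for p in patterns:
        if len(p) < 2:
            raise ValueError(f"panel peptide {p!r} shorter than 2 residues")
        bad = set(p) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"panel peptide {p!r} contains non-canonical residue(s) {sorted(bad)}"
            )
    return patterns


class AhoCorasick:
    """Multi-pattern exact matcher over the 20-letter amino-acid alphabet.

    Builds the classic trie + failure links, then flattens them into a dense
    per-state transition dict so scanning needs no failure chasing. Any
    character outside the canonical alphabet (ambiguity codes B/J/O/U/X/Z,
    etc.) resets the automaton to the root and thus breaks matches.
    """

    def __init__(self, patterns: Sequence[str]):
        self.patterns = tuple(patterns)
        # trie construction
        goto: list[dict[str, int]] = [{}]
        out: list[list[str]] = [[]]
        for pat in self.patterns:
            state = 0
            for ch in pat:
                nxt = goto[state].get(ch)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[state][ch] = nxt
                state = nxt
            out[state].append(pat)
        # BFS: failure links and merged outputs
        fail = [0] * len(goto)
        queue: deque[int] = deque(goto[0].values())
        while queue:
            state = queue.popleft()
            for ch, nxt in goto[state].items():
                f = fail[state]
                while f and ch not in goto[f]:
                    f = fail[f]
                cand = goto[f].get(ch, 0)
                fail[nxt] = cand if cand != nxt else 0
                out[nxt].extend(out[fail[nxt]])
                queue.append(nxt)
        self._trans = self._resolve_transitions(goto, fail)
        # emission table: (length, pattern) pairs, sorted for determinism
        self._out = [
            tuple(sorted((len(p), p) for p in pats)) for pats in out
        ]

    @staticmethod
    def _resolve_transitions(
        goto: list[dict[str, int]], fail: list[int]
    ) -> list[dict[str, int]]:
        trans: list[dict[str, int]] = [dict() for _ in goto]
        trans[0] = dict(goto[0])
        order: deque[int] = deque(goto[0].values())
        seen = set(goto[0].values())
        while order:
            state = order.popleft()
            merged = dict(trans[fail[state]])
            merged.update(goto[state])
            trans[state] = merged
            for s in goto[state].values():
                if s not in seen:
                    seen.add(s)
                    order.append(s)
        return trans

    def finditer(self, text: str) -> Iterator[tuple[int, int, str]]:
        """Yield (start, end, pattern) for every occurrence, by end position."""
        trans = self._trans
        out = self._out
        state = 0
        row = trans[0]
        for i, ch in enumerate(text):
            state = row.get(ch, 0)
            row = trans[state]
            if out[state]:
                end = i + 1
                for plen, pat in out[state]:
                    yield end - plen, end, pat


def map_peptides(proteome: Proteome, panel: Iterable[str]) -> HitTable:
    """Locate every occurrence of every panel peptide in every protein.

    Overlapping occurrences all count; each protein is scanned independently
    (no cross-record matches). Panel peptides must be canonical-alphabet
    and at least 2 residues long.
    """
    patterns = _validate_panel(panel)
    automaton = AhoCorasick(patterns)
    hits: list[PeptideHit] = []
    for rec in proteome:
        rec_hits = [
            PeptideHit(rec.protein_id, s, e, pat)
            for s, e, pat in automaton.finditer(rec.sequence)
        ]
        rec_hits.sort(key=lambda h: (h.start, h.peptide_sequence))
        hits.extend(rec_hits)
    logger.info(
        "stage=map_peptides species=%s proteins=%d panel=%d hits=%d",
        proteome.species, len(proteome), len(patterns), len(hits),
    )
    return HitTable(proteome.species, tuple(hits), frozenset(patterns))


def naive_scan(proteome: Proteome, panel: Iterable[str]) -> HitTable:
    """Reference oracle: per-peptide sliding-window scan, no indexing structure.

    Identical contract to :func:`map_peptides`; exists solely so the main
    path can be verified against an implementation too simple to be wrong.
    """
    patterns = _validate_panel(panel)
    hits: list[PeptideHit] = []
    for rec in proteome:
        seq = rec.sequence
        rec_hits: list[PeptideHit] = []
        for pat in patterns:
            k = len(pat)
            for i in range(len(seq) - k + 1):
                if seq.startswith(pat, i):
                    rec_hits.append(PeptideHit(rec.protein_id, i, i + k, pat))
        rec_hits.sort(key=lambda h: (h.start, h.peptide_sequence))
        hits.extend(rec_hits)
    return HitTable(proteome.species, tuple(hits), frozenset(patterns))


def write_hits_tsv(table: HitTable, path: str | Path, bed_style: bool = False) -> None:
    """Export hits as TSV.

    Default columns are 1-based inclusive (start_1based, end_1based);
    ``bed_style=True`` writes 0-based half-open (start_0based, end_0based)
    instead. The coordinate convention is stated in a leading comment line.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        if bed_style:
            fh.write("# coordinates: 0-based, end-exclusive (BED-like)\n")
            fh.write("species\tpeptide\tprotein_id\tstart_0based\tend_0based\n")
            for h in table.hits:
                fh.write(
                    f"{table.species}\t{h.peptide_sequence}\t{h.protein_id}\t"
                    f"{h.start}\t{h.end}\n"
                )
        else:
            fh.write("# coordinates: 1-based, start and end inclusive\n")
            fh.write("species\tpeptide\tprotein_id\tstart_1based\tend_1based\n")
            for h in table.hits:
                fh.write(
                    f"{table.species}\t{h.peptide_sequence}\t{h.protein_id}\t"
                    f"{h.start + 1}\t{h.end}\n"
                )


def read_hits_tsv(path: str | Path) -> HitTable:
    """Read a hit table written by :func:`write_hits_tsv` (either convention)."""
    species = ""
    hits: list[PeptideHit] = []
    panel: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no header row")
    header = lines[0].split("\t")
    zero_based = "start_0based" in header
    for ln in lines[1:]:
        if not ln:
            continue
        sp, pep, pid, s, e = ln.split("\t")
        species = sp
        start = int(s) if zero_based else int(s) - 1
        hits.append(PeptideHit(pid, start, int(e), pep))
        panel.add(pep)
    return HitTable(species, tuple(hits), frozenset(panel))
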