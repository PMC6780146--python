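"""Per-species and cross-species statistics of the AHTP screen.

Produces, for each species: total hits, mapped-protein count, mapping rate
(mapped/total), average hits per mapped protein, the per-peptide hit
spectrum, collagen-subunit counts among mapped proteins, and a ranking of
proteins by hit abundance. Ratios are carried at full precision and rounded
half-away-from-zero to a fixed number of decimals (default 4) only at
report time.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import IntegrityError
from .mapping import HitTable
from .proteome_io import Proteome

UNANNOTATED_KEY = "unannotated"

#: Row labels of the cross-species summary table, in print order.
SUMMARY_ROWS = (
    "Total hits",
    "Mapped protein",
    "Total protein",
    "Mapping rate",
    "Average AHTPs number in mapped protein",
    "Collagen subunit number in mapped protein",
)


def report_round(value: float, decimals: int = 4) -> float:
    """Round half-away-from-zero to ``decimals`` places (report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def mapping_rate(mapped: int, total: int) -> float:
    """Mapped proteins over total proteins; 0 for an empty proteome."""
    return mapped / total if total else 0.0


def average_hits(total_hits: int, mapped: int) -> float:
    """Total occurrences over mapped proteins; 0 when nothing mapped."""
    return total_hits / mapped if mapped else 0.0


@dataclass(frozen=True)
class SpeciesSummary:
    """The per-species summary row set of the screen."""

    species: str
    total_hits: int
    mapped_protein_count: int
    total_protein_count: int
    distinct_peptides_found: int
    per_peptide_counts: dict[str, int]
    collagen_mapped_count: int

    @property
    def mapping_rate(self) -> float:
        return mapping_rate(self.mapped_protein_count, self.total_protein_count)

    @property
    def avg_hits_per_mapped(self) -> float:
        return average_hits(self.total_hits, self.mapped_protein_count)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "total_hits": self.total_hits,
            "mapped_protein_count": self.mapped_protein_count,
            "total_protein_count": self.total_protein_count,
            "distinct_peptides_found": self.distinct_peptides_found,
            "per_peptide_counts": self.per_peptide_counts,
            "collagen_mapped_count": self.collagen_mapped_count,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciesSummary":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)


@dataclass(frozen=True)
class ProteinHitSummary:
    protein_id: str
    description: str
    hit_count: int
    distinct_peptides: int
    is_collagen: bool


def _check_hits_resolve(hit_table: HitTable, proteome: Proteome) -> None:
    orphans = {h.protein_id for h in hit_table if proteome.get(h.protein_id) is None}
    if orphans:
        raise IntegrityError(
            f"hits reference protein id(s) absent from proteome: {sorted(orphans)[:5]}"
        )


def is_collagen_description(description: str, token: str = "collagen") -> bool:
    """Collagen rule: case-insensitive substring match of ``token``."""
    return token.lower() in description.lower()


def count_collagen(
    proteome: Proteome, mapped_ids: Iterable[str], token: str = "collagen"
) -> int:
    """Number of mapped proteins whose description satisfies the collagen rule."""
    idset = set(mapped_ids)
    return sum(
        1
        for rec in proteome
        if rec.protein_id in idset and is_collagen_description(rec.description, token)
    )


def summarize_species(
    hit_table: HitTable, proteome: Proteome, collagen_token: str = "collagen"
) -> SpeciesSummary:
    """Compute the full summary for one species from its hit table."""
    _check_hits_resolve(hit_table, proteome)
    per_peptide = Counter(h.peptide_sequence for h in hit_table)
    mapped_ids = {h.protein_id for h in hit_table}
    return SpeciesSummary(
        species=hit_table.species,
        total_hits=len(hit_table),
        mapped_protein_count=len(mapped_ids),
        total_protein_count=proteome.total_protein_count,
        distinct_peptides_found=len(per_peptide),
        per_peptide_counts=dict(sorted(per_peptide.items())),
        collagen_mapped_count=count_collagen(proteome, mapped_ids, collagen_token),
    )


def rank_proteins(
    hit_table: HitTable,
    proteome: Proteome,
    n: int,
    collagen_token: str = "collagen",
) -> list[ProteinHitSummary]:
    """Top-``n`` mapped proteins by hit count (ties by protein_id ascending).

    Only proteins with at least one hit appear, so the result is shorter
    than ``n`` when fewer proteins are mapped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_hits_resolve(hit_table, proteome)
    counts: Counter[str] = Counter()
    peptides: dict[str, set[str]] = {}
    for h in hit_table:
        counts[h.protein_id] += 1
        peptides.setdefault(h.protein_id, set()).add(h.peptide_sequence)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    out = []
    for pid, c in ranked:
        rec = proteome.get(pid)
        assert rec is not None
        out.append(
            ProteinHitSummary(
                protein_id=pid,
                description=rec.description,
                hit_count=c,
                distinct_peptides=len(peptides[pid]),
                is_collagen=is_collagen_description(rec.description, collagen_token),
            )
        )
    return out


def top_n_peptides(summary: SpeciesSummary, n: int) -> list[str]:
    """The ``n`` most abundant peptides (count descending, ties lexicographic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(summary.per_peptide_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pep for pep, _ in ranked[:n]]


@dataclass(frozen=True)
class ComparisonTables:
    """Cross-species comparison: the summary-statistic table (statistics as
    rows, species as columns) and the peptide-by-species hit-count matrix."""

    summary: pd.DataFrame
    peptide_matrix: pd.DataFrame


def compare_species(
    summaries: Sequence[SpeciesSummary],
    annotated_counts: Optional[Mapping[str, int]] = None,
    decimals: int = 4,
) -> ComparisonTables:
    """Assemble the cross-species tables from per-species summaries.

    The peptide matrix is the union of peptide sets across species,
    zero-filled where a peptide was not found. ``annotated_counts`` (species
    -> number of annotated mapped proteins, from a user-supplied annotation
    table) adds an "Annotated protein number" row when given. Ratio rows are
    rounded at ``decimals`` places, half-away-from-zero.
    """
    if not summaries:
        raise ValueError("at least one species summary required")
    species = [s.species for s in summaries]
    if len(species) != len(set(species)):
        raise ValueError(f"duplicate species labels in {species}")

    rows: dict[str, list] = {
        "Total hits": [s.total_hits for s in summaries],
        "Mapped protein": [s.mapped_protein_count for s in summaries],
        "Total protein": [s.total_protein_count for s in summaries],
        "Mapping rate": [report_round(s.mapping_rate, decimals) for s in summaries],
        "Average AHTPs number in mapped protein": [
            report_round(s.avg_hits_per_mapped, decimals) for s in summaries
        ],
        "Collagen subunit number in mapped protein": [
            s.collagen_mapped_count for s in summaries
        ],
    }
    index = list(SUMMARY_ROWS)
    if annotated_counts is not None:
        rows["Annotated protein number"] = [
            annotated_counts.get(s.species, 0) for s in summaries
        ]
        index.insert(3, "Annotated protein number")
    # object dtype keeps count rows integer next to the float ratio rows
    summary_df = pd.DataFrame(
        {s: [rows[label][i] for label in index] for i, s in enumerate(species)},
        index=index,
        dtype=object,
    )
    summary_df.index.name = "statistic"
    summary_df.columns.name = "species"

    all_peptides = sorted(set().union(*(s.per_peptide_counts for s in summaries)))
    matrix = pd.DataFrame(
        {s.species: [s.per_peptide_counts.get(p, 0) for p in all_peptides] for s in summaries},
        index=all_peptides,
        dtype=int,
    )
    matrix.index.name = "peptide"
    matrix.columns.name = "species"
    return ComparisonTables(summary=summary_df, peptide_matrix=matrix)


def annotate_mapped(
    mapped_ids: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> dict[str, int]:
    """Tally mapped proteins per functional category.

    Each mapped protein contributes one count to each of its categories;
    mapped proteins absent from the annotation are counted under the
    reserved ``unannotated`` key (always present, possibly 0).
    """
    counts: Counter[str] = Counter()
    unannotated = 0
    for pid in set(mapped_ids):
        cats = set(annotation.get(pid, ()))
        cats.discard(UNANNOTATED_KEY)
        if cats:
            counts.update(cats)
        else:
            unannotated += 1
    result = dict(sorted(counts.items()))
    result[UNANNOTATED_KEY] = unannotated
    return result


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read a protein_id -> category-terms table (TSV, two columns; multiple
    terms separated by ';' or repeated rows)."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if "\t" not in header:
            raise ValueError(f"{path}: expected two tab-separated columns")
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            pid, terms = ln.split("\t", 1)
            mapping.setdefault(pid, set()).update(
                t.strip() for t in terms.split(";") if t.strip()
            )
    return mapping
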