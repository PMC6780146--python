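"""Synthetic proteomes with oracle-finalized planted ground truth.

Generates protein sets with a truncated log-normal length distribution and
i.i.d. residues from configurable background frequencies, then overwrites
non-overlapping windows with planted peptide copies at known coordinates.
Because planting can create incidental new occurrences at window
boundaries, the ground truth is always finalized by running the naive
sliding-window oracle over the final sequences — never assumed from the
plant plan — so ``per_peptide_totals`` is exactly what the mapper must
report.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .ahtp_db import CANONICAL_AA
from .errors import GenerationError
from .mapping import PeptideHit, naive_scan
from .proteome_io import ProteinRecord, Proteome

logger = logging.getLogger(__name__)

#: Description applied to collagen-flagged synthetic records.
COLLAGEN_DESCRIPTION = "collagen type IV alpha 5"
_OTHER_DESCRIPTION = "hypothetical protein"

_MAX_PLANT_ATTEMPTS = 200


def uniform_background() -> dict[str, float]:
    """Uniform frequencies over the 20 canonical residues (analytically
    tractable: a length-k peptide is expected (L-k+1)/20**k times per
    length-L protein)."""
    return {aa: 1.0 / 20.0 for aa in CANONICAL_AA}


def vertebrate_background() -> dict[str, float]:
    """Vertebrate-like residue frequencies (SwissProt-style composition)."""
    freqs = {
        "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
        "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
        "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
        "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
    }
    total = sum(freqs.values())
    return {aa: f / total for aa, f in freqs.items()}


@dataclass(frozen=True)
class PlantDirective:
    """Plant ``copies`` occurrences of ``peptide``; ``protein_fraction``
    restricts the eligible target proteins to a random subset of that size
    (None = all proteins eligible)."""

    peptide: str
    copies: int
    protein_fraction: Optional[float] = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic proteome.

    ``length_loc``/``length_scale`` are the log-normal location and scale of
    protein lengths (residues), truncated by rejection to
    [``min_length``, ``max_length``]. Defaults give a median length around
    330 residues with a realistic right tail.
    """

    n_proteins: int
    length_loc: float = 5.8
    length_scale: float = 0.7
    min_length: int = 20
    max_length: int = 50_000
    background_freqs: dict[str, float] = field(default_factory=uniform_background)
    plant_plan: tuple[PlantDirective, ...] = ()
    collagen_fraction: float = 0.0
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 20 <= self.min_length <= self.max_length:
            raise ValueError("need 20 <= min_length <= max_length")
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise ValueError("collagen_fraction must be in [0, 1]")
        bad = set(self.background_freqs) - set(CANONICAL_AA)
        if bad:
            raise ValueError(f"non-canonical residues in background_freqs: {sorted(bad)}")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total!r}, not 1")
        for d in self.plant_plan:
            if len(d.peptide) < 2 or set(d.peptide) - set(CANONICAL_AA):
                raise ValueError(f"invalid plant peptide {d.peptide!r}")
            if d.copies < 0:
                raise ValueError("plant copies must be >= 0")
            if d.protein_fraction is not None and not 0.0 < d.protein_fraction <= 1.0:
                raise ValueError("protein_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        plan = tuple(
            PlantDirective(
                peptide=d["peptide"],
                copies=int(d["copies"]),
                protein_fraction=d.get("protein_fraction"),
            )
            for d in raw.pop("plant_plan", [])
        )
        return cls(plant_plan=plan, **raw)


@dataclass(frozen=True)
class GroundTruth:
    """Oracle-finalized truth for one synthetic proteome.

    ``planted_hits`` are the deliberately written copies;
    ``background_hits`` are all other occurrences of the planted peptides in
    the final sequences (found by the naive oracle); ``per_peptide_totals``
    is their peptide-wise sum and equals what the mapper must report.
    """

    planted_hits: tuple[PeptideHit, ...]
    background_hits: tuple[PeptideHit, ...]

    @property
    def per_peptide_totals(self) -> dict[str, int]:
        totals: Counter[str] = Counter()
        for h in self.planted_hits:
            totals[h.peptide_sequence] += 1
        for h in self.background_hits:
            totals[h.peptide_sequence] += 1
        return dict(sorted(totals.items()))


def _sample_lengths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated log-normal lengths by rejection sampling."""
    out = np.empty(spec.n_proteins, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        need = spec.n_proteins - filled
        if need == 0:
            break
        draw = np.rint(rng.lognormal(spec.length_loc, spec.length_scale, need)).astype(
            np.int64
        )
        ok = draw[(draw >= spec.min_length) & (draw <= spec.max_length)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    if filled < spec.n_proteins:
        raise GenerationError("length model rejects almost all draws; widen bounds")
    return out


def _overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def generate_proteome(spec: SyntheticSpec) -> tuple[Proteome, GroundTruth]:
    """Generate a proteome and its oracle-finalized ground truth.

    Deterministic given ``spec.seed``. Raises :class:`GenerationError` when a
    peptide cannot be placed (longer than every eligible protein, or the
    non-overlap demand is infeasible).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _sample_lengths(spec, rng)

    letters = sorted(spec.background_freqs)
    probs = np.array([spec.background_freqs[a] for a in letters])
    probs = probs / probs.sum()
    alphabet = np.frombuffer("".join(letters).encode(), dtype=np.uint8)
    total = int(lengths.sum())
    residues = alphabet[rng.choice(len(letters), size=total, p=probs)]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    seqs = [bytearray(residues[bounds[i] : bounds[i + 1]]) for i in range(spec.n_proteins)]

    n_collagen = math.floor(spec.collagen_fraction * spec.n_proteins)
    collagen_idx = set(
        rng.choice(spec.n_proteins, size=n_collagen, replace=False).tolist()
    )

    planted: list[PeptideHit] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    ids = [f"SYNP{i:05d}" for i in range(spec.n_proteins)]
    for directive in spec.plant_plan:
        pep = directive.peptide.encode()
        k = len(pep)
        if directive.protein_fraction is None:
            eligible = np.arange(spec.n_proteins)
        else:
            n_eligible = max(1, math.ceil(directive.protein_fraction * spec.n_proteins))
            eligible = rng.choice(spec.n_proteins, size=n_eligible, replace=False)
        eligible = eligible[lengths[eligible] >= k]
        if len(eligible) == 0:
            raise GenerationError(
                f"peptide {directive.peptide!r} longer than every eligible protein"
            )
        for _ in range(directive.copies):
            for _attempt in range(_MAX_PLANT_ATTEMPTS):
                pidx = int(eligible[rng.integers(len(eligible))])
                offset = int(rng.integers(lengths[pidx] - k + 1))
                if not _overlaps(occupied.get(pidx, []), offset, offset + k):
                    break
            else:
                raise GenerationError(
                    f"could not place all {directive.copies} copies of "
                    f"{directive.peptide!r} without overlap"
                )
            seqs[pidx][offset : offset + k] = pep
            occupied.setdefault(pidx, []).append((offset, offset + k))
            planted.append(
                PeptideHit(ids[pidx], offset, offset + k, directive.peptide)
            )

    records = tuple(
        ProteinRecord(
            ids[i],
            COLLAGEN_DESCRIPTION if i in collagen_idx else _OTHER_DESCRIPTION,
            seqs[i].decode(),
        )
        for i in range(spec.n_proteins)
    )
    proteome = Proteome(spec.species, records)

    background: tuple[PeptideHit, ...] = ()
    if spec.plant_plan:
        panel = {d.peptide for d in spec.plant_plan}
        planted_set = set(planted)
        scan = naive_scan(proteome, panel)
        background = tuple(h for h in scan if h not in planted_set)
    truth = GroundTruth(tuple(sorted(planted)), tuple(sorted(background)))
    logger.info(
        "stage=generate_proteome species=%s proteins=%d residues=%d planted=%d background=%d",
        spec.species, spec.n_proteins, total, len(planted), len(background),
    )
    return proteome, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as TSV (1-based inclusive coordinates).

    Per-peptide totals are the peptide-wise row counts, so the file
    round-trips losslessly through :func:`read_truth`.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("peptide\tprotein_id\tstart_1based\tend_1based\torigin\n")
        for origin, hits in (("planted", truth.planted_hits), ("background", truth.background_hits)):
            for h in hits:
                fh.write(
                    f"{h.peptide_sequence}\t{h.protein_id}\t{h.start + 1}\t{h.end}\t{origin}\n"
                )


def read_truth(path: str | Path) -> GroundTruth:
    planted: list[PeptideHit] = []
    background: list[PeptideHit] = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["peptide", "protein_id", "start_1based", "end_1based", "origin"]:
            raise ValueError(f"{path}: unexpected truth-file header {header}")
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            pep, pid, s, e, origin = ln.split("\t")
            hit = PeptideHit(pid, int(s) - 1, int(e), pep)
            (planted if origin == "planted" else background).append(hit)
    return GroundTruth(tuple(sorted(planted)), tuple(sorted(background)))
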