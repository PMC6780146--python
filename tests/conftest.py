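import textwrap
from pathlib import Path

import pytest

from ahtpscreen.proteome_io import ProteinRecord, Proteome


@pytest.fixture
def tiny_proteome() -> Proteome:
    return Proteome(
        "tiny",
        (
            ProteinRecord("p1", "titin", "AGLPGLPX"),
            ProteinRecord("p2", "collagen type IV alpha 5", "GLPGLP"),
            ProteinRecord("p3", "hypothetical protein", "MKVSVQQQ"),
        ),
    )


@pytest.fixture
def db_file(tmp_path: Path):
    """Write an AHTP database TSV from (id, seq, activity, source) rows."""

    def _write(rows, name="db.tsv"):
        lines = ["peptide_id\tsequence\tactivity_um\tsource"]
        for r in rows:
            lines.append("\t".join("" if v is None else str(v) for v in r))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def fasta_file(tmp_path: Path):
    def _write(text, name="prot.faa"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).lstrip("\n"), encoding="utf-8")
        return path

    return _write
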