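"""Per-species summaries, protein ranking, collagen counts, comparisons."""

import random
from collections import Counter
from fractions import Fraction

import pytest

from ahtpscreen import (
    annotate_mapped,
    compare_species,
    count_collagen,
    map_peptides,
    rank_proteins,
    report_round,
    summarize_species,
    top_n_peptides,
)
from ahtpscreen.errors import IntegrityError
from ahtpscreen.mapping import HitTable, PeptideHit
from ahtpscreen.proteome_io import ProteinRecord, Proteome
from ahtpscreen.species_stats import (
    SpeciesSummary,
    average_hits,
    mapping_rate,
)


def _table(species, hits, panel):
    return HitTable(species, tuple(hits), frozenset(panel))


@pytest.fixture
def three_protein_case():
    prot = Proteome(
        "x",
        (
            ProteinRecord("p1", "titin", "AGLPGLPA"),
            ProteinRecord("p2", "collagen alpha-1(VIII) chain", "LGPAAA"),
            ProteinRecord("p3", "hypothetical protein", "MMMM"),
        ),
    )
    hits = _table(
        "x",
        [
            PeptideHit("p1", 1, 4, "GLP"),
            PeptideHit("p1", 4, 7, "GLP"),
            PeptideHit("p2", 0, 3, "LGP"),
        ],
        {"GLP", "LGP", "VSV"},
    )
    return prot, hits


class TestSummarize:
    def test_hand_counts(self, three_protein_case):
        prot, hits = three_protein_case
        s = summarize_species(hits, prot)
        assert s.total_hits == 3
        assert s.mapped_protein_count == 2
        assert s.total_protein_count == 3
        assert s.mapping_rate == pytest.approx(2 / 3)
        assert s.avg_hits_per_mapped == pytest.approx(1.5)
        assert s.per_peptide_counts == {"GLP": 2, "LGP": 1}
        assert s.distinct_peptides_found == 2
        assert s.collagen_mapped_count == 1

    def test_empty_hit_table_is_degenerate_but_total(self):
        prot = Proteome(
            "x", tuple(ProteinRecord(f"p{i}", "", "MMMM") for i in range(10))
        )
        s = summarize_species(_table("x", [], {"GLP"}), prot)
        assert (s.total_hits, s.mapped_protein_count) == (0, 0)
        assert s.mapping_rate == 0.0
        assert s.avg_hits_per_mapped == 0.0

    def test_orphan_hit_is_integrity_error(self, three_protein_case):
        prot, _ = three_protein_case
        bad = _table("x", [PeptideHit("ghost", 0, 3, "GLP")], {"GLP"})
        with pytest.raises(IntegrityError, match="ghost"):
            summarize_species(bad, prot)

    def test_invariants_on_random_mapping(self):
        rng = random.Random(5)
        prot = Proteome(
            "r",
            tuple(
                ProteinRecord(
                    f"p{i}", "", "".join(rng.choice("ACDG") for _ in range(80))
                )
                for i in range(30)
            ),
        )
        panel = {"AC", "CD", "GAC", "DG"}
        s = summarize_species(map_peptides(prot, panel), prot)
        assert sum(s.per_peptide_counts.values()) == s.total_hits
        assert s.mapped_protein_count <= s.total_protein_count
        assert s.distinct_peptides_found <= len(panel)
        if s.mapped_protein_count:
            assert s.avg_hits_per_mapped >= 1
        # rate * total == mapped exactly, checked in rational arithmetic
        assert (
            Fraction(s.mapped_protein_count, s.total_protein_count)
            * s.total_protein_count
            == s.mapped_protein_count
        )


class TestReportedRatios:
    """The printed whole-proteome screen statistics are reproducible from the
    integer counts through the ratio + rounding logic alone."""

    def test_white_dolphin_row(self):
        assert report_round(mapping_rate(11323, 18387)) == 0.6158
        assert report_round(average_hits(27260, 11323)) == 2.4075

    def test_rounding_is_half_away_from_zero(self):
        assert report_round(0.61585, 4) == 0.6159
        assert report_round(2.30495, 4) == 2.3050
        assert report_round(-0.00005, 4) == -0.0001


class TestRankProteins:
    def test_tie_broken_by_protein_id(self, three_protein_case):
        prot, _ = three_protein_case
        hits = _table(
            "x",
            [PeptideHit("p2", 0, 3, "LGP")] * 0
            + [
                PeptideHit("p1", 1, 4, "GLP"),
                PeptideHit("p1", 4, 7, "GLP"),
                PeptideHit("p2", 0, 3, "LGP"),
                PeptideHit("p2", 3, 5, "AA"),
            ],
            {"GLP", "LGP", "AA"},
        )
        top = rank_proteins(hits, prot, 2)
        assert [p.protein_id for p in top] == ["p1", "p2"]
        assert top[1].is_collagen is True

    def test_never_returns_unmapped_proteins(self, three_protein_case):
        prot, hits = three_protein_case
        top = rank_proteins(hits, prot, 100)
        assert {p.protein_id for p in top} == {"p1", "p2"}

    def test_matches_full_sort_oracle(self):
        rng = random.Random(11)
        prot = Proteome(
            "r",
            tuple(
                ProteinRecord(f"p{i:02d}", "", "".join(rng.choice("AC") for _ in range(40)))
                for i in range(20)
            ),
        )
        hits = map_peptides(prot, {"AC", "CA"})
        got = [(p.protein_id, p.hit_count) for p in rank_proteins(hits, prot, 5)]
        counts = Counter(h.protein_id for h in hits)
        oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        assert got == oracle
        for p in rank_proteins(hits, prot, 5):
            assert p.distinct_peptides <= p.hit_count


class TestCountCollagen:
    def test_rule_application(self):
        prot = Proteome(
            "x",
            (
                ProteinRecord("p1", "collagen type IV alpha 5", "MM"),
                ProteinRecord("p2", "titin", "MM"),
                ProteinRecord("p3", "Collagen alpha-1(VIII) chain", "MM"),
            ),
        )
        assert count_collagen(prot, {"p1", "p2", "p3"}) == 2
        assert count_collagen(prot, {"p2"}) == 0

    def test_constructed_48_collagen_proteome(self):
        records = [
            ProteinRecord(f"c{i}", "collagen type IV alpha 5", "GLPGLP")
            for i in range(48)
        ] + [ProteinRecord(f"n{i}", "keratin", "GLPGLP") for i in range(30)]
        prot = Proteome("x", tuple(records))
        mapped = {r.protein_id for r in records}
        assert count_collagen(prot, mapped) == 48


class TestTopPeptides:
    def _summary(self, counts):
        return SpeciesSummary(
            species="x",
            total_hits=sum(counts.values()),
            mapped_protein_count=1,
            total_protein_count=1,
            distinct_peptides_found=len(counts),
            per_peptide_counts=counts,
            collagen_mapped_count=0,
        )

    def test_tie_rule(self):
        s = self._summary({"GLP": 10, "LGP": 10, "VSV": 5})
        assert top_n_peptides(s, 2) == ["GLP", "LGP"]

    def test_n_larger_than_distinct(self):
        s = self._summary({"GLP": 3, "LGP": 2, "VSV": 1, "AW": 1, "VY": 1})
        assert len(top_n_peptides(s, 8)) == 5

    def test_matches_sort_oracle(self):
        rng = random.Random(3)
        counts = {f"PEP{i}": rng.randint(1, 40) for i in range(25)}
        got = top_n_peptides(self._summary(counts), 8)
        oracle = [p for p, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))][:8]
        assert got == oracle


class TestCompareSpecies:
    def _species(self, seed, label):
        rng = random.Random(seed)
        prot = Proteome(
            label,
            tuple(
                ProteinRecord(f"{label}{i}", "", "".join(rng.choice("ACDG") for _ in range(60)))
                for i in range(15)
            ),
        )
        hits = map_peptides(prot, {"AC", "GA", "CDG"})
        return summarize_species(hits, prot)

    def test_single_species_column_consistent(self):
        s = self._species(1, "a")
        tables = compare_species([s])
        col = tables.summary["a"]
        assert col["Total hits"] == s.total_hits
        assert col["Mapping rate"] == report_round(s.mapping_rate)

    def test_zero_fill_for_absent_peptides(self):
        s1 = summarize_species(
            _table("a", [PeptideHit("p1", 0, 3, "VSV")], {"VSV"}),
            Proteome("a", (ProteinRecord("p1", "", "VSVM"),)),
        )
        s2 = summarize_species(
            _table("b", [PeptideHit("q1", 0, 3, "GLP")], {"GLP", "VSV"}),
            Proteome("b", (ProteinRecord("q1", "", "GLPM"),)),
        )
        m = compare_species([s1, s2]).peptide_matrix
        assert m.loc["VSV", "b"] == 0
        assert m.loc["GLP", "a"] == 0

    def test_five_species_columns_match_independent_summaries(self):
        summaries = [self._species(i, f"sp{i}") for i in range(5)]
        tables = compare_species(summaries)
        assert list(tables.summary.columns) == [s.species for s in summaries]
        for s in summaries:
            col = tables.summary[s.species]
            assert col["Total hits"] == s.total_hits
            assert col["Mapped protein"] == s.mapped_protein_count
            assert col["Total protein"] == s.total_protein_count
            assert col["Collagen subunit number in mapped protein"] == s.collagen_mapped_count
            # matrix column sums equal total hits
            assert tables.peptide_matrix[s.species].sum() == s.total_hits

    def test_duplicate_labels_rejected(self):
        s = self._species(1, "a")
        with pytest.raises(ValueError, match="duplicate"):
            compare_species([s, s])

    def test_annotated_counts_row_optional(self):
        s = self._species(1, "a")
        t = compare_species([s], annotated_counts={"a": 7})
        assert t.summary.loc["Annotated protein number", "a"] == 7
        assert "Annotated protein number" not in compare_species([s]).summary.index


class TestAnnotateMapped:
    def test_counting_rule(self):
        counts = annotate_mapped(
            {"p1", "p2"},
            {"p1": {"binding"}, "p2": {"binding", "catalytic activity"}},
        )
        assert counts == {"binding": 2, "catalytic activity": 1, "unannotated": 0}

    def test_empty_annotation(self):
        assert annotate_mapped({"p1", "p2"}, {}) == {"unannotated": 2}

    def test_matches_brute_force_tally(self):
        rng = random.Random(21)
        cats = ["binding", "catalytic", "transport", "structural"]
        mapped = {f"p{i}" for i in range(40)}
        annotation = {
            f"p{i}": set(rng.sample(cats, rng.randint(1, 3)))
            for i in range(40)
            if rng.random() < 0.7
        }
        got = annotate_mapped(mapped, annotation)
        brute = Counter()
        un = 0
        for pid in mapped:
            if pid in annotation:
                brute.update(annotation[pid])
            else:
                un += 1
        assert got == {**dict(brute), "unannotated": un}
        # multiplicity conservation
        assert sum(v for k, v in got.items() if k != "unannotated") == sum(
            len(v) for v in annotation.values()
        )
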