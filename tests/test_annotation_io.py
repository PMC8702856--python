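"""Overview parsing, consensus filtering and genome-table summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cazytyping import annotation_io as aio

HEADER = "Gene ID\tHMMER\tHotpep\tDIAMOND\t#ofTools"


def make_lines(*rows):
    return [HEADER, *rows]


class TestParseOverview:
    def test_two_tool_line(self):
        recs = aio.parse_overview(make_lines("g1\t-\tGH13(5)\tGH13\t2"))
        (rec,) = recs
        assert rec.gene_id == "g1"
        assert rec.tool_calls["HMMER"] == frozenset()
        assert rec.tool_calls["Hotpep"] == {"GH13"}
        assert rec.tool_calls["DIAMOND"] == {"GH13"}
        assert rec.n_tools == 2

    def test_single_tool_line(self):
        (rec,) = aio.parse_overview(make_lines("g2\t-\t-\tGT2\t1"))
        assert rec.tool_calls["DIAMOND"] == {"GT2"}
        assert rec.n_tools == 1

    def test_multidomain_split_on_plus(self):
        (rec,) = aio.parse_overview(
            make_lines("g3\t-\tGH5_4+CBM6\tGH5_4+CBM6\t2")
        )
        assert rec.tool_calls["Hotpep"] == {"GH5_4", "CBM6"}
        assert rec.tool_calls["DIAMOND"] == {"GH5_4", "CBM6"}

    def test_pipe_separator_and_annotations(self):
        (rec,) = aio.parse_overview(
            make_lines("g4\tGH3(120-450)|GH5(1-100)\t-\t-\t1")
        )
        assert rec.tool_calls["HMMER"] == {"GH3", "GH5"}

    def test_malformed_line_names_line_number(self):
        with pytest.raises(aio.OverviewParseError, match="line 3"):
            aio.parse_overview(make_lines("g1\t-\t-\tGT2\t1", "broken\tonly"))

    def test_empty_input_returns_empty_list(self, caplog):
        with caplog.at_level("WARNING"):
            assert aio.parse_overview([]) == []
        assert "empty" in caplog.text


class TestConsensusFilter:
    def rec(self, gene="g", hotpep=(), diamond=(), hmmer=()):
        return aio.OverviewRecord(
            gene_id=gene,
            tool_calls={
                "HMMER": frozenset(hmmer),
                "Hotpep": frozenset(hotpep),
                "DIAMOND": frozenset(diamond),
            },
        )

    def test_single_tool_gene_excluded(self):
        assert aio.consensus_filter([self.rec(diamond={"GT2"})]) == []

    def test_agreeing_gene_kept_with_intersection(self):
        out = aio.consensus_filter([self.rec(hotpep={"GH13"}, diamond={"GH13"})])
        assert out == [("g", frozenset({"GH13"}))]

    def test_disagreement_falls_back_to_union(self, caplog):
        with caplog.at_level("INFO"):
            out = aio.consensus_filter(
                [self.rec(hotpep={"GH13"}, diamond={"GH31"})]
            )
        assert out == [("g", frozenset({"GH13", "GH31"}))]
        assert "disagreement" in caplog.text

    def test_hmmer_not_consulted_by_default(self):
        rec = self.rec(hmmer={"GH1"}, diamond={"GH1"})
        assert aio.consensus_filter([rec]) == []
        assert aio.consensus_filter([rec], tools=aio.OVERVIEW_TOOLS) == [
            ("g", frozenset({"GH1"}))
        ]

    def test_min_tools_one_retains_every_called_gene(self):
        recs = [
            self.rec("a", hotpep={"GH1"}),
            self.rec("b", diamond={"GT2"}),
            self.rec("c"),
        ]
        kept = aio.consensus_filter(recs, min_tools=1)
        assert [g for g, _ in kept] == ["a", "b"]

    @given(
        st.lists(
            st.tuples(
                st.sets(st.sampled_from(["GH1", "GH2", "GT2", "PL9"]), max_size=3),
                st.sets(st.sampled_from(["GH1", "GH2", "GT2", "PL9"]), max_size=3),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_filter_monotone_in_min_tools(self, call_pairs):
        """Lowering min_tools never removes a retained gene."""
        recs = [
            self.rec(f"g{i}", hotpep=h, diamond=d)
            for i, (h, d) in enumerate(call_pairs)
        ]
        kept2 = {g for g, _ in aio.consensus_filter(recs, min_tools=2)}
        kept1 = {g for g, _ in aio.consensus_filter(recs, min_tools=1)}
        assert kept2 <= kept1


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, family, cls",
        [
            ("GH13_18", "GH13", "GH"),
            ("CBM6", "CBM6", "CBM"),
            ("GT2_Glyco_tranf_2_3", "GT2", "GT"),
            ("AA10", "AA10", "AA"),
        ],
    )
    def test_suffix_stripping(self, raw, family, cls):
        fam = aio.canonicalize_family(raw)
        assert fam.family_id == family
        assert fam.cazy_class == cls

    def test_unknown_prefix_rejected(self):
        with pytest.raises(aio.UnknownFamilyError, match="XY9"):
            aio.canonicalize_family("XY9")


TAXONOMY = pd.DataFrame(
    {
        "genus": ["GenA", "GenB"],
        "phylum": ["PhyA", "PhyB"],
        "genome_size_bp": [3_000_000, 4_000_000],
    },
    index=pd.Index(["sA", "sB"], name="strain_id"),
)


class TestBuildGenomeTable:
    def test_hand_count(self):
        annotations = {
            "sA": [
                ("g1", frozenset({"GH13"})),
                ("g2", frozenset({"GH13_18"})),
                ("g3", frozenset({"GT2"})),
            ],
            "sB": [],
        }
        table = aio.build_genome_table(annotations, TAXONOMY)
        assert table.counts.loc["sA", "GH13"] == 2  # subfamily collapsed
        assert table.counts.loc["sA", "GT2"] == 1
        assert (table.counts.loc["sB"] == 0).all()  # zero row retained

    def test_multifamily_gene_counts_once_per_family(self):
        annotations = {"sA": [("g1", frozenset({"GH5_4", "CBM6"}))], "sB": []}
        table = aio.build_genome_table(annotations, TAXONOMY)
        assert table.counts.loc["sA", "GH5"] == 1
        assert table.counts.loc["sA", "CBM6"] == 1

    def test_disjoint_genomes_union_and_zero_fill(self):
        annotations = {
            "sA": [("g1", frozenset({"GH1"}))],
            "sB": [("g2", frozenset({"PL9"}))],
        }
        table = aio.build_genome_table(annotations, TAXONOMY)
        assert set(table.families) == {"GH1", "PL9"}
        assert table.counts.loc["sA", "PL9"] == 0
        assert table.counts.loc["sB", "GH1"] == 0

    def test_missing_taxonomy_names_strain(self):
        with pytest.raises(KeyError, match="sC"):
            aio.build_genome_table({"sC": []}, TAXONOMY)

    def test_count_conservation(self):
        """Total cells equal the number of (gene, canonical family) pairs."""
        rng = np.random.default_rng(3)
        fams = ["GH1", "GH2", "GT2", "PL9", "CBM6"]
        annotations = {}
        n_pairs = 0
        for strain in TAXONOMY.index:
            genes = []
            for g in range(rng.integers(1, 20)):
                chosen = frozenset(
                    rng.choice(fams, size=rng.integers(1, 3), replace=False)
                )
                genes.append((f"{strain}_g{g}", chosen))
                n_pairs += len(chosen)
            annotations[strain] = genes
        table = aio.build_genome_table(annotations, TAXONOMY)
        assert table.total_copies() == n_pairs

    def test_tsv_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "table.tsv"
        toy_table.to_tsv(path)
        back = aio.GenomeCazymeTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
        pd.testing.assert_frame_equal(back.meta, toy_table.meta)


class TestSummaries:
    def test_class_shares_symmetric_case(self):
        counts = pd.DataFrame(
            {"GH1": [2], "GT2": [2]}, index=pd.Index(["sA"], name="strain_id")
        )
        table = aio.GenomeCazymeTable(counts, TAXONOMY.iloc[:1])
        shares = aio.class_shares(table)
        assert shares["GH"] == pytest.approx(50.0)
        assert shares["GT"] == pytest.approx(50.0)
        assert shares[["PL", "CE", "CBM", "AA"]].sum() == 0.0

    def test_class_shares_sum_to_100(self, toy_table):
        assert aio.class_shares(toy_table).sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_table_errors(self):
        counts = pd.DataFrame({"GH1": [0]}, index=pd.Index(["sA"], name="strain_id"))
        table = aio.GenomeCazymeTable(counts, TAXONOMY.iloc[:1])
        with pytest.raises(ValueError, match="all-zero"):
            aio.class_shares(table)

    def test_genus_summary_constant(self, toy_table):
        # Bacteroides GH totals: s1 = 2+1 = 3, s2 = 1
        n, mean, sd = aio.genus_summary(toy_table, "GH", "Bacteroides")
        assert (n, mean) == (2, 2.0)
        assert sd == pytest.approx(np.std([3, 1], ddof=1))

    def test_genus_summary_hand_sd(self):
        counts = pd.DataFrame(
            {"GH1": [0, 20]}, index=pd.Index(["sA", "sB"], name="strain_id")
        )
        meta = TAXONOMY.copy()
        meta["genus"] = "GenA"
        table = aio.GenomeCazymeTable(counts, meta)
        n, mean, sd = aio.genus_summary(table, "GH", "GenA")
        assert (n, mean) == (2, 10.0)
        assert sd == pytest.approx(14.1421356, abs=1e-6)

    def test_genus_summary_unknown_genus(self, toy_table):
        with pytest.raises(KeyError, match="Escherichia"):
            aio.genus_summary(toy_table, "GH", "Escherichia")

    def test_phylum_contribution_hand_ratio(self, toy_table):
        contrib = aio.phylum_family_contribution(toy_table)
        # GH13: Bacteroidota 2, Firmicutes 10 -> 1/6 vs 5/6
        assert contrib.loc["GH13", "Bacteroidota"] == pytest.approx(100 / 6)
        assert contrib.loc["GH13", "Firmicutes"] == pytest.approx(500 / 6)
        # PL1 only in Firmicutes genomes
        assert contrib.loc["PL1", "Firmicutes"] == pytest.approx(100.0)
        assert np.allclose(contrib.sum(axis=1), 100.0, atol=1e-9)

    def test_phylum_contribution_excludes_zero_family(self, caplog):
        counts = pd.DataFrame(
            {"GH1": [1, 0], "GT2": [0, 0]},
            index=pd.Index(["sA", "sB"], name="strain_id"),
        )
        table = aio.GenomeCazymeTable(counts, TAXONOMY)
        with caplog.at_level("INFO"):
            contrib = aio.phylum_family_contribution(table)
        assert "GT2" not in contrib.index

    def test_size_correlation_perfect_linearity(self):
        rng = np.random.default_rng(0)
        totals = rng.integers(10, 200, size=30)
        counts = pd.DataFrame(
            {"GH1": totals}, index=pd.Index([f"s{i}" for i in range(30)], name="strain_id")
        )
        meta = pd.DataFrame(
            {
                "genus": "G",
                "phylum": "P",
                "genome_size_bp": 1_000_000 + 20_000 * totals,
            },
            index=counts.index,
        )
        assert aio.size_correlation(aio.GenomeCazymeTable(counts, meta)) == pytest.approx(1.0)

    def test_size_correlation_independent_near_zero(self):
        """Monte-Carlo oracle: independent size and copies give r^2 ~ 1/n."""
        rng = np.random.default_rng(7)
        n = 4000
        counts = pd.DataFrame(
            {"GH1": rng.integers(10, 200, size=n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="strain_id"),
        )
        meta = pd.DataFrame(
            {
                "genus": "G",
                "phylum": "P",
                "genome_size_bp": rng.integers(2_000_000, 6_000_000, size=n),
            },
            index=counts.index,
        )
        assert aio.size_correlation(aio.GenomeCazymeTable(counts, meta)) < 0.01

    def test_size_correlation_zero_variance_errors(self):
        counts = pd.DataFrame(
            {"GH1": [5, 5, 5]},
            index=pd.Index(["a", "b", "c"], name="strain_id"),
        )
        meta = pd.DataFrame(
            {"genus": "G", "phylum": "P", "genome_size_bp": [1e6, 2e6, 3e6]},
            index=counts.index,
        )
        with pytest.raises(ValueError, match="zero variance"):
            aio.size_correlation(aio.GenomeCazymeTable(counts, meta))
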