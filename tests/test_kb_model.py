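"""Knowledge-graph and expression-catalog loading, lookup and round-trips."""
import numpy as np
import pytest
from scipy import stats

import tissuenet as tn
from tissuenet.kb_model import (
    EXPRESSION_COLUMNS,
    FormatError,
    ParseError,
    PatternError,
    TissueLookupError,
    load_expression,
    load_gene_set,
    load_interactions,
    write_expression,
    write_interactions,
)

from conftest import INTERACTIONS_HEADER, write_tsv


class TestLoadInteractions:
    def test_three_line_file(self, tiny_kb_file):
        kb = load_interactions(tiny_kb_file)
        assert len(kb.nodes) == 4
        assert len(kb.edges) == 3
        assert kb.gene_universe == {"g1", "g2"}
        assert kb.proteins_of("g1") == {"p1"}

    def test_duplicate_edges_collapse(self, tmp_path):
        path = tmp_path / "kb.tsv"
        write_tsv(
            path,
            [
                INTERACTIONS_HEADER,
                ("g1", "gene", "expression", "p1", "protein", "true"),
                ("p1", "protein", "interaction", "p2", "protein", "false"),
                ("p2", "protein", "interaction", "p1", "protein", "false"),
                ("g2", "gene", "expression", "p2", "protein", "true"),
            ],
        )
        kb = load_interactions(path)
        assert len(kb.edges) == 3
        assert kb.n_duplicates_collapsed == 1

    def test_self_loop_dropped(self, tmp_path):
        path = tmp_path / "kb.tsv"
        write_tsv(
            path,
            [
                INTERACTIONS_HEADER,
                ("g1", "gene", "association", "g1", "gene", "false"),
                ("g1", "gene", "expression", "p1", "protein", "true"),
                ("g2", "gene", "expression", "p1", "protein", "true"),
            ],
        )
        kb = load_interactions(path)
        assert len(kb.edges) == 2
        assert kb.n_selfloops_dropped == 1

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "kb.tsv"
        write_tsv(path, [("source_id", "source_kind", "itype", "target_id", "target_kind")])
        with pytest.raises(FormatError, match="directed"):
            load_interactions(path)

    @pytest.mark.parametrize(
        "row",
        [
            ("g1", "enzyme", "expression", "p1", "protein", "true"),
            ("g1", "gene", "binds", "p1", "protein", "true"),
            ("g1", "gene", "expression", "p1", "protein", "maybe"),
        ],
    )
    def test_unknown_token_reports_line(self, tmp_path, row):
        path = tmp_path / "kb.tsv"
        write_tsv(path, [INTERACTIONS_HEADER, row])
        with pytest.raises(ParseError, match="line 2"):
            load_interactions(path)

    def test_roundtrip_is_canonical(self, tmp_path, tiny_kb_file):
        kb = load_interactions(tiny_kb_file)
        out1 = tmp_path / "out1.tsv"
        write_interactions(kb, out1)
        kb2 = load_interactions(out1)
        out2 = tmp_path / "out2.tsv"
        write_interactions(kb2, out2)
        assert out1.read_bytes() == out2.read_bytes()
        assert {e.key() for e in kb.edges} == {e.key() for e in kb2.edges}

    def test_load_order_insensitive(self, tmp_path):
        rows = [
            ("g1", "gene", "expression", "p1", "protein", "true"),
            ("p1", "protein", "interaction", "p2", "protein", "false"),
            ("g2", "gene", "expression", "p2", "protein", "true"),
            ("g1", "gene", "association", "g2", "gene", "false"),
        ]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(a, [INTERACTIONS_HEADER] + rows)
        write_tsv(b, [INTERACTIONS_HEADER] + rows[::-1])
        ka, kb_ = load_interactions(a), load_interactions(b)
        assert ka.nodes == kb_.nodes
        assert ka.edges == kb_.edges


class TestExpressionCatalog:
    def test_present_rows_only(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_tsv(
            path,
            [
                EXPRESSION_COLUMNS,
                ("g1", "lymph node", "present"),
                ("g2", "lymph node", "absent"),
            ],
        )
        catalog = load_expression(path)
        assert catalog.genes_expressed_in("lymph node") == {"g1"}

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_tsv(path, [EXPRESSION_COLUMNS])
        catalog = load_expression(path)
        assert catalog.tissue_names == []

    def test_all_present_grid(self, tmp_path):
        path = tmp_path / "expr.tsv"
        rows = [EXPRESSION_COLUMNS]
        for t in ("t1", "t2", "t3"):
            for g in ("g1", "g2"):
                rows.append((g, t, "present"))
        write_tsv(path, rows)
        catalog = load_expression(path)
        assert len(catalog.tissue_names) == 3
        assert all(
            len(catalog.genes_expressed_in(t)) == 2 for t in catalog.tissue_names
        )

    def test_unknown_call_token(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_tsv(path, [EXPRESSION_COLUMNS, ("g1", "retina", "expressed")])
        with pytest.raises(ParseError, match="line 2"):
            load_expression(path)

    def test_absent_only_tissue_retained_empty(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_tsv(path, [EXPRESSION_COLUMNS, ("g1", "retina", "absent")])
        catalog = load_expression(path)
        assert catalog.tissue_names == ["retina"]
        assert catalog.genes_expressed_in("retina") == frozenset()

    def test_case_fold_lookup(self, fixture_catalog):
        assert fixture_catalog.genes_expressed_in("t1") == fixture_catalog.genes_expressed_in("T1")

    def test_unknown_tissue_suggests(self):
        catalog = tn.ExpressionCatalog({"lymph node": {"g1"}, "retina": set()})
        with pytest.raises(TissueLookupError, match="lymph node"):
            catalog.genes_expressed_in("lymph nodes")

    def test_roundtrip_preserves_tissues_and_calls(self, tmp_path, fixture_catalog):
        path = tmp_path / "expr.tsv"
        write_expression(fixture_catalog, path)
        back = load_expression(path)
        assert back.tissue_names == fixture_catalog.tissue_names
        for t in back.tissue_names:
            assert back.genes_expressed_in(t) == fixture_catalog.genes_expressed_in(t)

    def test_load_order_insensitive(self, tmp_path):
        rows = [("g1", "t1", "present"), ("g2", "t1", "present"), ("g1", "t2", "present")]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(a, [EXPRESSION_COLUMNS] + rows)
        write_tsv(b, [EXPRESSION_COLUMNS] + rows[::-1])
        ca, cb = load_expression(a), load_expression(b)
        assert set(ca.tissue_names) == set(cb.tissue_names)
        for t in ca.tissue_names:
            assert ca.genes_expressed_in(t) == cb.genes_expressed_in(t)


class TestMatchTissues:
    @pytest.fixture()
    def catalog(self):
        return tn.ExpressionCatalog(
            {"lymph node": {"g1"}, "lymphatic vessel": set(), "retina": {"g2"}}
        )

    def test_prefix_wildcard(self, catalog):
        assert catalog.match_tissues("lymph*") == ["lymph node", "lymphatic vessel"]

    def test_exact(self, catalog):
        assert catalog.match_tissues("retina") == ["retina"]
        assert catalog.match_tissues("cornea") == []

    def test_malformed_wildcard(self, catalog):
        with pytest.raises(PatternError):
            catalog.match_tissues("liv*er")

    def test_full_name_plus_star_includes_exact(self, catalog):
        for name in ("lymph node", "retina"):
            assert name in catalog.match_tissues(name + "*")


class TestTissueGeneCounts:
    def test_counts_rows(self):
        catalog = tn.ExpressionCatalog({"a": {"g1", "g2"}, "b": {"g3", "g4"}, "c": set()})
        df = catalog.tissue_gene_counts()
        assert list(df["n_expressed_genes"]) == [2, 2, 0]

    def test_empty_catalog(self):
        catalog = tn.ExpressionCatalog({})
        assert catalog.tissue_gene_counts().empty

    def test_synthetic_coverage_within_binomial_band(self):
        cfg = tn.SyntheticConfig(n_genes=1000, coverage=0.5, n_tissues=4,
                                 tissue_correlation=0.0, seed=7)
        kb = tn.generate_kb(cfg)
        catalog = tn.generate_catalog(cfg, kb)
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        counts = catalog.tissue_gene_counts()["n_expressed_genes"]
        assert ((counts >= lo) & (counts <= hi)).all()


class TestGeneSets:
    def test_plain_list(self, tmp_path):
        path = tmp_path / "set.txt"
        path.write_text("# comment\ng1\ng2\ng1\n", encoding="utf-8")
        name, genes = load_gene_set(path)
        assert name == "set"
        assert genes == ["g1", "g2"]

    def test_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "apoptosis\tdesc\tg1\tg2\tg3\nother\tdesc\tg9\n", encoding="utf-8"
        )
        name, genes = load_gene_set(path)
        assert (name, genes) == ("apoptosis", ["g1", "g2", "g3"])
        name, genes = load_gene_set(path, set_name="other")
        assert genes == ["g9"]


def test_count_histogram_and_plot(tmp_path):
    catalog = tn.ExpressionCatalog({"a": {"g1", "g2"}, "b": {"g3"}, "c": set()})
    hist = catalog.count_histogram(n_bins=4)
    assert hist["n_tissues"].sum() == 3
    out = tmp_path / "dist.png"
    catalog.plot_count_histogram(out)
    assert out.stat().st_size > 0
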