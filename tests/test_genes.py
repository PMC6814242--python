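import numpy as np
import pandas as pd
import pytest

from colonywave.genes import (
    DETable,
    correlation_matrix,
    filter_de,
    intersection_count,
    lineage_specific_genes,
    make_de_table,
    top_ranked,
    ttest_significance,
    union_top_set,
    venn_overlap,
)
from colonywave.synth import ExpressionSpec, gen_expression


def de_table(rows):
    return DETable(frame=pd.DataFrame(rows))


class TestFilterDE:
    def test_exact_boundary_values_retained(self):
        # FC = 2.0 exactly, abundance exactly 1.0: inclusive thresholds
        t = de_table(
            [{"gene": "g", "fold_change": 2.0, "direction": "up",
              "significant": True, "max_abundance": 1.0}]
        )
        assert len(filter_de(t)) == 1

    def test_low_abundance_removed_despite_large_fold_change(self):
        t = de_table(
            [{"gene": "g", "fold_change": 10.0, "direction": "up",
              "significant": True, "max_abundance": 0.5}]
        )
        assert len(filter_de(t)) == 0

    def test_downregulation_uses_symmetric_threshold(self):
        rows = [
            {"gene": "a", "fold_change": 0.5, "direction": "down",
             "significant": True, "max_abundance": 5.0},
            {"gene": "b", "fold_change": 0.6, "direction": "down",
             "significant": True, "max_abundance": 5.0},
        ]
        out = filter_de(de_table(rows))
        assert out.frame["gene"].tolist() == ["a"]

    def test_insignificant_removed(self):
        t = de_table(
            [{"gene": "g", "fold_change": 8.0, "direction": "up",
              "significant": False, "max_abundance": 10.0}]
        )
        assert len(filter_de(t)) == 0


class TestUnionAndVenn:
    def _tables(self, rankings):
        tables = {}
        for cond, genes in rankings.items():
            rows = []
            for i, g in enumerate(genes):
                rows.append(
                    {"gene": g, "fold_change": 200.0 - i, "direction": "up",
                     "significant": True, "max_abundance": 10.0}
                )
                rows.append(
                    {"gene": "d_" + g, "fold_change": 1.0 / (200.0 - i),
                     "direction": "down", "significant": True,
                     "max_abundance": 10.0}
                )
            tables[cond] = de_table(rows)
        return tables

    def test_identical_rankings_give_union_of_200(self):
        genes = [f"g{i}" for i in range(150)]
        tables = self._tables({"A": genes, "B": genes, "C": genes})
        union, _ = union_top_set(tables, n_top=100)
        assert len(union) == 200  # 100 up + 100 down

    def test_disjoint_top_lists_give_600(self):
        tables = self._tables(
            {c: [f"{c}{i}" for i in range(100)] for c in "ABC"}
        )
        union, _ = union_top_set(tables, n_top=100)
        assert len(union) == 600

    def test_short_direction_takes_all_available(self):
        tables = self._tables({"A": ["x", "y"]})
        union, per = union_top_set(tables, n_top=100)
        assert per["A"]["up"] == ["x", "y"]
        assert len(union) == 4

    def test_rank_ties_broken_lexicographically(self):
        rows = [
            {"gene": g, "fold_change": 4.0, "direction": "up",
             "significant": True, "max_abundance": 5.0}
            for g in ["zeta", "alpha", "mid"]
        ]
        assert top_ranked(de_table(rows), "up", 2) == ["alpha", "mid"]

    def test_venn_regions_sum_to_union(self):
        sets = {
            "A": {"a", "b", "c", "x"},
            "B": {"b", "c", "y"},
            "C": {"c", "z", "x"},
        }
        regions = venn_overlap(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))
        assert regions["A&B&C"] == 1
        assert intersection_count(sets) == 1

    def test_disjoint_and_identical_sets(self):
        assert intersection_count({"A": {"a"}, "B": {"b"}, "C": {"c"}}) == 0
        s = {f"g{i}" for i in range(7)}
        assert intersection_count({"A": set(s), "B": set(s), "C": set(s)}) == 7


class TestCorrelation:
    def _expr(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        return pd.DataFrame(
            {"s1": rng.uniform(1, 100, 50), "s2": rng.uniform(1, 100, 50)},
            index=pd.Index(genes, name="gene"),
        )

    def test_duplicated_sample_correlates_perfectly(self):
        expr = self._expr()
        expr["s3"] = expr["s1"]
        r = correlation_matrix(expr, set(expr.index))
        assert r.loc["s1", "s3"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.values, r.values.T)

    def test_negated_zscores_anticorrelate(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(40)
        expr = pd.DataFrame(
            {"s1": z, "s2": -z}, index=[f"g{i}" for i in range(40)]
        )
        r = correlation_matrix(expr, set(expr.index), transform="raw")
        assert r.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_common_factor_model_matches_analytic_expectation(self):
        """Two samples sharing a fraction of variance through a common factor:
        r approaches rho = var_shared / (var_shared + var_noise)."""
        rng = np.random.default_rng(2)
        n = 4000
        shared = rng.standard_normal(n)
        s1 = shared + rng.standard_normal(n)
        s2 = shared + rng.standard_normal(n)
        expr = pd.DataFrame(
            {"s1": s1, "s2": s2}, index=[f"g{i}" for i in range(n)]
        )
        r = correlation_matrix(expr, set(expr.index), transform="raw")
        assert r.loc["s1", "s2"] == pytest.approx(0.5, abs=0.05)

    def test_planted_treatment_structure_correlates_treatments(self):
        expr, flags, truth = gen_expression(ExpressionSpec(seed=0))
        genes = set()
        for cond in truth.up_sets:
            genes |= truth.up_sets[cond] | truth.down_sets[cond]
        r = correlation_matrix(expr, genes)
        assert r.loc["BMP_1", "BMP_SB_1"] > r.loc["BMP_1", "mTeSR_1"]


class TestLineageFilter:
    def _embryo(self):
        genes = ["te_marker", "te_unstable", "te_low", "epi_marker", "bg"]
        cols = {}
        for lin in ("EPI", "PE", "TE"):
            for day in ("E5", "E6", "E7"):
                cols[f"{lin}_{day}"] = [1.0] * len(genes)
        expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        expr.loc["te_marker", [f"TE_{d}" for d in ("E5", "E6", "E7")]] = 100.0
        expr.loc["te_unstable", [f"TE_{d}" for d in ("E5", "E6", "E7")]] = 100.0
        expr.loc["te_low", "TE_E7"] = 100.0  # RPKM >= 10 on one day only
        expr.loc["epi_marker", [f"EPI_{d}" for d in ("E5", "E6", "E7")]] = 50.0
        return expr

    def _de(self):
        between = pd.DataFrame(
            [
                {"gene": "te_marker", "lineage": "TE", "significant": True},
                {"gene": "te_unstable", "lineage": "TE", "significant": True},
                {"gene": "te_low", "lineage": "TE", "significant": True},
                {"gene": "epi_marker", "lineage": "EPI", "significant": True},
            ]
        )
        within = pd.DataFrame(
            [{"gene": "te_unstable", "lineage": "TE", "significant": True}]
        )
        return between, within

    def test_stable_high_marker_selected(self):
        between, within = self._de()
        out = lineage_specific_genes(self._embryo(), between, within)
        te = set(out[out["lineage"] == "TE"]["gene"])
        assert "te_marker" in te

    def test_within_lineage_variability_excluded(self):
        between, within = self._de()
        out = lineage_specific_genes(self._embryo(), between, within)
        assert "te_unstable" not in set(out["gene"])

    def test_low_expression_on_two_days_excluded(self):
        between, within = self._de()
        out = lineage_specific_genes(self._embryo(), between, within)
        assert "te_low" not in set(out["gene"])

    def test_missing_time_point_rejected(self):
        between, within = self._de()
        expr = self._embryo().drop(columns=["PE_E6"])
        with pytest.raises(KeyError):
            lineage_specific_genes(expr, between, within)


class TestPlantedRoundTrip:
    def test_union_and_venn_counts_recovered_from_synthetic_data(self):
        """End-to-end: planted DE structure with external significance flags
        reproduces the designed union size and triple overlaps exactly."""
        spec = ExpressionSpec(seed=11)
        expr, flags, truth = gen_expression(spec)
        tables = {}
        for cond in spec.conditions[1:]:
            sub = flags[flags["condition"] == cond]
            sig = pd.Series(True, index=sub[sub["significant"]]["gene"])
            tables[cond] = filter_de(make_de_table(expr, cond, "mTeSR", significant=sig))
        union, per = union_top_set(tables, n_top=spec.n_planted)
        assert len(union) == truth.union_size == 284
        up_sets = {c: set(v["up"]) for c, v in per.items()}
        down_sets = {c: set(v["down"]) for c, v in per.items()}
        assert intersection_count(up_sets) == truth.triple_up == 77
        assert intersection_count(down_sets) == truth.triple_down == 54

    def test_zero_effect_with_builtin_test_retains_almost_nothing(self):
        spec = ExpressionSpec(
            seed=5, n_genes=800, n_replicates=4, effect_fold=1.0
        )
        expr, _, _ = gen_expression(spec)
        table = filter_de(make_de_table(expr, "BMP", "mTeSR"))
        assert len(table) <= 8  # BH-controlled false positives only

    def test_builtin_test_finds_planted_effects_with_replication(self):
        spec = ExpressionSpec(seed=6, n_genes=800, n_replicates=4)
        expr, _, truth = gen_expression(spec)
        sig = ttest_significance(expr, "BMP", "mTeSR")
        planted = truth.up_sets["BMP"] | truth.down_sets["BMP"]
        recovered = set(sig[sig].index) & planted
        assert len(recovered) / len(planted) > 0.9
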