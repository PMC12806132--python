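import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omicflux.expression import ExpressionMatrix
from omicflux.stats import (
    ComparisonGroup,
    bh_adjust,
    build_groups,
    differential_analysis,
    lilliefors_test,
    rank_test,
    reaction_expression,
)


def two_sample(name, a, b):
    return ComparisonGroup(
        name=name, member_sets=(("A", frozenset(a)), ("B", frozenset(b)))
    )


def values_from(arrs):
    """Map synthetic sample ids to values: a0..a(n-1), b0..."""
    out = {}
    for prefix, arr in arrs.items():
        for i, v in enumerate(arr):
            out[f"{prefix}{i}"] = v
    return out


def oracle_mw_p(x, y):
    """Independent exact two-sided p: U counted pairwise, full enumeration."""

    def u_stat(a, b):
        u = 0.0
        for xi in a:
            for yj in b:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    null = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        null.append(u_stat(a, b))
    null = np.array(null)
    p_le = np.mean(null <= u_obs + 1e-9)
    p_ge = np.mean(null >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def oracle_bh(p):
    """Step-up definition, written from scratch."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        value = p[i] * m / (rank_idx + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(1.0, running_min)
    return adjusted


class TestBuildGroups:
    @pytest.fixture
    def pancreas_meta(self):
        rows = []
        for i in range(6):
            rows.append({"sample_id": f"n{i}", "condition": "N", "subtype": "N", "stage": "-"})
        for i in range(8):
            stage = "S1" if i < 4 else "S2"
            rows.append(
                {"sample_id": f"c{i}", "condition": "C", "subtype": "C", "stage": stage}
            )
        return pd.DataFrame(rows)

    def test_pancreas_scheme(self, pancreas_meta):
        groups = build_groups(pancreas_meta, scheme="pancreas2")
        assert [g.name for g in groups] == ["N-C", "N-S1"]
        n_c = groups[0]
        assert n_c.test_kind == "two_sample"
        assert len(dict(n_c.member_sets)["C"]) == 8
        assert len(dict(groups[1].member_sets)["S1"]) == 4

    def test_lung_scheme_drops_empty_sets(self):
        rows = []
        for i in range(5):
            rows.append({"sample_id": f"n{i}", "condition": "N", "subtype": "N", "stage": "-"})
        for i in range(5):
            rows.append({"sample_id": f"a{i}", "condition": "C", "subtype": "AD", "stage": "S1"})
        groups = build_groups(pd.DataFrame(rows), scheme="lung36")
        names = {g.name for g in groups}
        # only comparisons involving N/AD survive; SC-involving ones dropped
        assert "C-N" in names and "AD-N" in names and "ADS1-N" in names
        assert not any("SC" in n for n in names)

    def test_lung_scheme_full_metadata(self):
        rows = []
        k = 0
        for i in range(6):
            rows.append({"sample_id": f"n{i}", "condition": "N", "subtype": "N", "stage": "-"})
        for sub in ("AD", "SC"):
            for stage in ("S1", "S2", "S3", "S4"):
                for i in range(3):
                    rows.append(
                        {
                            "sample_id": f"c{k}",
                            "condition": "C",
                            "subtype": sub,
                            "stage": stage,
                        }
                    )
                    k += 1
        for i in range(4):
            rows.append({"sample_id": f"s{i}", "condition": "C", "subtype": "SCLC", "stage": "-"})
        groups = build_groups(pd.DataFrame(rows), scheme="lung36")
        names = [g.name for g in groups]
        assert len(names) == len(set(names)) == 32
        kinds = {g.name: g.test_kind for g in groups}
        assert kinds["N-AD-SC"] == "k_sample"
        assert kinds["AD-stages"] == "k_sample"
        assert kinds["AD-S2-S1"] == "two_sample"

    def test_custom_k_sample(self):
        rows = [
            {"sample_id": f"s{i}", "condition": lab}
            for i, lab in enumerate(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        ]
        groups = build_groups(pd.DataFrame(rows), scheme="custom")
        assert len(groups) == 1
        assert groups[0].test_kind == "k_sample"

    def test_unknown_scheme(self, pancreas_meta):
        with pytest.raises(ValueError, match="scheme"):
            build_groups(pancreas_meta, scheme="nope")

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ComparisonGroup(
                name="bad",
                member_sets=(("A", frozenset({"s1"})), ("B", frozenset({"s1"}))),
            )


class TestLilliefors:
    def test_heavy_tail_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_cauchy(500)
        res = lilliefors_test(x, n_mc=500, seed=1)
        assert res.pvalue < 0.01

    def test_normal_not_rejected_typically(self):
        rng = np.random.default_rng(6)
        x = rng.normal(3, 2, size=500)
        res = lilliefors_test(x, n_mc=500, seed=2)
        assert res.pvalue > 0.01

    def test_calibration_uniform_p(self):
        """Null p-values pass a KS test against uniform."""
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(40):
            x = rng.normal(size=80)
            ps.append(lilliefors_test(x, n_mc=200, seed=100 + rep).pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_degenerate(self):
        res = lilliefors_test([2.0] * 10, n_mc=1000, seed=0)
        assert res.degenerate
        assert res.pvalue <= 1 / 1000

    def test_too_small(self):
        with pytest.raises(ValueError, match="n >= 4"):
            lilliefors_test([1.0, 2.0, 3.0])

    def test_seed_determinism(self):
        x = np.random.default_rng(8).normal(size=50)
        a = lilliefors_test(x, n_mc=300, seed=9)
        b = lilliefors_test(x, n_mc=300, seed=9)
        assert a.pvalue == b.pvalue


class TestRankTest:
    def test_separated_triples_exact(self):
        group = two_sample("t", ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        vals = values_from({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = rank_test(group, vals)
        assert res.method == "mw_exact"
        assert res.p_raw == pytest.approx(0.1)

    def test_identical_sets_p_one(self):
        group = two_sample("t", ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        vals = values_from({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = rank_test(group, vals)
        assert res.p_raw == pytest.approx(1.0)

    def test_all_constant_degenerate(self):
        group = two_sample("t", ["a0", "a1"], ["b0", "b1"])
        vals = values_from({"a": [2, 2], "b": [2, 2]})
        res = rank_test(group, vals)
        assert res.degenerate and res.p_raw == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            group = two_sample("t", [f"a{i}" for i in range(n1)], [f"b{i}" for i in range(n2)])
            vals = values_from({"a": x, "b": y})
            res = rank_test(group, vals)
            assert res.p_raw == pytest.approx(oracle_mw_p(x, y), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        group = two_sample("t", [f"a{i}" for i in range(15)], [f"b{i}" for i in range(15)])
        res = rank_test(group, values_from({"a": x, "b": y}))
        assert res.method == "mw_normal"
        scipy_p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert res.p_raw == pytest.approx(scipy_p)

    def test_k_sample_kruskal(self):
        rng = np.random.default_rng(13)
        arrs = {"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8), "c": rng.normal(2, 1, 8)}
        group = ComparisonGroup(
            name="k",
            member_sets=tuple(
                (k, frozenset(f"{k}{i}" for i in range(8))) for k in "abc"
            ),
        )
        res = rank_test(group, values_from(arrs))
        assert res.method == "kruskal"
        assert res.p_raw < 0.05

    def test_small_set_rejected(self):
        group = two_sample("t", ["a0"], ["b0", "b1"])
        with pytest.raises(ValueError, match=">= 2"):
            rank_test(group, values_from({"a": [1], "b": [2, 3]}))


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_single_identity(self):
        assert bh_adjust([0.5])[0] == pytest.approx(0.5)

    def test_equal_ps_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_matches_stepup_oracle_random_vectors(self):
        rng = np.random.default_rng(15)
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)


class TestReactionExpression:
    def test_single_gene_identity(self, chain_model):
        df = pd.DataFrame(
            {"s1": {"g1": 0.3, "g2": 0.9}, "s2": {"g1": 0.6, "g2": 0.2}}
        )
        expr = ExpressionMatrix(values=df, layer="TX")
        chain_model.get_reaction("A2B").gpr = None
        from omicflux.gsmm import parse_gpr

        chain_model.get_reaction("A2B").gpr = parse_gpr("g1")
        out = reaction_expression(chain_model, expr)
        np.testing.assert_allclose(
            out.values.loc["A2B"].to_numpy(), df.loc["g1"].to_numpy()
        )

    def test_and_is_elementwise_min(self, chain_model):
        df = pd.DataFrame(
            {"s1": {"g1": 0.3, "g2": 0.9}, "s2": {"g1": 0.6, "g2": 0.2}}
        )
        expr = ExpressionMatrix(values=df, layer="TX")
        out = reaction_expression(chain_model, expr)
        np.testing.assert_allclose(out.values.loc["A2B"].to_numpy(), [0.3, 0.2])
        assert out.layer == "reaction_expression"

    def test_row_count_is_gpr_bearing_reactions(self, toy_model, toy_cohort):
        from omicflux.expression import normalize_reference_minmax

        expr = normalize_reference_minmax(toy_cohort.tx, "PKM")
        out = reaction_expression(toy_model, expr)
        expected = sum(1 for r in toy_model.reactions if r.gpr is not None)
        assert out.shape[0] == expected


class TestDifferentialAnalysis:
    def test_zero_variance_excluded(self):
        df = pd.DataFrame(
            {
                "a0": {"f1": 1.0, "f2": 5.0},
                "a1": {"f1": 2.0, "f2": 5.0},
                "b0": {"f1": 9.0, "f2": 5.0},
                "b1": {"f1": 8.0, "f2": 5.0},
            }
        )
        matrix = ExpressionMatrix(values=df, layer="JX")
        group = two_sample("t", ["a0", "a1"], ["b0", "b1"])
        (result,) = differential_analysis(matrix, [group])
        assert result.excluded_features == ["f2"]
        assert result.table["feature_id"].tolist() == ["f1"]

    def test_padj_monotone_vs_praw(self, toy_cohort):
        matrix = toy_cohort.gx
        group = two_sample(
            "t",
            [s for s in matrix.sample_ids if s.startswith("N")],
            [s for s in matrix.sample_ids if s.startswith("C")],
        )
        (result,) = differential_analysis(matrix, [group])
        assert (result.table["p_adj"] >= result.table["p_raw"] - 1e-12).all()

    def test_missing_samples_rejected(self):
        df = pd.DataFrame({"a0": {"f1": 1.0}, "a1": {"f1": 2.0}})
        matrix = ExpressionMatrix(values=df, layer="JX")
        group = two_sample("t", ["a0", "a1"], ["zz0", "zz1"])
        with pytest.raises(ValueError, match="absent"):
            differential_analysis(matrix, [group])
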