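"""Enrichment-testing power pipeline: ground truth, null classification,
data generation, term statistics (against brute-force oracles), correction,
and the Power/FDP bookkeeping."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from goscope.dag import AnnotationMap, OntologyDAG, refine_dag
from goscope.ontology_io import propagate_annotations
from goscope.power import (
    SimulationConfig,
    bh_reject,
    bonferroni_reject,
    classify_nulls,
    designate_ground_truth,
    gene_pvalues,
    hypergeom_pvalue,
    power_fdp,
    run_power_study,
    simes_pvalue,
    simulate_expression,
    term_pvalues,
)
from goscope.power import testable_terms as hypothesis_family

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def simes_oracle(pvals):
    p = sorted(pvals)
    m = len(p)
    return min(1.0, min(m * p[k] / (k + 1) for k in range(m)))


def hypergeom_oracle(k, term_size, n_sig, universe):
    """Exact enumeration: fraction of n_sig-subsets with overlap >= k."""
    pop = range(universe)
    term = set(range(term_size))
    hits = total = 0
    for draw in itertools.combinations(pop, n_sig):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def bh_oracle(pvals, q):
    """Quadratic-time step-up reference."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kstar = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= q * rank / m:
            kstar = rank
    return {order[i] for i in range(kstar)}


# ---------------------------------------------------------------------------
# ground truth and null classification
# ---------------------------------------------------------------------------


def small_ann():
    universe = frozenset(f"g{i}" for i in range(1, 11))
    return AnnotationMap(
        {"T": frozenset({"g1", "g2"}), "U": frozenset({"g3", "g4"})}, universe
    )


class TestGroundTruth:
    def test_fraction_one_takes_all_genes(self, worked):
        dag, direct = worked["diamond"]
        ann = propagate_annotations(dag, direct)
        de = designate_ground_truth(dag, ann, {"B"}, 1.0)
        assert de == ann.genes_of["B"]

    def test_half_fraction_is_reproducible_subset(self, worked):
        dag, direct = worked["diamond"]
        ann = propagate_annotations(dag, direct)
        a = designate_ground_truth(dag, ann, {"A"}, 0.5, seed=3)
        b = designate_ground_truth(dag, ann, {"A"}, 0.5, seed=3)
        assert a == b and len(a) == math.ceil(0.5 * ann.size("A"))
        assert a <= ann.genes_of["A"]

    def test_union_over_terms_without_duplicates(self, worked):
        dag, direct = worked["diamond"]
        ann = propagate_annotations(dag, direct)
        de = designate_ground_truth(dag, ann, {"B", "C"}, 1.0)
        assert de == ann.genes_of["B"] | ann.genes_of["C"]

    def test_empty_annotation_term_rejected(self):
        dag = OntologyDAG({"A": ""}, [])
        ann = AnnotationMap({"A": frozenset()}, frozenset())
        with pytest.raises(ValueError, match="A"):
            designate_ground_truth(dag, ann, {"A"}, 1.0)


class TestClassifyNulls:
    def test_overlapping_term_nonnull_both_frameworks(self):
        ann = small_ann()
        assert "T" in classify_nulls(ann, {"g1"}, "self_contained")
        assert "T" in classify_nulls(ann, {"g1"}, "competitive")  # 1/2 > 0/8

    def test_disjoint_term_null_both_frameworks(self):
        ann = small_ann()
        assert "U" not in classify_nulls(ann, {"g1"}, "self_contained")
        assert "U" not in classify_nulls(ann, {"g1"}, "competitive")

    def test_all_genes_de_is_competitive_null(self):
        ann = small_ann()
        de = set(ann.universe)
        assert classify_nulls(ann, de, "self_contained") == {"T", "U"}
        assert classify_nulls(ann, de, "competitive") == frozenset()  # 1 not > 1

    def test_whole_universe_term_excluded_from_competitive(self):
        universe = frozenset({"g1", "g2"})
        ann = AnnotationMap({"ALL": universe, "T": frozenset({"g1"})}, universe)
        assert "ALL" not in hypothesis_family(ann, "competitive")
        assert "ALL" in hypothesis_family(ann, "self_contained")

    def test_self_contained_nonnull_propagates_to_ancestors(self, worked):
        dag, direct = worked["buoyant4"]
        ann = propagate_annotations(dag, direct)
        de = designate_ground_truth(dag, ann, {"C"}, 1.0)
        a1 = classify_nulls(ann, de, "self_contained")
        assert dag.ancestors("C") <= a1


# ---------------------------------------------------------------------------
# data generation and gene-level test
# ---------------------------------------------------------------------------


class TestSimulateExpression:
    def test_null_configuration_has_zero_mean(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(5)]
        ds = simulate_expression(genes, set(), 0.0, 5000, 5000, rng)
        se = 1 / math.sqrt(ds.matrix.shape[1])
        assert abs(ds.matrix.mean()) < 4 * se / math.sqrt(len(genes))

    def test_de_gene_mean_difference_matches_effect(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        ds = simulate_expression(genes, {"g0"}, 5.0, 50, 50, rng)
        diff = ds.matrix[0, 50:].mean() - ds.matrix[0, :50].mean()
        assert abs(diff - 5.0) < 4 * math.sqrt(2 / 50)
        other = ds.matrix[1, 50:].mean() - ds.matrix[1, :50].mean()
        assert abs(other) < 4 * math.sqrt(2 / 50)

    def test_fixed_seed_bitwise_identical(self):
        genes = ["a", "b"]
        x = simulate_expression(genes, {"a"}, 1.0, 3, 3, np.random.default_rng(9)).matrix
        y = simulate_expression(genes, {"a"}, 1.0, 3, 3, np.random.default_rng(9)).matrix
        assert np.array_equal(x, y)

    def test_equicorrelation_raises_gene_gene_correlation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(4)]
        ds = simulate_expression(genes, set(), 0.0, 2000, 2000, rng, rho=0.5)
        c = np.corrcoef(ds.matrix)
        off = c[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 0.5) < 0.1)


class TestGenePvalues:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(1000)]
        ds = simulate_expression(genes, set(), 0.0, 30, 30, rng)
        p = np.array(list(gene_pvalues(ds).values()))
        assert stats.kstest(p, "uniform").pvalue > 1e-3

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([np.zeros(4), np.ones(4)]) + 1e-3 * rng.standard_normal(8)
        from goscope.power import ExpressionDataset

        ds = ExpressionDataset(x[None, :], ["g"], np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        assert gene_pvalues(ds)["g"] < 1e-6

    def test_label_swap_symmetric(self):
        from goscope.power import ExpressionDataset

        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 10))
        g = np.array([0] * 5 + [1] * 5)
        a = gene_pvalues(ExpressionDataset(x, ["a", "b", "c"], g))
        b = gene_pvalues(ExpressionDataset(x, ["a", "b", "c"], 1 - g))
        assert a == pytest.approx(b)

    def test_zero_variance_gene_warns_and_p_is_one(self):
        from goscope.power import ExpressionDataset

        x = np.ones((1, 8))
        ds = ExpressionDataset(x, ["g"], np.array([0] * 4 + [1] * 4))
        with pytest.warns(UserWarning, match="zero pooled variance"):
            assert gene_pvalues(ds)["g"] == 1.0


# ---------------------------------------------------------------------------
# term-level statistics vs oracles
# ---------------------------------------------------------------------------


class TestSimes:
    def test_single_p_is_itself(self):
        assert simes_pvalue([0.2]) == pytest.approx(0.2)

    def test_equal_ps_return_the_common_value(self):
        assert simes_pvalue([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_worked_example(self):
        assert simes_pvalue([0.01, 0.04, 0.9]) == pytest.approx(0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simes_pvalue([])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_bracketed_by_min_p_and_bonferroni(self, pvals):
        """p_(1) <= Simes <= min(1, m * p_(1)) for any p-vector."""
        s = simes_pvalue(pvals)
        pmin = min(pvals)
        m = len(pvals)
        assert pmin - 1e-12 <= s <= min(1.0, m * pmin) + 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(
        st.sets(st.text("abc", min_size=1, max_size=3), max_size=8),
        st.sets(st.text("abc", min_size=1, max_size=3), max_size=8),
    )
    def test_power_fdp_always_in_unit_interval(self, a1, r):
        power, fdp = power_fdp(a1, r)
        assert 0.0 <= power <= 1.0 and 0.0 <= fdp <= 1.0

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            m = int(rng.integers(1, 12))
            p = rng.random(m)
            assert simes_pvalue(p) == pytest.approx(simes_oracle(list(p)))


class TestHypergeom:
    def test_worked_example(self):
        assert hypergeom_pvalue(3, 3, 4, 10) == pytest.approx(4 / 120)

    def test_zero_overlap_is_one(self):
        assert hypergeom_pvalue(0, 3, 4, 10) == pytest.approx(1.0)

    def test_term_equal_universe_forces_full_overlap(self):
        assert hypergeom_pvalue(4, 10, 4, 10) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 3, 4, 10)

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            universe = int(rng.integers(4, 13))
            term = int(rng.integers(1, universe + 1))
            n_sig = int(rng.integers(1, universe + 1))
            k = int(rng.integers(0, min(term, n_sig) + 1))
            assert hypergeom_pvalue(k, term, n_sig, universe) == pytest.approx(
                hypergeom_oracle(k, term, n_sig, universe)
            )


class TestCorrection:
    def test_worked_bh_example(self):
        p = {"a": 0.01, "b": 0.02, "c": 0.05, "d": 0.8}
        assert bh_reject(p, 0.1) == {"a", "b", "c"}

    def test_all_ones_reject_nothing(self):
        assert bh_reject({"a": 1.0, "b": 1.0}, 0.1) == frozenset()

    def test_single_small_p_rejected(self):
        assert bh_reject({"a": 0.04}, 0.05) == {"a"}

    def test_bonferroni_stricter_than_bh(self):
        rng = np.random.default_rng(8)
        p = {f"t{i}": float(x) for i, x in enumerate(rng.random(30) * 0.2)}
        assert bonferroni_reject(p, 0.1) <= bh_reject(p, 0.1)

    def test_matches_quadratic_oracle_on_random_psets(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            m = int(rng.integers(1, 25))
            p = rng.random(m)
            q = float(rng.uniform(0.01, 0.3))
            named = {f"t{i:03d}": float(p[i]) for i in range(m)}
            expected = {f"t{i:03d}" for i in bh_oracle(list(p), q)}
            assert bh_reject(named, q) == expected


class TestPowerFdp:
    def test_worked_example(self):
        assert power_fdp({"t1", "t2"}, {"t1", "t3"}) == (0.5, 0.5)

    def test_empty_sets_guarded(self):
        assert power_fdp(set(), set()) == (0.0, 0.0)

    def test_perfect_recovery(self):
        assert power_fdp({"a", "b"}, {"a", "b"}) == (1.0, 0.0)

    def test_relabeling_invariance(self):
        a1, r = {"x", "y", "z"}, {"y", "w"}
        ren = {t: t.upper() for t in a1 | r}
        assert power_fdp(a1, r) == power_fdp({ren[t] for t in a1}, {ren[t] for t in r})


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def study_inputs(seed=11):
    from goscope import fixtures as fx

    dag, direct = fx.random_godag(fx.FixtureSpec(n_terms=40, n_genes=200, seed=seed))
    ann = propagate_annotations(dag, direct)
    ref = refine_dag(dag, ann)
    return ref, ann.restrict(ref.terms)


class TestRunPowerStudy:
    def test_global_null_has_zero_power(self):
        dag, ann = study_inputs()
        cfg = SimulationConfig(beta_effect=0.0, n_control=5, n_case=5, reps=5, seed=1)
        report = run_power_study(dag, ann, frozenset(), cfg)
        assert report.nonnull_terms == frozenset()
        assert np.all(report.power_samples[(5, 5)] == 0.0)

    def test_reproducible_under_seed(self):
        dag, ann = study_inputs()
        mid = sorted(dag.terms, key=ann.size)[len(dag.terms) // 2]
        de = designate_ground_truth(dag, ann, {mid}, 1.0, seed=2)
        cfg = SimulationConfig(beta_effect=1.0, n_control=10, n_case=10, reps=5, seed=3)
        a = run_power_study(dag, ann, de, cfg)
        b = run_power_study(dag, ann, de, cfg)
        assert a.rejection_freq == b.rejection_freq
        assert np.array_equal(a.fdp_samples[(10, 10)], b.fdp_samples[(10, 10)])

    def test_competitive_pipeline_runs_and_controls_family(self):
        dag, ann = study_inputs()
        mid = sorted(dag.terms, key=ann.size)[len(dag.terms) // 2]
        de = designate_ground_truth(dag, ann, {mid}, 1.0, seed=4)
        cfg = SimulationConfig(
            beta_effect=2.0, n_control=20, n_case=20, reps=10, seed=5,
            framework="competitive",
        )
        report = run_power_study(dag, ann, de, cfg)
        assert set(report.tested_terms) <= set(dag.terms)
        assert np.all(report.fdp_samples[(20, 20)] <= 1.0)

    def test_summary_and_tables_shape(self):
        dag, ann = study_inputs()
        mid = sorted(dag.terms, key=ann.size)[len(dag.terms) // 2]
        de = designate_ground_truth(dag, ann, {mid}, 1.0, seed=6)
        cfg = SimulationConfig(reps=3, seed=7)
        report = run_power_study(dag, ann, de, cfg, grid=[(5, 5), (10, 10)])
        s = report.summary()
        assert list(s["n_control"]) == [5, 10]
        tab = report.rejection_table()
        assert tab.shape == (len(report.tested_terms), 2)
        assert report.to_json_dict()["grid"] == [[5, 5], [10, 10]]

    def test_term_pvalues_simes_uses_term_genes_only(self):
        ann = small_ann()
        gene_p = {f"g{i}": 0.5 for i in range(1, 11)}
        gene_p["g1"] = 0.001
        tp = term_pvalues(ann, gene_p, "self_contained", ["T", "U"])
        assert tp["T"] < tp["U"]
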