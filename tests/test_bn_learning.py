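"""Structure learning: standardization, the Gaussian BIC score, lasso
candidate screening, hill-climbing against exhaustive enumeration, ML weight
recovery against population coefficients, and the feature/statistics layer.
"""

import itertools

import numpy as np
import pytest

from rsbn.bn_learning import (
    BNLearnConfig,
    FamilyScorer,
    FeatureTable,
    StandardizedData,
    edge_group_stats,
    fit_weights_ml,
    gaussian_bic,
    group_bn,
    hill_climb_dag,
    lasso_parent_candidates,
    learn_bn,
    standardize,
    subject_feature_table,
)
from rsbn.datatypes import DAGModel
from rsbn.graphs import markov_equivalent
from rsbn.synthetic_data import simulate_cohort, simulate_subject


def all_dag_structures(k):
    """Every labelled DAG on k nodes, as parent-set dicts (oracle helper)."""
    subsets = [frozenset(s) for r in range(k) for s in itertools.combinations(range(k), r)]
    out = []
    for combo in itertools.product(*[[s for s in subsets if j not in s] for j in range(k)]):
        struct = {j: combo[j] for j in range(k)}
        try:
            gaussian_bic(struct, _DUMMY[k])  # acyclicity gate (score unused)
        except ValueError:
            continue
        out.append(struct)
    return out


# tiny standardized datasets reused by the enumeration helper's acyclicity gate
_rng = np.random.default_rng(0)
_DUMMY = {k: standardize(_rng.normal(size=(k + 2, k))) for k in (3, 4)}


def random_dag(k, seed, p_edge=0.5, w_lo=0.3, w_hi=1.0):
    rng = np.random.default_rng(seed)
    order = rng.permutation(k)
    w = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            if rng.random() < p_edge:
                w[order[a], order[b]] = rng.uniform(w_lo, w_hi) * rng.choice([-1, 1])
    return DAGModel(node_names=[f"x{i}" for i in range(k)], weights=w)


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, rng):
        z = standardize(rng.normal(2.0, 5.0, size=(100, 4)))
        assert np.all(np.abs(z.data.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(z.data.std(axis=0) - 1) < 1e-10)

    def test_idempotent(self, rng):
        z = standardize(rng.normal(size=(50, 3)))
        again = standardize(z.data)
        assert np.allclose(z.data, again.data, atol=1e-10)

    def test_constant_column_error_names_node(self, rng):
        data = rng.normal(size=(30, 3))
        data[:, 1] = 5.0
        with pytest.raises(ValueError, match="x1"):
            standardize(data)


class TestGaussianBIC:
    def test_single_standardized_node_closed_form(self, rng):
        """Empty graph on one z-scored column of N=100: the ML variance is
        exactly 1, so the score is -(N/2)(1+log 2pi) - (1/2) log N."""
        z = standardize(rng.normal(size=(100, 1)))
        expected = -(100 / 2) * (1 + np.log(2 * np.pi)) - 0.5 * np.log(100)
        assert gaussian_bic({0: []}, z) == pytest.approx(expected)
        assert gaussian_bic({0: []}, z) == pytest.approx(-144.196, abs=5e-4)

    def test_null_parent_usually_lowers_score(self):
        """Adding an irrelevant parent costs (log N)/2 but buys ~chi2_1/2 of
        fit, so at N=5000 the penalty wins almost always."""
        worse = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            z = standardize(rng.normal(size=(5000, 2)))
            if gaussian_bic({0: [], 1: [0]}, z) < gaussian_bic({0: [], 1: []}, z):
                worse += 1
        assert worse >= 38  # >= 95%

    def test_decomposes_over_families(self, rng):
        z = standardize(rng.normal(size=(200, 4)))
        struct = {0: [], 1: [0], 2: [0, 1], 3: [2]}
        scorer = FamilyScorer(z)
        total = sum(scorer.family_score(j, frozenset(p)) for j, p in struct.items())
        assert gaussian_bic(struct, z) == pytest.approx(total)

    def test_cyclic_structure_rejected(self, rng):
        z = standardize(rng.normal(size=(50, 3)))
        with pytest.raises(ValueError, match="cycle"):
            gaussian_bic({0: [1], 1: [0], 2: []}, z)


class TestLassoCandidates:
    def test_pure_noise_target_gets_no_parents(self, rng):
        z = standardize(rng.normal(size=(5000, 4)))
        assert lasso_parent_candidates(z, 0) == frozenset()

    def test_single_true_parent_found_and_matches_subset_oracle(self):
        """x3 = 0.8 x1 + eps in a 4-node system: the lasso-path screen must
        return {x1}, the same support an exhaustive per-family BIC search
        over all 2^3 parent subsets selects."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(5000, 4))
        x[:, 3] = 0.8 * x[:, 1] + rng.normal(size=5000)
        z = standardize(x)
        got = lasso_parent_candidates(z, 3)
        scorer = FamilyScorer(z)
        oracle = max(
            (frozenset(s) for r in range(4) for s in itertools.combinations([0, 1, 2], r)),
            key=lambda s: scorer.family_score(3, s),
        )
        assert got == oracle == frozenset({1})

    def test_path_starts_empty_at_critical_lambda(self, rng):
        from sklearn.linear_model import lasso_path

        z = standardize(rng.normal(size=(300, 3)))
        x, y = z.data[:, 1:], z.data[:, 0]
        lam_max = np.max(np.abs(x.T @ y)) / len(y)
        _, coefs, _ = lasso_path(x, y, alphas=[lam_max])
        assert np.all(coefs == 0)

    def test_non_descending_grid_rejected(self, rng):
        z = standardize(rng.normal(size=(50, 3)))
        with pytest.raises(ValueError):
            lasso_parent_candidates(z, 0, lambda_grid=np.array([0.1, 0.5]))


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self, rng):
        z = standardize(rng.normal(size=(5000, 4)))
        struct = hill_climb_dag(z, n_restarts=5, seed=0)
        assert all(len(p) == 0 for p in struct.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search_on_4_nodes(self, seed):
        """The climbed score must equal the maximum of the BIC over all 543
        labelled 4-node DAGs (the full oracle sweep lives in the acceptance
        suite; this spot-checks ten datasets)."""
        dag = random_dag(4, seed)
        z = standardize(simulate_subject(dag, 1000, seed=1000 + seed).data)
        scorer = FamilyScorer(z)
        best = max(scorer.total_score(s) for s in ALL_4NODE_DAGS)
        struct = hill_climb_dag(z, n_restarts=10, seed=0)
        assert gaussian_bic(struct, z) == pytest.approx(best, abs=1e-9)

    def test_deterministic_and_acyclic(self, rng):
        z = standardize(rng.normal(size=(400, 5)))
        a = hill_climb_dag(z, n_restarts=10, seed=3)
        b = hill_climb_dag(z, n_restarts=10, seed=3)
        assert a == b
        gaussian_bic(a, z)  # raises if cyclic

    def test_local_optimum_over_move_set(self):
        """No single add/delete/reverse inside the move set improves the
        returned structure's score."""
        dag = random_dag(5, seed=42)
        z = standardize(simulate_subject(dag, 800, seed=8).data)
        struct = hill_climb_dag(z, n_restarts=5, seed=0)
        score = gaussian_bic(struct, z)
        k = 5
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                trial = {n: set(p) for n, p in struct.items()}
                if i in struct[j]:
                    trial[j].discard(i)  # delete
                else:
                    trial[j].add(i)  # add
                try:
                    assert gaussian_bic(trial, z) <= score + 1e-9
                except ValueError:
                    pass  # cyclic: not in the move set
                if i in struct[j]:
                    rev = {n: set(p) for n, p in struct.items()}
                    rev[j].discard(i)
                    rev[i].add(j)
                    try:
                        assert gaussian_bic(rev, z) <= score + 1e-9
                    except ValueError:
                        pass


ALL_4NODE_DAGS = all_dag_structures(4)


def test_there_are_543_labelled_4node_dags():
    assert len(ALL_4NODE_DAGS) == 543


class TestFitWeights:
    def test_noiseless_relation_recovered_exactly(self):
        x1 = np.linspace(-2, 2, 101)
        data = np.column_stack([x1, 0.7 * x1])
        z_cols = data / data.std(axis=0)
        z = StandardizedData(z_cols - z_cols.mean(axis=0), ["x1", "x2"])
        model = fit_weights_ml({0: [], 1: [0]}, z)
        # standardized: x2 = x1 exactly (correlation 1)
        assert model.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_population_coefficients_recovered(self, dag_ec):
        """Fitted weights at N=50000 with the true structure match the
        population standardized coefficients solved from the implied
        covariance (normal equations per family) within 0.02."""
        z = standardize(simulate_subject(dag_ec, 50_000, seed=21).data,
                        node_names=dag_ec.node_names)
        model = fit_weights_ml(dag_ec.parent_sets(), z)
        sigma = dag_ec.implied_covariance()
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        for j, parents in dag_ec.parent_sets().items():
            if not parents:
                continue
            p = sorted(parents)
            beta = np.linalg.solve(corr[np.ix_(p, p)], corr[p, j])
            assert np.allclose(model.weights[p, j], beta, atol=0.02)

    def test_empty_structure_all_zero_weights(self, rng):
        z = standardize(rng.normal(size=(500, 3)))
        model = fit_weights_ml({0: [], 1: [], 2: []}, z)
        assert np.all(model.weights == 0)
        assert np.allclose(model.noise_sd, 1.0)


class TestLearnBN:
    def test_recovers_ec_equivalence_class_at_large_n(self, dag_ec):
        z = standardize(simulate_subject(dag_ec, 4600, seed=0).data,
                        node_names=dag_ec.node_names)
        model = learn_bn(z)
        assert markov_equivalent(model, dag_ec.parent_sets())
        assert model.bic >= gaussian_bic({j: [] for j in range(9)}, z)

    def test_independent_noise_gives_empty_model(self, rng):
        z = standardize(rng.normal(size=(5000, 4)))
        model = learn_bn(z)
        assert np.all(model.weights == 0)


class TestGroupAndFeatures:
    def test_group_bn_contains_shared_strong_edges(self, default_cohort):
        """The five high-weight edges common to both published networks must
        appear in the learned EC group model at the default scale."""
        model = group_bn(default_cohort, "EC", BNLearnConfig(seed=0))
        edges = {(s, t) for s, t, _ in model.edges()}
        for edge in [("SN", "aDMN"), ("SN", "pDMN"), ("HVN", "PVN"),
                     ("PSMN", "PVN"), ("aDMN", "DAN")]:
            assert edge in edges

    def test_group_bn_unknown_condition(self, default_cohort):
        with pytest.raises(ValueError, match="condition"):
            group_bn(default_cohort, "REM")

    def test_feature_table_shape_and_zero_diagonal(self, default_features):
        assert default_features.matrix.shape == (40, 81)
        k = 9
        diag_cols = [k * i + i for i in range(k)]
        assert np.all(default_features.matrix[:, diag_cols] == 0)
        assert sorted(set(default_features.labels)) == ["EC", "EO"]

    def test_feature_column_layout(self, default_features):
        names = default_features.node_names
        for si, s in enumerate(names):
            for ti, t in enumerate(names):
                assert default_features.column_index(s, t) == 9 * si + ti

    def test_identical_recordings_give_identical_rows(self, dag_ec, dag_eo):
        cohort = simulate_cohort(dag_ec, dag_eo, 2, 120, 0.0, master_seed=4)
        # duplicate subject 1's EC data into subject 2's EC slot
        cohort.recordings[2].data = cohort.recordings[0].data.copy()
        ft = subject_feature_table(cohort, BNLearnConfig(seed=0))
        assert np.array_equal(ft.matrix[0], ft.matrix[2])


class TestEdgeStats:
    def _table(self, matrix, labels=None, names=("a", "b", "c")):
        n = matrix.shape[0]
        labels = labels or ["EC"] * n
        return FeatureTable(
            matrix=matrix, node_names=list(names),
            labels=labels, subject_ids=[f"s{i}" for i in range(n)],
        )

    def test_identically_zero_column_not_significant(self):
        ft = self._table(np.zeros((10, 9)))
        stats = edge_group_stats(ft, "EC")
        assert all(e.p_value == 1.0 and not e.significant for e in stats)

    def test_constant_plus_tiny_noise_is_significant(self, rng):
        m = np.zeros((20, 9))
        m[:, 1] = 2.0 + rng.normal(0, 0.01, size=20)  # edge a->b
        stats = edge_group_stats(self._table(m), "EC")
        by_edge = {(e.source, e.target): e for e in stats}
        assert by_edge[("a", "b")].significant
        assert by_edge[("a", "b")].p_value < 1e-10

    def test_alpha_zero_nothing_significant(self, rng):
        m = np.zeros((10, 9))
        m[:, 1] = 5.0 + rng.normal(0, 0.1, size=10)
        stats = edge_group_stats(self._table(m), "EC", alpha=0.0)
        assert not any(e.significant for e in stats)

    def test_too_few_rows_rejected(self):
        ft = self._table(np.zeros((4, 9)), labels=["EC", "EC", "EO", "EO"])
        with pytest.raises(ValueError):
            edge_group_stats(ft, "EC")

    def test_diagonal_excluded(self):
        stats = edge_group_stats(self._table(np.zeros((5, 9))), "EC")
        assert len(stats) == 6  # 3*3 - 3
        assert all(e.source != e.target for e in stats)
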