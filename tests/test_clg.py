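import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coremir import clg
from coremir.engines_io import ExpressionDataset, build_candidate_pool
from coremir.functional import CmiConfig
from coremir.hierarchy import InteractionRanking, ScoredInteraction
from coremir.structural import build_consistency_matrix, structural_scores


def make_ranking(pairs):
    items = [
        ScoredInteraction(mirna=m, gene=g, si=0.5, fi=0.2, presence_mask="1100",
                          struct_rank=i + 1, func_rank=i + 1, final_rank=i + 1)
        for i, (m, g) in enumerate(pairs)
    ]
    return InteractionRanking(interactions=items, mode="alternative", ties="isolated")


def dataset_from(matrix: pd.DataFrame, y) -> ExpressionDataset:
    roles = pd.Series(
        ["mirna" if c.startswith("hsa-") else "mrna" for c in matrix.columns],
        index=matrix.columns,
    )
    return ExpressionDataset(matrix=matrix, feature_roles=roles,
                             class_vector=np.asarray(y))


class TestBuildTopology:
    def test_shared_mirna_parent(self):
        ranking = make_ranking([("hsa-miR-1", "G1"), ("hsa-miR-1", "G2")])
        topo = clg.build_topology(ranking, 2)
        assert topo.mirnas == ["hsa-miR-1"]
        assert set(topo.edges()) == {("hsa-miR-1", "G1"), ("hsa-miR-1", "G2")}

    def test_multi_parent_mrna(self):
        ranking = make_ranking([("hsa-miR-1", "G1"), ("hsa-miR-2", "G1")])
        topo = clg.build_topology(ranking, 2)
        assert topo.parents["G1"] == ["hsa-miR-1", "hsa-miR-2"]

    def test_k_boundary_includes_everything(self):
        pairs = [("hsa-miR-1", "G1"), ("hsa-miR-2", "G2"), ("hsa-miR-3", "G3")]
        ranking = make_ranking(pairs)
        topo = clg.build_topology(ranking, len(ranking))
        assert topo.interactions == pairs

    def test_k_out_of_range(self):
        ranking = make_ranking([("hsa-miR-1", "G1")])
        with pytest.raises(ValueError):
            clg.build_topology(ranking, 0)
        with pytest.raises(ValueError):
            clg.build_topology(ranking, 2)

    def test_graph_is_acyclic(self):
        import networkx as nx
        pairs = [(f"hsa-miR-{i}", f"G{j}") for i in range(1, 4) for j in range(1, 4)]
        ranking = make_ranking(pairs)
        topo = clg.build_topology(ranking, 9)
        g = nx.DiGraph(topo.edges())
        assert nx.is_directed_acyclic_graph(g)


class TestFitParameters:
    def test_mirna_mle_by_hand(self):
        m = pd.DataFrame({
            "hsa-miR-1": [1.0, 2.0, 3.0, 9.0, 10.0, 11.0],
            "G1": [0.0, 0.5, 0.0, 1.0, 1.0, 2.0],
        })
        y = [0, 0, 0, 1, 1, 1]
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        mu0, var0 = params.mirna_params["hsa-miR-1"][0]
        assert mu0 == pytest.approx(2.0)
        assert var0 == pytest.approx(2 / 3)  # MLE divides by n_c
        assert params.class_prior == {0: 0.5, 1: 0.5}

    def test_ols_recovery(self):
        rng = np.random.default_rng(0)
        n = 2000
        mirna = rng.normal(0, 1, 2 * n)
        gene = 3.0 - 2.0 * mirna + rng.normal(0, 0.5, 2 * n)
        m = pd.DataFrame({"hsa-miR-1": mirna, "G1": gene})
        y = np.repeat([0, 1], n)
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        for c in (0, 1):
            b0, beta, var = params.mrna_params["G1"][c]
            assert b0 == pytest.approx(3.0, rel=0.05)
            assert beta[0] == pytest.approx(-2.0, rel=0.05)
            assert var == pytest.approx(0.25, rel=0.05)

    def test_variance_floor_applied(self):
        mirna = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        m = pd.DataFrame({
            "hsa-miR-1": mirna,
            "G1": [2 * v for v in mirna],  # exact linear response, zero residual
        })
        y = [0, 0, 0, 1, 1, 1]
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        for c in (0, 1):
            assert params.mrna_params["G1"][c][2] >= clg.VARIANCE_FLOOR

    def test_constant_parent_design_raises(self):
        m = pd.DataFrame({
            "hsa-miR-1": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
            "G1": [5.0, 5.1, 4.9, 5.0, 5.2, 5.1],
        })
        y = [0, 0, 0, 1, 1, 1]
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        with pytest.raises(np.linalg.LinAlgError, match="G1"):
            clg.fit_parameters(topo, dataset_from(m, y))

    def test_parameter_recovery_from_known_clg(self):
        """mu/beta within 3%, variances within 10%, over 10 seeds at n=5000."""
        truth = dict(mu={0: 1.5, 1: -1.5}, sig={0: 1.5, 1: 0.8},
                     b0={0: 4.0, 1: -3.0}, b={0: 2.0, 1: -1.5},
                     noise={0: 0.6, 1: 1.1})
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            y = np.repeat([0, 1], n)
            mirna = np.concatenate([
                rng.normal(truth["mu"][c], np.sqrt(truth["sig"][c]), n) for c in (0, 1)
            ])
            gene = np.concatenate([
                truth["b0"][c] + truth["b"][c] * mirna[y == c]
                + rng.normal(0, np.sqrt(truth["noise"][c]), n)
                for c in (0, 1)
            ])
            params = clg.fit_parameters(
                topo, dataset_from(pd.DataFrame({"hsa-miR-1": mirna, "G1": gene}), y))
            for c in (0, 1):
                mu, sig = params.mirna_params["hsa-miR-1"][c]
                b0, beta, noise = params.mrna_params["G1"][c]
                assert mu == pytest.approx(truth["mu"][c], rel=0.03)
                assert sig == pytest.approx(truth["sig"][c], rel=0.10)
                assert b0 == pytest.approx(truth["b0"][c], rel=0.03)
                assert beta[0] == pytest.approx(truth["b"][c], rel=0.03)
                assert noise == pytest.approx(truth["noise"][c], rel=0.10)

    def test_too_few_samples_raises(self):
        m = pd.DataFrame({"hsa-miR-1": [1.0, 2.0, 3.0], "G1": [1.0, 2.0, 3.0]})
        topo = clg.build_topology(make_ranking([("hsa-miR-1", "G1")]), 1)
        with pytest.raises(ValueError, match="fewer"):
            clg.fit_parameters(topo, dataset_from(m, [0, 0, 1]))


def single_node_model(mu0=0.0, mu1=0.0, var0=1.0, var1=1.0, prior0=0.5):
    topo = clg.NetworkTopology(mirnas=["hsa-miR-1"], mrnas=[], parents={},
                               interactions=[("hsa-miR-1", "G1")], k=1)
    params = clg.CLGParameters(
        class_prior={0: prior0, 1: 1 - prior0},
        mirna_params={"hsa-miR-1": {0: (mu0, var0), 1: (mu1, var1)}},
        mrna_params={},
    )
    return topo, params


class TestLogJointAndPrediction:
    def test_hand_value_single_gaussian_node(self):
        topo, params = single_node_model()
        x = pd.DataFrame({"hsa-miR-1": [0.0]})
        expected = np.log(0.5) - 0.5 * np.log(2 * np.pi)
        assert clg.log_joint(params, topo, x, 0)[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_toward_class_mean(self):
        topo, params = single_node_model(mu0=2.0)
        xs = pd.DataFrame({"hsa-miR-1": [5.0, 4.0, 3.0, 2.0]})
        lj = clg.log_joint(params, topo, xs, 0)
        assert np.all(np.diff(lj) > 0)

    def test_additivity_over_nodes(self):
        rng = np.random.default_rng(1)
        n = 200
        y = np.repeat([0, 1], n)
        m = pd.DataFrame({
            "hsa-miR-1": rng.normal(0, 1, 2 * n) + y,
            "hsa-miR-2": rng.normal(5, 2, 2 * n),
            "G1": rng.normal(1, 1, 2 * n),
        })
        ranking = make_ranking([("hsa-miR-1", "G1"), ("hsa-miR-2", "G1")])
        topo = clg.build_topology(ranking, 2)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        lj = clg.log_joint(params, topo, m.head(5), 0)
        # per-node terms computed independently
        total = np.full(5, np.log(params.class_prior[0]))
        for node in topo.mirnas:
            mu, var = params.mirna_params[node][0]
            total += stats.norm.logpdf(m[node].head(5), mu, np.sqrt(var))
        b0, beta, var = params.mrna_params["G1"][0]
        mean = b0 + m[topo.parents["G1"]].head(5).to_numpy() @ beta
        total += stats.norm.logpdf(m["G1"].head(5), mean, np.sqrt(var))
        np.testing.assert_allclose(lj, total, rtol=1e-12)

    def test_missing_node_column_raises(self):
        topo, params = single_node_model()
        with pytest.raises(KeyError, match="hsa-miR-1"):
            clg.log_joint(params, topo, pd.DataFrame({"other": [1.0]}), 0)

    def test_symmetric_classes_give_half(self):
        topo, params = single_node_model()
        proba = clg.predict_proba(params, topo, pd.DataFrame({"hsa-miR-1": [0.7]}))
        np.testing.assert_allclose(proba, [[0.5, 0.5]])
        assert clg.predict(params, topo, pd.DataFrame({"hsa-miR-1": [0.7]}))[0] == 0

    def test_separated_means_log_odds_50(self):
        topo, params = single_node_model(mu0=0.0, mu1=10.0)
        proba = clg.predict_proba(params, topo, pd.DataFrame({"hsa-miR-1": [0.0]}))
        assert proba[0, 0] == pytest.approx(1 / (1 + np.exp(-50)))

    def test_rows_sum_to_one_and_no_overflow(self):
        topo, params = single_node_model(mu0=0.0, mu1=1.0, var0=1e-4, var1=1e-4)
        x = pd.DataFrame({"hsa-miR-1": np.linspace(-100, 100, 50)})
        proba = clg.predict_proba(params, topo, x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.isfinite(proba))

    def test_posterior_matches_brute_force_densities(self):
        """Likelihood-based posterior equals direct density evaluation."""
        rng = np.random.default_rng(2)
        n = 100
        y = np.repeat([0, 1], n)
        m = pd.DataFrame({
            "hsa-miR-1": rng.normal(0, 1, 2 * n) + 2 * y,
            "hsa-miR-2": rng.normal(3, 1, 2 * n) - y,
            "G1": rng.normal(0, 1, 2 * n),
            "G2": rng.normal(0, 1, 2 * n),
        })
        ranking = make_ranking([
            ("hsa-miR-1", "G1"), ("hsa-miR-2", "G1"), ("hsa-miR-2", "G2"),
        ])
        topo = clg.build_topology(ranking, 3)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        proba = clg.predict_proba(params, topo, m.head(10))
        # brute force: plain products of scipy densities, no log space
        for i in range(10):
            row = m.iloc[[i]]
            dens = []
            for c in (0, 1):
                d = params.class_prior[c]
                for node in topo.mirnas:
                    mu, var = params.mirna_params[node][c]
                    d *= stats.norm.pdf(row[node].iloc[0], mu, np.sqrt(var))
                for node in topo.mrnas:
                    b0, beta, var = params.mrna_params[node][c]
                    mean = b0 + (row[topo.parents[node]].to_numpy() @ beta).item()
                    d *= stats.norm.pdf(row[node].iloc[0], mean, np.sqrt(var))
                dens.append(d)
            expected = dens[1] / (dens[0] + dens[1])
            assert proba[i, 1] == pytest.approx(expected, abs=1e-12)


class TestSweepK:
    @pytest.fixture(scope="class")
    def study(self, informative_study):
        spec, panel, _, data = informative_study
        pool = build_candidate_pool(data, panel)
        cm = build_consistency_matrix(panel)
        si = structural_scores(pool, cm)
        return data, pool, si

    def test_reproducible_for_same_seed(self, study):
        data, pool, si = study
        kwargs = dict(k_max=3, folds=3, repeats=1, seed=5,
                      cmi_cfg=CmiConfig(precision=24))
        a = clg.sweep_k(data, pool, si, **kwargs)
        b = clg.sweep_k(data, pool, si, **kwargs)
        np.testing.assert_array_equal(a.accuracy_mean, b.accuracy_mean)
        np.testing.assert_array_equal(a.auc_mean, b.auc_mean)
        assert a.best_k == b.best_k

    def test_signal_beats_k1_and_metrics_bounded(self, study):
        data, pool, si = study
        result = clg.sweep_k(data, pool, si, k_max=6, folds=3, repeats=1,
                             seed=0, cmi_cfg=CmiConfig(precision=24))
        assert np.all((result.accuracy_mean >= 0) & (result.accuracy_mean <= 1))
        assert np.all((result.auc_mean >= 0) & (result.auc_mean <= 1))
        assert 1 <= result.best_k <= 6
        assert result.accuracy_mean.max() > result.accuracy_mean[0]

    def test_permuted_labels_near_chance(self, informative_study):
        spec, panel, _, data = informative_study
        accs = []
        for perm_seed in range(3):
            rng = np.random.default_rng(perm_seed)
            permuted = ExpressionDataset(
                matrix=data.matrix,
                feature_roles=data.feature_roles,
                class_vector=rng.permutation(data.class_vector),
            )
            pool = build_candidate_pool(permuted, panel)
            cm = build_consistency_matrix(panel)
            si = structural_scores(pool, cm)
            result = clg.sweep_k(permuted, pool, si, k_max=2, folds=3, repeats=1,
                                 seed=1, cmi_cfg=CmiConfig(precision=24))
            accs.append(result.accuracy_mean[-1])
        n_tests = 3 * len(data.class_vector)
        assert abs(np.mean(accs) - 0.5) < 3 * 0.5 / np.sqrt(n_tests)

    def test_class_smaller_than_folds_raises(self, study):
        data, pool, si = study
        tiny = ExpressionDataset(
            matrix=data.matrix.iloc[:4],
            feature_roles=data.feature_roles,
            class_vector=np.array([0, 0, 0, 1]),
        )
        with pytest.raises(ValueError, match="fewer"):
            clg.sweep_k(tiny, pool, si, k_max=2, folds=3)


class TestSerialization:
    def test_round_trip_exact(self, tmp_path, study=None):
        rng = np.random.default_rng(3)
        n = 50
        y = np.repeat([0, 1], n)
        m = pd.DataFrame({
            "hsa-miR-1": rng.normal(0, 1, 2 * n),
            "G1": rng.normal(0, 1, 2 * n),
            "G2": rng.normal(0, 1, 2 * n),
        })
        ranking = make_ranking([("hsa-miR-1", "G1"), ("hsa-miR-1", "G2")])
        topo = clg.build_topology(ranking, 2)
        params = clg.fit_parameters(topo, dataset_from(m, y))
        path = tmp_path / "model.json"
        clg.save_model(path, topo, params)
        topo2, params2 = clg.load_model(path)
        assert topo2.parents == topo.parents
        assert topo2.interactions == topo.interactions
        assert params2.class_prior == params.class_prior
        for node in topo.mirnas:
            for c in (0, 1):
                assert params2.mirna_params[node][c] == tuple(params.mirna_params[node][c])
        for node in topo.mrnas:
            for c in (0, 1):
                b0a, betaa, vara = params.mrna_params[node][c]
                b0b, betab, varb = params2.mrna_params[node][c]
                assert b0b == b0a and varb == vara
                np.testing.assert_array_equal(betab, betaa)
        # predictions identical through the round trip
        np.testing.assert_array_equal(
            clg.predict_proba(params, topo, m.head(5)),
            clg.predict_proba(params2, topo2, m.head(5)),
        )
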