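"""Network inference: biweight midcorrelation against a definitional
oracle, the edge test, BH correction, CLR, glasso + StARS, and graph
statistics against brute-force enumeration."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from digestnet.datatypes import ValidationError
from digestnet.network import (
    NetworkConfig,
    avg_clustering_coefficient,
    bh_adjust,
    bicor,
    bicor_matrix,
    build_network,
    clr_transform,
    correlation_test,
    edge_statistics,
    sparse_precision_network,
)
from digestnet.simulate import (
    GuildModule,
    SimulationScenario,
    simulate_timeseries,
)


def bicor_oracle(x, y):
    """Literal transcription of the biweight-midcorrelation definition,
    kept independent of the library implementation."""
    out = []
    for v in (np.asarray(x, float), np.asarray(y, float)):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        out.append((v - med) * w)
    a, b = out
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


class TestBicor:
    def test_identity_and_affine(self):
        x = np.arange(1.0, 21.0)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -2.0 * x + 5.0) == pytest.approx(-1.0)

    def test_outlier_case_matches_definitional_oracle(self):
        x = np.arange(1.0, 21.0)
        y = x.copy()
        y[-1] = 1000.0
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        assert bicor(x, y) > abs(stats.pearsonr(x, y)[0])

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(25):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_approximates_pearson_on_gaussian_data(self, rng):
        # u = (x - med) / (9 MAD) is scale-free, so Tukey weights are never
        # literally all 1 on continuous data; on outlier-free Gaussian data
        # no point is rejected and bicor tracks Pearson closely
        x = rng.normal(0, 1e-3, size=2000) + 5
        y = 0.5 * x + rng.normal(0, 1e-3, size=2000)
        assert bicor(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=0.05)

    def test_zero_mad_falls_back_to_pearson_with_warning(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 8.0, 1.0, 1.0])  # MAD = 0
        y = np.arange(7.0)
        with pytest.warns(UserWarning, match="zero MAD"):
            r = bicor(x, y)
        assert abs(r) <= 1.0

    def test_matrix_agrees_with_pairwise(self, rng):
        data = rng.lognormal(size=(30, 6))
        m = bicor_matrix(data)
        for i, j in itertools.combinations(range(6), 2):
            assert m[i, j] == pytest.approx(
                bicor(data[:, i], data[:, j]), abs=1e-12
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            bicor([1.0, 2.0], [3.0, 4.0])


class TestCorrelationTest:
    def test_zero_correlation(self):
        res = correlation_test(0.0, 10)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.df == 8

    def test_hand_formula_r_half_n4(self):
        res = correlation_test(0.5, 4)
        t_hand = 0.5 * np.sqrt(2) / np.sqrt(0.75)  # 0.81650
        assert res.t == pytest.approx(t_hand, abs=1e-5)
        assert res.p == pytest.approx(2 * stats.t.sf(t_hand, 2), abs=1e-12)

    def test_perfect_correlation_flagged_exact(self):
        res = correlation_test(1.0, 5)
        assert res.p == 0.0
        assert res.exact


class TestBhAdjust:
    def test_single_and_equal_and_hand_stepup(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9]
        )

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q.max() <= 1.0


def _scenario_table(seed, n_asvs=30, n_samples=40, modules=(), depth=200_000):
    blocks = (("SOI", 0, n_samples // 2), ("SER", n_samples // 2, n_samples))
    sc = SimulationScenario(
        n_samples=n_samples, n_asvs=n_asvs, configuration_blocks=blocks,
        guild_modules=modules, depth=depth, seed=seed,
    )
    return simulate_timeseries(sc)


class TestBuildNetwork:
    def test_planted_two_member_module_recovered(self):
        mod = GuildModule(members=(0, 1), guilds=("syntroph", "syntroph"),
                          rho=0.9, shifted_configuration=None)
        table, _, _, truth = _scenario_table(11, modules=(mod,), n_samples=60)
        net = build_network(table)
        assert net.has_edge("ASV0000", "ASV0001")

    def test_low_prevalence_node_excluded(self):
        table, _, _, _ = _scenario_table(3)
        counts = table.counts.copy()
        row = np.zeros(40, dtype=int)
        row[:9] = 5  # 22.5 % prevalence < 25 %
        counts.loc["rare"] = row
        table2 = type(table)(counts, table.sample_dates, table.configuration)
        net = build_network(table2)
        assert "rare" not in net.nodes

    def test_deterministic(self):
        table, _, _, _ = _scenario_table(5)
        n1 = build_network(table)
        n2 = build_network(table)
        assert sorted(n1.edges()) == sorted(n2.edges())
        for u, v in n1.edges():
            assert n1.edges[u, v]["weight"] == n2.edges[u, v]["weight"]

    def test_node_attribute_mean_relative_abundance(self):
        table, _, _, _ = _scenario_table(5)
        net = build_network(table)
        rel = table.counts / table.counts.sum(axis=0)
        node = next(iter(net.nodes))
        assert net.nodes[node]["mean_rel_abundance"] == pytest.approx(
            rel.loc[node].mean()
        )

    def test_pooled_fdr_within_budget(self):
        """Pooled false-discovery proportion over 50 seeded runs with one
        planted correlated block stays within 1.5x the nominal q<0.05 level.

        The fixture uses independent per-ASV counts (no compositional
        closure) so that non-block pairs are genuinely uncorrelated and the
        Student-t null applies; closure-induced correlations are a separate,
        documented property of compositional data.
        """
        import datetime as dt

        true_edges = {frozenset((f"a{i}", f"a{j}"))
                      for i in range(5) for j in range(i + 1, 5)}
        v = r = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            n, p = 40, 30
            latent = g.standard_normal((p, n))
            shared = g.standard_normal(n)
            # block of 5 with latent correlation 0.8
            latent[:5] = np.sqrt(0.8) * shared + np.sqrt(0.2) * latent[:5]
            counts = g.poisson(np.exp(latent + 5.0))
            samples = [f"s{j}" for j in range(n)]
            from digestnet.datatypes import AbundanceTable

            table = AbundanceTable(
                pd.DataFrame(counts, index=[f"a{i}" for i in range(p)],
                             columns=samples),
                pd.Series([dt.date(2017, 1, 1) + dt.timedelta(days=j)
                           for j in range(n)], index=samples),
                pd.Series(["A"] * 20 + ["B"] * 20, index=samples),
            )
            net = build_network(table)
            found = {frozenset(e) for e in net.edges()}
            r += len(found)
            v += len(found - true_edges)
        assert r > 0
        assert v / r <= 1.5 * 0.05


class TestClrTransform:
    def test_uniform_column_is_zero_and_scale_invariance(self):
        counts = pd.DataFrame({"s1": [5, 5, 5], "s2": [1, 2, 4]})
        clr = clr_transform(counts, pseudocount=1)
        np.testing.assert_allclose(clr["s1"], 0.0, atol=1e-12)
        np.testing.assert_allclose(clr.sum(axis=0), 0.0, atol=1e-9)
        # doubling counts (with pc -> 0 limit) leaves CLR unchanged
        clr_a = clr_transform(counts * 2, pseudocount=1e-9)
        clr_b = clr_transform(counts, pseudocount=1e-9)
        np.testing.assert_allclose(clr_a, clr_b, atol=1e-6)

    def test_three_part_hand_case(self):
        counts = pd.DataFrame({"s": [0, 1, 7]})
        clr = clr_transform(counts, pseudocount=1)
        x = np.array([1.0, 2.0, 8.0])
        expected = np.log(x) - np.mean(np.log(x))
        np.testing.assert_allclose(clr["s"], expected)


class TestSparsePrecisionNetwork:
    def _clr_from(self, cov, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n)
        frame = pd.DataFrame(x.T, index=[f"v{i}" for i in range(cov.shape[0])])
        return frame - frame.mean(axis=0)

    def test_lambda_max_gives_empty_graph(self):
        cov = np.eye(6) + 0.4 * (np.ones((6, 6)) - np.eye(6))
        clr = self._clr_from(cov, 100, 0)
        cfg = NetworkConfig(glasso_path_length=2, stars_subsamples=4, seed=0)
        net = sparse_precision_network(clr, cfg)
        assert net.graph["lambda_path"][0] >= max(net.graph["lambda_path"])

    def test_block_structure_recovered(self):
        """3 independent correlated blocks of 3 variables (staggered
        strengths 0.6/0.75/0.9) in an identity background, n=200: the
        StARS-selected graph's edges equal the true within-block pairs
        (precision = recall = 1).

        A strict instability threshold is used because with only
        C(24,2) = 276 candidate pairs a single flickering edge contributes
        ~0.002 average instability; the default 0.05 (tuned for
        hundreds-of-taxa problems) stops far too deep in the path here.
        """
        p = 24
        cov = np.eye(p)
        for b, rho in enumerate((0.6, 0.75, 0.9)):
            cov[3 * b:3 * b + 3, 3 * b:3 * b + 3] = (
                np.full((3, 3), rho) + (1 - rho) * np.eye(3)
            )
        clr = self._clr_from(cov, 200, 2)
        cfg = NetworkConfig(seed=2, stars_instability_threshold=0.01,
                            stars_subsamples=10, glasso_path_length=12)
        net = sparse_precision_network(clr, cfg)
        true = {frozenset((f"v{3 * b + i}", f"v{3 * b + j}"))
                for b in range(3)
                for i in range(3) for j in range(i + 1, 3)}
        assert {frozenset(e) for e in net.edges()} == true

    def test_iid_data_selects_sparse_graph(self):
        clr = self._clr_from(np.eye(15), 200, 2)
        net = sparse_precision_network(clr, NetworkConfig(seed=2))
        density = nx.density(net)
        assert density < 0.02

    def test_edge_set_monotone_along_path(self):
        """Fewer edges at stronger penalties (monotone non-increasing)."""
        from digestnet.network import _glasso_adjacency

        cov = np.cov(self._clr_from(
            np.eye(8) + 0.3 * (np.ones((8, 8)) - np.eye(8)), 120, 3
        ).to_numpy(), rowvar=True)
        lam_max = np.abs(cov - np.diag(np.diag(cov))).max()
        path = np.geomspace(lam_max, lam_max * 0.1, 8)
        sizes = []
        for lam in path:
            adj = _glasso_adjacency(cov, lam)
            sizes.append(adj.sum())
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestAvgClusteringCoefficient:
    def test_triangle_and_star(self):
        assert avg_clustering_coefficient(nx.complete_graph(3)) == 1.0
        assert avg_clustering_coefficient(nx.star_graph(3)) == 0.0

    def test_five_node_fixture_matches_triangle_enumeration(self):
        net = nx.Graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"),
             ("c", "e")]
        )

        def local_cc(g, v):
            nbrs = list(g.neighbors(v))
            k = len(nbrs)
            if k < 2:
                return 0.0
            links = sum(
                1 for x, y in itertools.combinations(nbrs, 2)
                if g.has_edge(x, y)
            )
            return 2 * links / (k * (k - 1))

        brute = np.mean([local_cc(net, v) for v in net.nodes])
        assert avg_clustering_coefficient(net) == pytest.approx(brute)

    def test_exclude_low_degree_convention(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        incl = avg_clustering_coefficient(net)
        excl = avg_clustering_coefficient(net, exclude_low_degree=True)
        assert excl >= incl

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            avg_clustering_coefficient(nx.Graph())


class TestEdgeStatistics:
    def test_t_and_q_consistent(self, rng):
        rel = pd.DataFrame(rng.lognormal(size=(8, 20)))
        e = edge_statistics(rel)
        row = e.iloc[0]
        res = correlation_test(row["r"], 20)
        assert row["t"] == pytest.approx(res.t)
        assert row["p"] == pytest.approx(res.p)
        np.testing.assert_allclose(
            e["q"].to_numpy(), bh_adjust(e["p"].to_numpy())
        )
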