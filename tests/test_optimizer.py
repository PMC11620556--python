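"""Clustered grey wolf optimizer: partitioning, roles, dynamics, encoding."""

import itertools

import numpy as np
import pytest

from kcbgwo import benchmarks, gwo
from kcbgwo.optimizer import (
    KCBGWOConfig,
    Pack,
    assign_roles,
    decode_candidate,
    encode_search_space,
    initialize_population,
    kmeans_partition,
    minimize,
)


class TestInitialization:
    def test_binary_bits_are_fair_coins(self, rng):
        cfg = KCBGWOConfig(pop_size=30, mode="binary")
        pack = initialize_population(cfg, 20, rng)
        bits = pack.positions
        assert set(np.unique(bits)) <= {0.0, 1.0}
        n = bits.size
        se = np.sqrt(0.25 / n)
        assert abs(bits.mean() - 0.5) <= 3 * se

    def test_continuous_within_bounds(self, rng):
        cfg = KCBGWOConfig(pop_size=10, mode="continuous", bounds=(-1, 1))
        pack = initialize_population(cfg, 5, rng)
        assert pack.positions.min() >= -1 and pack.positions.max() <= 1

    def test_same_seed_identical_packs(self):
        cfg = KCBGWOConfig(pop_size=8, mode="binary")
        a = initialize_population(cfg, 6, np.random.default_rng(3))
        b = initialize_population(cfg, 6, np.random.default_rng(3))
        assert np.array_equal(a.positions, b.positions)

    def test_missing_bounds_rejected(self, rng):
        cfg = KCBGWOConfig(pop_size=8, mode="continuous", bounds=None)
        with pytest.raises(ValueError, match="bounds"):
            initialize_population(cfg, 4, rng)


class TestKMeans:
    def test_single_cluster_centroid_is_grand_mean(self, rng):
        pts = rng.normal(size=(12, 4))
        model = kmeans_partition(pts, 1, rng=rng)
        assert np.allclose(model.centroids[0], pts.mean(axis=0), atol=1e-10)

    def test_recovers_two_separated_blobs(self, rng):
        a = 10.0 + 0.1 * rng.normal(size=(15, 3))
        b = -10.0 + 0.1 * rng.normal(size=(15, 3))
        pts = np.vstack([a, b])
        model = kmeans_partition(pts, 2, rng=rng)
        got = np.sort(model.centroids[:, 0])
        assert abs(got[0] + 10) < 0.5 and abs(got[1] - 10) < 0.5

    def test_objective_matches_brute_force_on_toy_data(self, rng):
        # two tight triads; exhaustive search over all 2^6 assignments
        pts = np.array(
            [[0.0, 0.0], [0.2, 0.1], [0.1, -0.1],
             [5.0, 5.0], [5.2, 4.9], [4.9, 5.1]]
        )
        best = np.inf
        for labels in itertools.product([0, 1], repeat=6):
            labels = np.array(labels)
            total = 0.0
            for k in (0, 1):
                members = pts[labels == k]
                if len(members):
                    total += ((members - members.mean(axis=0)) ** 2).sum()
            best = min(best, total)
        model = kmeans_partition(pts, 2, rng=rng)
        assert model.inertia == pytest.approx(best, rel=1e-10)

    def test_objective_non_increasing_and_centroids_are_means(self, rng):
        pts = rng.normal(size=(40, 6))
        trace: list = []
        model = kmeans_partition(pts, 4, rng=rng, trace=trace)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        for k in range(4):
            members = pts[model.assignments == k]
            if len(members):
                assert np.allclose(model.centroids[k], members.mean(axis=0),
                                   atol=1e-10)

    def test_assignments_partition_the_pack(self, rng):
        pts = rng.normal(size=(25, 3))
        model = kmeans_partition(pts, 5, rng=rng)
        assert model.assignments.shape == (25,)
        assert set(model.assignments) <= set(range(5))

    def test_agrees_with_sklearn_on_separated_data(self, rng):
        from sklearn.cluster import KMeans

        centers = np.array([[0, 0], [20, 0], [0, 20]], dtype=float)
        pts = np.vstack(
            [c + 0.2 * rng.normal(size=(20, 2)) for c in centers]
        )
        ours = kmeans_partition(pts, 3, rng=rng)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_more_clusters_than_wolves_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_partition(rng.normal(size=(3, 2)), 4, rng=rng)


class TestRoles:
    def _cluster_of_all(self, n):
        from kcbgwo.optimizer import ClusterModel

        return ClusterModel(
            n_clusters=1,
            centroids=np.zeros((1, 2)),
            assignments=np.zeros(n, dtype=int),
            inertia=0.0,
        )

    def test_fitness_order_assigns_roles(self):
        pack = Pack(np.zeros((4, 2)), np.array([0.3, 0.1, 0.2, 0.9]))
        roles = assign_roles(pack, self._cluster_of_all(4))
        assert roles.alpha[0] == 1
        assert roles.beta[0] == 2
        assert roles.delta[0] == 0
        assert list(roles.omega[0]) == [3]

    def test_ties_break_by_wolf_index(self):
        pack = Pack(np.zeros((4, 2)), np.array([1.0, 1.0, 1.0, 1.0]))
        roles = assign_roles(pack, self._cluster_of_all(4))
        assert (roles.alpha[0], roles.beta[0], roles.delta[0]) == (0, 1, 2)

    def test_global_best_matches_linear_scan(self, rng):
        n = 30
        fitness = rng.normal(size=n)
        pts = rng.normal(size=(n, 3))
        pack = Pack(pts, fitness)
        model = kmeans_partition(pts, 3, rng=rng)
        roles = assign_roles(pack, model)
        best = 0
        for i in range(n):
            if fitness[i] < fitness[best]:
                best = i
        assert roles.global_best_index == best
        assert roles.global_best_fitness == fitness[best]

    def test_small_cluster_reuses_best_wolf(self):
        from kcbgwo.optimizer import ClusterModel

        pack = Pack(np.zeros((5, 2)), np.array([0.5, 0.4, 9.0, 9.1, 9.2]))
        model = ClusterModel(
            n_clusters=2,
            centroids=np.zeros((2, 2)),
            assignments=np.array([0, 0, 1, 1, 1]),
            inertia=0.0,
        )
        roles = assign_roles(pack, model)
        assert roles.alpha[0] == 1 and roles.beta[0] == 0
        assert roles.delta[0] == 1  # missing role filled by the cluster's best

    def test_hierarchy_invariant_per_cluster(self, rng):
        n = 40
        pack = Pack(rng.normal(size=(n, 4)), rng.normal(size=n))
        model = kmeans_partition(pack.positions, 4, rng=rng)
        roles = assign_roles(pack, model)
        f = pack.fitness
        for c in range(4):
            assert f[roles.alpha[c]] <= f[roles.beta[c]] <= f[roles.delta[c]]
            for w in roles.omega[c]:
                assert f[roles.delta[c]] <= f[w]

    def test_unevaluated_pack_rejected(self):
        pack = Pack(np.zeros((4, 2)))
        with pytest.raises(RuntimeError):
            assign_roles(pack, self._cluster_of_all(4))


class TestMinimize:
    def test_sphere_reference_convergence(self):
        spec = benchmarks.get_objective("f1", 10)
        cfg = KCBGWOConfig(pop_size=30, iterations=200, n_clusters=3, seed=1)
        res = minimize(spec, cfg)
        assert res.best_fitness <= 1e-6

    def test_binary_onemax_finds_all_ones(self):
        d = 20
        cfg = KCBGWOConfig(pop_size=20, iterations=100, mode="binary",
                           seed=0, dim=d)
        res = minimize(lambda bits: float(d - bits.sum()), cfg)
        assert res.best_fitness == 0.0
        assert np.array_equal(res.best_position, np.ones(d))

    @pytest.mark.parametrize("mode,seed", [("continuous", 0), ("continuous", 4),
                                           ("binary", 0), ("binary", 4)])
    def test_history_non_increasing(self, mode, seed):
        spec = benchmarks.get_objective("f7", 8)
        cfg = KCBGWOConfig(pop_size=12, iterations=40, n_clusters=3,
                           mode=mode, seed=seed,
                           bounds=(-5.12, 5.12) if mode == "continuous" else None)
        if mode == "binary":
            res = minimize(lambda b: float(8 - b.sum()), KCBGWOConfig(
                pop_size=12, iterations=40, n_clusters=3, mode="binary",
                seed=seed, dim=8))
        else:
            res = minimize(spec, cfg)
        assert all(b <= a for a, b in zip(res.history, res.history[1:]))
        assert res.history[-1] == res.best_fitness
        assert len(res.history) == 41

    def test_binary_positions_stay_bits_continuous_stay_bounded(self):
        d = 10
        seen = []
        def probe(x):
            seen.append(x.copy())
            return float(np.sum(x * x))
        cfg = KCBGWOConfig(pop_size=8, iterations=20, mode="binary", seed=2, dim=d)
        minimize(probe, cfg)
        assert all(set(np.unique(x)) <= {0.0, 1.0} for x in seen)

        seen.clear()
        spec = benchmarks.get_objective("f1", d)
        minimize(spec, KCBGWOConfig(pop_size=8, iterations=20, seed=2))
        assert all((x >= -100).all() and (x <= 100).all() for x in seen)

    def test_early_stop_triggers_iff_threshold_met(self):
        spec = benchmarks.get_objective("f1", 5)
        stopping = minimize(spec, KCBGWOConfig(pop_size=20, iterations=300,
                                               seed=3, threshold=1e-3))
        assert stopping.config["stopped_early"]
        assert stopping.best_fitness <= 1e-3
        assert len(stopping.history) < 301

        full = minimize(spec, KCBGWOConfig(pop_size=20, iterations=50, seed=3,
                                           threshold=-1.0))
        assert not full.config["stopped_early"]
        assert len(full.history) == 51

    def test_single_cluster_run_equals_plain_gwo(self):
        spec = benchmarks.get_objective("f3", 12)
        cfg = KCBGWOConfig(pop_size=10, iterations=50, n_clusters=1, seed=7)
        ours = minimize(spec, cfg)
        ref = gwo.gwo_minimize(spec, pop_size=10, iterations=50, seed=7)
        assert ours.history == ref.history
        assert np.array_equal(ours.best_position, ref.best_position)

    def test_seeded_determinism(self):
        spec = benchmarks.get_objective("f9", 6)
        cfg = KCBGWOConfig(pop_size=10, iterations=30, seed=9)
        a = minimize(spec, cfg)
        b = minimize(spec, KCBGWOConfig(pop_size=10, iterations=30, seed=9))
        assert a.history == b.history

    def test_objective_errors_carry_iteration_context(self):
        calls = {"n": 0}
        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 12:
                raise RuntimeError("bad evaluation")
            return float(x.sum())
        cfg = KCBGWOConfig(pop_size=8, iterations=10, mode="binary", seed=1, dim=4)
        with pytest.raises(RuntimeError):
            minimize(flaky, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KCBGWOConfig(pop_size=3).validate()
        with pytest.raises(ValueError):
            KCBGWOConfig(pop_size=10, n_clusters=11).validate()
        with pytest.raises(ValueError):
            KCBGWOConfig(threshold=float("inf")).validate()


class TestSearchSpaceEncoding:
    def test_three_choice_parameter_wraps_modulo(self):
        enc = encode_search_space([("width", (4, 8, 16))])
        assert enc.total_bits == 2
        decoded = [decode_candidate(bits, enc)["width"]
                   for bits in ([0, 0], [0, 1], [1, 0], [1, 1])]
        assert decoded == [4, 8, 16, 4]

    def test_binary_flags_decode_identity(self):
        enc = encode_search_space([(f"flag{i}", (0, 1)) for i in range(3)])
        assert enc.total_bits == 3
        for bits in itertools.product([0, 1], repeat=3):
            setting = decode_candidate(np.array(bits), enc)
            assert tuple(setting.values()) == bits

    def test_every_bit_string_decodes_in_domain(self):
        space = [("lr", (0.1, 0.01, 0.001)), ("depth", tuple(range(5))),
                 ("act", ("relu", "tanh"))]
        enc = encode_search_space(space)
        assert enc.total_bits <= 12
        domains = dict(space)
        for bits in itertools.product([0, 1], repeat=enc.total_bits):
            setting = decode_candidate(np.array(bits), enc)
            for name, value in setting.items():
                assert value in domains[name]

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            encode_search_space([("p", ())])

    def test_wrong_bit_length_rejected(self):
        enc = encode_search_space([("p", (1, 2, 3, 4))])
        with pytest.raises(ValueError):
            decode_candidate([0, 1, 1], enc)
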