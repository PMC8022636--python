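import numpy as np
import pytest

from mowoats import (
    AlgorithmConfig,
    DomainError,
    EliteList,
    ShapeError,
    Solution,
    SyntheticSpec,
    crossover_phase,
    crossover_solutions,
    generate_dataset,
    init_population,
    mowoats_step,
    run_mowoats,
    woa_encircle,
    woa_spiral,
    woa_update_params,
)


def small_config(**kw):
    defaults = dict(k=3, seed=5, max_it=4, n_whales=4, bounds=np.array([[-5.0, 5.0]] * 4))
    defaults.update(kw)
    return AlgorithmConfig(**defaults)


@pytest.fixture
def blob20():
    spec = SyntheticSpec(n_genes=20, n_features=4, k=3, seed=2)
    matrix, labels = generate_dataset(spec)
    return matrix


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(DomainError):
            AlgorithmConfig(k=1)
        with pytest.raises(DomainError):
            AlgorithmConfig(k=2, p_threshold=1.5)
        with pytest.raises(DomainError):
            AlgorithmConfig(k=2, metric="cosine")

    def test_bounds_from_data(self):
        cfg = AlgorithmConfig(k=2).with_bounds_from(np.array([[0.0, 5.0], [2.0, 1.0]]))
        np.testing.assert_array_equal(cfg.bounds, [[0, 2], [1, 5]])
        assert cfg.dim == 4


class TestInitPopulation:
    def test_rows_sampled_without_replacement(self):
        rng = np.random.default_rng(0)
        data = np.arange(30.0).reshape(10, 3)
        cfg = AlgorithmConfig(k=3, n_whales=4)
        for _ in range(250):  # 1000 solutions across repeats
            for sol in init_population(data, cfg, rng):
                rows = {tuple(c) for c in sol.centroids}
                assert len(rows) == 3
                for c in sol.centroids:
                    assert tuple(c) in {tuple(r) for r in data}

    def test_n_equals_k_is_permutation(self):
        rng = np.random.default_rng(1)
        data = np.arange(6.0).reshape(3, 2)
        cfg = AlgorithmConfig(k=3, n_whales=2)
        for sol in init_population(data, cfg, rng):
            assert sorted(map(tuple, sol.centroids)) == sorted(map(tuple, data))

    def test_fixed_seed_reproducible(self):
        data = np.random.default_rng(3).normal(size=(12, 3))
        cfg = AlgorithmConfig(k=4, n_whales=5)
        pops = [
            init_population(data, cfg, np.random.default_rng(42)) for _ in range(2)
        ]
        for a, b in zip(*pops):
            np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_n_below_k_rejected(self):
        with pytest.raises(DomainError):
            init_population(np.ones((2, 3)), AlgorithmConfig(k=3), np.random.default_rng(0))


class TestWOAParams:
    def test_schedule_endpoints(self):
        cfg = small_config(max_it=50)
        rng = np.random.default_rng(0)
        assert woa_update_params(0, cfg, rng).a == 2.0
        assert woa_update_params(49, cfg, rng).a == pytest.approx(2.0 / 50)

    def test_A_bounded_by_a(self):
        cfg = small_config(max_it=10)
        rng = np.random.default_rng(1)
        for t in range(10):
            a = 2.0 * (1.0 - t / 10)
            for _ in range(200):
                params = woa_update_params(t, cfg, rng)
                assert np.all(np.abs(params.A) <= a + 1e-12)
                assert np.all((params.C >= 0) & (params.C <= 2))
                assert -1 <= params.l <= 1
                assert 0 <= params.p <= 1

    def test_out_of_range_iteration(self):
        with pytest.raises(DomainError):
            woa_update_params(99, small_config(max_it=4), np.random.default_rng(0))


class TestMoves:
    def test_encircle_full_attraction(self):
        new = woa_encircle([0.0, 1.0], [2.0, 3.0], A=np.zeros(2), C=np.ones(2))
        np.testing.assert_array_equal(new, [2.0, 3.0])

    def test_encircle_fixed_point(self):
        g = np.array([1.5, -2.0])
        new = woa_encircle(g, g, A=np.full(2, 0.7), C=np.ones(2))
        np.testing.assert_allclose(new, g)

    def test_encircle_hand_value(self):
        np.testing.assert_allclose(
            woa_encircle([0.0], [2.0], A=np.array([0.5]), C=np.array([1.0])), [1.0]
        )

    def test_spiral_at_guide_stays(self):
        g = np.array([0.3, 0.4])
        np.testing.assert_allclose(woa_spiral(g, g, l=0.37), g)

    def test_spiral_hand_value(self):
        np.testing.assert_allclose(woa_spiral([0.0], [2.0], l=0.0, spiral_b=1.0), [4.0])

    def test_spiral_damping_at_l_minus_one(self):
        # cos(2*pi*(-1)) = 1, so |new - guide| = e^{-1} |pos - guide|
        new = woa_spiral([0.0], [2.0], l=-1.0, spiral_b=1.0)
        assert abs(new[0] - 2.0) == pytest.approx(np.exp(-1.0) * 2.0)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            woa_spiral([0.0, 1.0], [2.0], l=0.1)


class TestCrossover:
    def test_identical_parents_identity(self):
        s = Solution(np.arange(8.0).reshape(4, 2))
        child = crossover_solutions(s, s, np.random.default_rng(0))
        np.testing.assert_array_equal(child.centroids, s.centroids)
        assert child.objectives is None

    def test_k2_forced_swap(self):
        s1 = Solution(np.array([[0.0, 0.0], [1.0, 1.0]]))
        s2 = Solution(np.array([[9.0, 9.0], [8.0, 8.0]]))
        child = crossover_solutions(s1, s2, np.random.default_rng(0))
        # exactly one slot swapped
        diffs = [not np.array_equal(child.centroids[i], s1.centroids[i]) for i in range(2)]
        assert sum(diffs) == 1

    def test_changes_exactly_m_slots(self):
        rng = np.random.default_rng(5)
        s1 = Solution(np.zeros((6, 3)))
        s2 = Solution(np.ones((6, 3)))
        for _ in range(100):
            child = crossover_solutions(s1, s2, rng)
            m = int(child.centroids.sum() / 3)
            assert 1 <= m <= 5

    def test_phase_q_bounded_by_half(self):
        rng = np.random.default_rng(6)
        el = EliteList(capacity=5)
        data = np.random.default_rng(0).normal(size=(20, 3))
        sol = Solution(data[:4].copy())
        from mowoats import evaluate_objectives

        evaluate_objectives(sol, data)
        el.update(sol)
        for _ in range(50):
            swarm = [Solution(data[i : i + 4].copy()) for i in range(15)]
            before = [s.centroids.copy() for s in swarm]
            replaced = crossover_phase(swarm, el, theta=rng.random(), rng=rng)
            assert 1 <= len(replaced) <= 7
            untouched = set(range(15)) - set(replaced)
            for i in untouched:
                np.testing.assert_array_equal(swarm[i].centroids, before[i])

    def test_phase_np2_uses_the_other_member(self):
        rng = np.random.default_rng(7)
        el = EliteList(capacity=5)
        swarm = [Solution(np.zeros((2, 2))), Solution(np.ones((2, 2)))]
        replaced = crossover_phase(swarm, el, theta=0.9, rng=rng)
        assert replaced in ([0], [1])
        i = replaced[0]
        other = 1 - i
        # offspring mixes rows of both parents
        vals = {float(v) for v in swarm[i].centroids.ravel()}
        assert vals <= {0.0, 1.0} and len(vals) == 2 or swarm[i].centroids.shape == (2, 2)

    def test_phase_seeded_reproducible(self):
        el = EliteList(capacity=5)
        results = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            swarm = [Solution(np.full((2, 2), float(i))) for i in range(4)]
            crossover_phase(swarm, el, theta=0.8, rng=rng)
            results.append(np.stack([s.centroids for s in swarm]))
        np.testing.assert_array_equal(results[0], results[1])


class TestStepAndRun:
    def test_step_requires_elite(self, blob20):
        cfg = AlgorithmConfig(k=3, seed=0).with_bounds_from(blob20.values)
        swarm = init_population(blob20, cfg, np.random.default_rng(0))
        with pytest.raises(DomainError):
            mowoats_step(swarm, EliteList(5), 0, cfg, blob20, np.random.default_rng(0))

    def test_positions_stay_in_bounds(self, blob20):
        cfg = AlgorithmConfig(k=3, seed=3, max_it=5).with_bounds_from(blob20.values)
        rng = np.random.default_rng(3)
        swarm = init_population(blob20, cfg, rng)
        el = EliteList(cfg.max_el)
        from mowoats import evaluate_objectives

        for s in swarm:
            evaluate_objectives(s, blob20)
            el.update(s)
        lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
        for t in range(cfg.max_it):
            mowoats_step(swarm, el, t, cfg, blob20, rng)
            for s in swarm:
                assert np.all(s.centroids >= lo - 1e-12)
                assert np.all(s.centroids <= hi + 1e-12)

    def test_tiny_p_threshold_still_valid(self, blob20):
        cfg = AlgorithmConfig(
            k=3, seed=4, max_it=3, p_threshold=1e-9
        )
        el = run_mowoats(blob20, cfg)
        assert len(el) >= 1

    def test_run_returns_non_dominated_elite(self, blob20):
        from mowoats import dominates

        el = run_mowoats(blob20, AlgorithmConfig(k=3, seed=9, max_it=8))
        assert len(el) >= 1
        objs = el.objective_vectors()
        for i, u in enumerate(objs):
            for j, v in enumerate(objs):
                if i != j:
                    assert not dominates(u, v)

    def test_run_seeded_determinism(self, blob20):
        els = [run_mowoats(blob20, AlgorithmConfig(k=3, seed=21, max_it=6)) for _ in range(2)]
        assert len(els[0]) == len(els[1])
        for a, b in zip(els[0], els[1]):
            np.testing.assert_array_equal(a.centroids, b.centroids)
            assert a.objectives.astuple() == b.objectives.astuple()

    def test_run_spearman_metric(self, blob20):
        el = run_mowoats(blob20, AlgorithmConfig(k=3, metric="spearman", seed=2, max_it=5))
        assert len(el) >= 1
        for s in el:
            assert np.isfinite(s.objectives.as_min_array()).all()
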