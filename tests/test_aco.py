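"""Unit and property tests for the ant colony optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acovit.aco import (
    ACOConfig,
    AntSolution,
    ConvergenceTrace,
    SearchSpace,
    deposit_amount,
    initialize_pheromone,
    optimize,
    sample_solution,
    update_pheromone,
)


def space(*sizes):
    return SearchSpace(
        tuple(f"l{i}" for i in range(len(sizes))),
        tuple(tuple(f"c{j}" for j in range(s)) for s in sizes),
    )


class TestInitialization:
    def test_all_trails_start_at_tau0(self):
        ph = initialize_pheromone(space(3, 3), ACOConfig(tau0=1.0))
        assert ph.iteration == 0
        assert all(np.all(t == 1.0) and len(t) == 3 for t in ph.tau)

    def test_zero_tau0_rejected(self):
        with pytest.raises(ValueError):
            ACOConfig(tau0=0.0)

    def test_degenerate_single_candidate_space(self):
        ph = initialize_pheromone(space(1), ACOConfig(tau0=2.0))
        assert ph.tau[0].tolist() == [2.0]


class TestSampling:
    def test_empirical_frequencies_match_trail_ratios(self):
        sp = space(2)
        ph = initialize_pheromone(sp, ACOConfig())
        ph.tau[0][:] = [3.0, 1.0]
        rng = np.random.default_rng(0)
        cfg = ACOConfig(alpha=1.0)
        draws = np.array(
            [sample_solution(sp, ph, cfg, rng).choices[0] for _ in range(100_000)]
        )
        freq = np.bincount(draws, minlength=2) / len(draws)
        np.testing.assert_allclose(freq, [0.75, 0.25], atol=0.01)

    def test_single_candidate_layers_are_deterministic(self):
        sp = space(1, 1, 1)
        ph = initialize_pheromone(sp, ACOConfig())
        for seed in (0, 1, 99):
            s = sample_solution(sp, ph, ACOConfig(), np.random.default_rng(seed))
            assert s.choices == (0, 0, 0)
            assert s.fitness is None

    def test_alpha_zero_ignores_trails(self):
        sp = space(2)
        ph = initialize_pheromone(sp, ACOConfig())
        ph.tau[0][:] = [1000.0, 1.0]
        rng = np.random.default_rng(3)
        cfg = ACOConfig(alpha=0.0)
        draws = [sample_solution(sp, ph, cfg, rng).choices[0] for _ in range(2000)]
        assert 0.45 < np.mean(draws) < 0.55


class TestDeposit:
    @pytest.mark.parametrize(
        "fitness,q,expected",
        [(0.0, 1.0, 1.0), (1.0, 1.0, 0.5), (5.0, 0.0, 0.0), (np.inf, 1.0, 0.0)],
    )
    def test_deposit_formula(self, fitness, q, expected):
        assert deposit_amount(fitness, q) == pytest.approx(expected)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            deposit_amount(-0.1, 1.0)

    def test_deposit_decreasing_in_fitness(self):
        vals = [deposit_amount(f, 1.0) for f in (0.0, 0.5, 1.0, 10.0)]
        assert vals == sorted(vals, reverse=True)


class TestUpdate:
    def test_evaporation_plus_deposit(self):
        sp = space(2, 2)
        cfg = ACOConfig(rho=0.5, tau_min=1e-6)
        ph = initialize_pheromone(sp, cfg)
        best = AntSolution((0, 1), fitness=1.0)
        new = update_pheromone(ph, best, delta=0.2, config=cfg)
        assert new.tau[0][0] == pytest.approx(0.7)   # on path
        assert new.tau[0][1] == pytest.approx(0.5)   # off path
        assert new.tau[1][1] == pytest.approx(0.7)
        assert new.iteration == 1

    def test_full_evaporation_floors_at_tau_min(self):
        sp = space(3)
        cfg = ACOConfig(rho=1.0, tau_min=1e-6)
        ph = initialize_pheromone(sp, cfg)
        new = update_pheromone(ph, AntSolution((0,), fitness=0.0), 0.0, cfg)
        assert np.all(new.tau[0] == 1e-6)

    @given(
        rho=st.floats(0.05, 1.0),
        delta=st.floats(0.0, 2.0),
        steps=st.integers(1, 30),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trail_positivity_and_boundedness(self, rho, delta, steps):
        sp = space(2, 3)
        cfg = ACOConfig(rho=rho, tau0=1.0)
        ph = initialize_pheromone(sp, cfg)
        for _ in range(steps):
            ph = update_pheromone(ph, AntSolution((0, 0), fitness=0.0), delta, cfg)
        lo = min(t.min() for t in ph.tau)
        hi = max(t.max() for t in ph.tau)
        assert lo >= cfg.tau_min
        assert hi <= max(cfg.tau0, delta / rho) + 1e-9


class TestOptimize:
    def test_flat_landscape_any_solution_valid(self):
        sp = space(2, 2)
        best, trace = optimize(sp, lambda s: 1.0, ACOConfig(seed=0, max_iterations=20))
        assert best.fitness == 1.0
        assert len(set(trace.best_so_far)) == 1

    def test_finds_unique_minimum_of_enumerable_space(self):
        sp = space(2, 2)
        table = {(0, 0): 0.9, (0, 1): 0.4, (1, 0): 0.8, (1, 1): 0.2}
        brute = min(table.values())
        hits = 0
        for seed in range(20):
            best, _ = optimize(
                sp, lambda s: table[s.choices], ACOConfig(seed=seed)
            )
            assert best.fitness >= brute  # never below the brute-force minimum
            hits += best.fitness == brute
        assert hits >= 19

    def test_trace_monotone_and_deterministic(self):
        sp = space(3, 3)
        fn = lambda s: float(s.choices[0] + 2 * s.choices[1])  # noqa: E731
        cfg = ACOConfig(seed=7, max_iterations=15)
        best1, t1 = optimize(sp, fn, cfg)
        best2, t2 = optimize(sp, fn, cfg)
        assert best1.choices == best2.choices
        assert t1.best_so_far == t2.best_so_far
        assert all(
            a >= b for a, b in zip(t1.best_so_far, t1.best_so_far[1:])
        )

    def test_failing_fitness_reports_choices(self):
        sp = space(2)

        def boom(s):
            raise RuntimeError("broken")

        with pytest.raises(RuntimeError, match="fitness evaluation failed"):
            optimize(sp, boom, ACOConfig(seed=0))

    def test_trace_csv_roundtrip(self, tmp_path):
        tr = ConvergenceTrace()
        tr.append(0, 1.0, 1.0)
        tr.append(1, 0.5, 0.5)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "iteration,best_fitness,best_so_far"
        assert len(rows) == 3
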