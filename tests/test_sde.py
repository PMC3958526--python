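import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mescnet.model import drift_array
from mescnet.params import CellState
from mescnet.sde import cell_seeds, simulate_cell, simulate_population
from mescnet.steady_state import find_fixed_points, stable_branch_states


@pytest.fixture(scope="module")
def nh_state(ref):
    return stable_branch_states(find_fixed_points(ref))["NH"]


class TestSimulateCell:
    def test_same_seed_is_bit_identical(self, ref, nh_state):
        a = simulate_cell(ref, CellState.from_array(nh_state), 200.0, 0.1, seed=5)
        b = simulate_cell(ref, CellState.from_array(nh_state), 200.0, 0.1, seed=5)
        assert np.array_equal(a.states, b.states)
        c = simulate_cell(ref, CellState.from_array(nh_state), 200.0, 0.1, seed=6)
        assert not np.array_equal(a.states, c.states)

    def test_numba_kernel_matches_python_reference(self, ref, nh_state):
        jit = simulate_cell(ref, CellState.from_array(nh_state), 50.0, 0.1, seed=3)
        py = simulate_cell(ref, CellState.from_array(nh_state), 50.0, 0.1, seed=3,
                           use_python=True)
        assert np.array_equal(jit.states, py.states)

    def test_noise_free_cell_stays_at_fixed_point(self, ref, nh_state):
        quiet = ref.replace(sigma_OS=0, sigma_N=0, sigma_R=0)
        traj = simulate_cell(quiet, CellState.from_array(nh_state), 1000.0, 0.1)
        np.testing.assert_allclose(traj.states[-1], nh_state, rtol=1e-3)

    def test_noise_free_limit_matches_ode_integration(self, ref):
        """sigma = 0 Euler-Maruyama agrees with an independent ODE solver."""
        quiet = ref.replace(sigma_OS=0, sigma_N=0, sigma_R=0)
        start = CellState(60.0, 5.0, 10.0, 5.0)
        traj = simulate_cell(quiet, start, 600.0, 0.05)
        sol = solve_ivp(
            lambda t, x: drift_array(np.maximum(x, 0.0), quiet),
            (0.0, 600.0), start.to_array(), rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(traj.states[-1], sol.y[:, -1], rtol=1e-3)

    def test_nonnegative_everywhere(self, ref):
        loud = ref.replace(sigma_N=0.5, sigma_R=0.5, sigma_OS=0.3)
        traj = simulate_cell(loud, CellState(1, 1, 1, 1), 500.0, 0.1, seed=9)
        assert traj.states.min() >= 0.0

    def test_rejects_bad_step(self, ref):
        with pytest.raises(ValueError):
            simulate_cell(ref, CellState(1, 1, 1, 1), 10.0, dt=0.0)

    def test_large_step_warns(self, ref):
        with pytest.warns(UserWarning, match="unstable"):
            simulate_cell(ref, CellState(1, 1, 1, 1), 30.0, dt=10.0)


class TestSimulatePopulation:
    def test_reproducible_and_order_independent_seeds(self, ref):
        seeds_10 = cell_seeds(master_seed=3, n_cells=10)
        seeds_5 = cell_seeds(master_seed=3, n_cells=5)
        assert np.array_equal(seeds_10[:5], seeds_5)

    def test_same_master_seed_bit_identical(self, ref):
        kw = dict(n_cells=20, init_policy="at_NH", duration=100.0, dt=0.1,
                  master_seed=11)
        a = simulate_population(ref, **kw)
        b = simulate_population(ref, **kw)
        assert np.array_equal(a.states, b.states)

    def test_noise_free_population_converges_to_nh(self, ref, nh_state):
        quiet = ref.replace(sigma_OS=0, sigma_N=0, sigma_R=0)
        pop = simulate_population(quiet, n_cells=10, init_policy="at_NH",
                                  duration=500.0, dt=0.1, master_seed=0)
        np.testing.assert_allclose(
            pop.terminal_states(), np.tile(nh_state, (10, 1)), rtol=1e-3)

    def test_thinning_preserves_grid_and_endpoints(self, ref):
        pop = simulate_population(ref, n_cells=3, init_policy="at_NH",
                                  duration=100.0, dt=0.1, master_seed=2,
                                  record_stride=50)
        assert pop.times[0] == 0.0
        np.testing.assert_allclose(np.diff(pop.times), 5.0)

    def test_mixed_init_policy_splits_population(self, ref):
        pop = simulate_population(ref, n_cells=10,
                                  init_policy=("mixed", 0.3),
                                  duration=1.0, dt=0.5, master_seed=0)
        n0 = pop.species("N")[:, 0]
        assert (n0 < 10).sum() == 3

    def test_at_nl_policy_requires_bistability(self, ref_2i):
        with pytest.raises(ValueError, match="NL"):
            simulate_population(ref_2i, n_cells=2, init_policy="at_NL",
                                duration=1.0, dt=0.5, master_seed=0)

    def test_snapshot_csv_contains_parameters_and_reads_back(self, ref, tmp_path):
        import pandas as pd

        pop = simulate_population(ref, n_cells=4, init_policy="at_NH",
                                  duration=10.0, dt=0.1, master_seed=1)
        path = tmp_path / "snap.csv"
        pop.write_snapshot_csv(path)
        text = path.read_text()
        assert "# master_seed = 1" in text
        frame = pd.read_csv(path, comment="#")
        assert list(frame.columns) == ["cell_id", "t_min", "OS", "N", "R", "E"]
        assert len(frame) == 4
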