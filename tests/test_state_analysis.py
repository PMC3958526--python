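import numpy as np
import pytest

from mescnet.sde import PopulationRun, Trajectory
from mescnet.state_analysis import (
    basin_boundary,
    detect_transitions,
    nl_fraction_sweep,
    population_events,
    residence_records,
    residence_statistics,
    transition_rate,
)
from mescnet.steady_state import find_fixed_points, stable_branch_states

BOUNDARY = 50.0
HIGH, LOW = 150.0, 2.0


def make_traj(n_values, dt_sample=1.0, cell_id=0):
    n_values = np.asarray(n_values, dtype=float)
    times = np.arange(n_values.size) * dt_sample
    states = np.zeros((n_values.size, 4))
    states[:, 0] = 90.0
    states[:, 1] = n_values
    return Trajectory(cell_id=cell_id, times=times, states=states, seed=0,
                      dt=dt_sample)


def square_wave(*segments, dt_sample=1.0):
    """segments: (level, minutes) pairs sampled every dt_sample minutes."""
    values = np.concatenate([
        np.full(int(round(minutes / dt_sample)), level)
        for level, minutes in segments
    ])
    return make_traj(values, dt_sample)


class TestDetectTransitions:
    def test_constant_trajectory_has_no_events(self):
        assert detect_transitions(make_traj(np.full(800, HIGH)), BOUNDARY) == []

    def test_subhour_excursion_is_not_a_transition(self):
        traj = square_wave((HIGH, 600), (LOW, 30), (HIGH, 600))
        assert detect_transitions(traj, BOUNDARY, min_residence=60) == []

    def test_two_hour_excursion_gives_two_events_with_residences(self):
        traj = square_wave((HIGH, 600), (LOW, 120), (HIGH, 600))
        events = detect_transitions(traj, BOUNDARY, min_residence=60)
        assert [ev.direction for ev in events] == ["NH->NL", "NL->NH"]
        assert events[0].residence_in_destination == pytest.approx(120.0)
        assert events[1].residence_in_destination >= 590.0

    def test_short_trajectory_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert detect_transitions(make_traj([HIGH] * 10), BOUNDARY) == []

    def test_poisson_switching_no_overcount_and_rate_limit(self, rng):
        # telegraph process: exponential sojourns of mean 12 h per side
        levels, durations = [], []
        level = HIGH
        total = 0.0
        while total < 20 * 1440.0:
            stay = rng.exponential(720.0)
            levels.append(level)
            durations.append(stay)
            total += stay
            level = LOW if level == HIGH else HIGH
        traj = square_wave(*zip(levels, durations), dt_sample=2.0)
        true_switches = len(levels) - 1
        no_filter = detect_transitions(traj, BOUNDARY, min_residence=0.0)
        filtered = detect_transitions(traj, BOUNDARY, min_residence=60.0)
        assert len(no_filter) == true_switches
        assert len(filtered) <= true_switches
        # one-hour rule discards only the small fraction of sub-hour sojourns
        assert len(filtered) >= 0.85 * true_switches


class TestTransitionRate:
    def test_zero_events_zero_rate(self):
        report = transition_rate([[], []], n_cells=2, duration=1440.0)
        assert report.per_cell_per_day == 0.0

    def test_rate_arithmetic(self):
        traj = square_wave((HIGH, 600), (LOW, 120), (HIGH, 600))
        events = detect_transitions(traj, BOUNDARY)
        lists = [events] * 50 + [[]] * 50  # 100 events, 100 cells
        report = transition_rate(lists, n_cells=100, duration=3 * 1440.0)
        assert report.per_cell_per_day == pytest.approx(100 / (100 * 3))
        assert report.per_cell_per_hour * 24 == report.per_cell_per_day
        assert report.ci_low <= report.per_cell_per_day <= report.ci_high


class TestResidence:
    def test_records_partition_the_trajectory(self):
        traj = square_wave((HIGH, 600), (LOW, 180), (HIGH, 600), (LOW, 90))
        records = residence_records(traj, BOUNDARY)
        total = traj.times[-1]
        assert sum(r.duration for r in records) == pytest.approx(total)
        assert records[0].censored and records[-1].censored
        uncensored = [r for r in records if not r.censored]
        assert [(r.basin, r.duration) for r in uncensored] == [
            ("NL", pytest.approx(180.0)), ("NH", pytest.approx(600.0))]

    def test_transition_parity_per_cell(self, small_pop, boundary):
        for events in population_events(small_pop, boundary):
            n_down = sum(ev.direction == "NH->NL" for ev in events)
            n_up = sum(ev.direction == "NL->NH" for ev in events)
            assert abs(n_down - n_up) <= 1

    def test_exponential_sojourn_recovery(self, ref, rng):
        """Mean residence recovered within 15% from a telegraph ensemble."""
        # horizon >> sojourn means: completed-interval censoring biases
        # the recovered mean by about -2*tau/horizon, so keep it small
        target_nl, target_nh = 9.0 * 1440, 11.0 * 1440
        n_cells, horizon = 15, 300 * 1440.0
        dt_sample = 10.0
        n_t = int(horizon / dt_sample) + 1
        states = np.zeros((n_cells, n_t, 4))
        for c in range(n_cells):
            t, level = 0.0, HIGH
            values = np.empty(n_t)
            i = 0
            while i < n_t:
                stay = rng.exponential(target_nh if level == HIGH else target_nl)
                j = min(n_t, i + max(1, int(round(stay / dt_sample))))
                values[i:j] = level
                i = j
                level = LOW if level == HIGH else HIGH
            states[c, :, 1] = values
        pop = PopulationRun(params=ref, times=np.arange(n_t) * dt_sample,
                            states=states, master_seed=0, dt=dt_sample)
        stats = residence_statistics(pop, BOUNDARY)
        assert stats["NL"]["n_uncensored"] >= 150
        assert stats["NL"]["mean_days"] == pytest.approx(9.0, rel=0.15)
        assert stats["NH"]["mean_days"] == pytest.approx(11.0, rel=0.15)

    def test_no_events_flags_insufficient(self, ref):
        states = np.zeros((3, 200, 4))
        states[:, :, 1] = HIGH
        pop = PopulationRun(params=ref, times=np.arange(200.0) * 10,
                            states=states, master_seed=0, dt=10.0)
        stats = residence_statistics(pop, BOUNDARY)
        assert stats["NL"]["insufficient"] and stats["NH"]["insufficient"]


class TestBasinBoundary:
    def test_boundary_lies_between_attractors(self, ref, boundary):
        branches = stable_branch_states(find_fixed_points(ref))
        assert branches["NL"][1] < boundary < branches["NH"][1]

    def test_monostable_two_i_raises(self, ref_2i):
        with pytest.raises(ValueError, match="no basin boundary"):
            basin_boundary(ref_2i)

    def test_boundary_is_the_reduced_map_middle_root(self, ref, boundary):
        from .test_steady_state import brute_force_nanog_roots
        from mescnet.model import hill
        from mescnet.steady_state import os_branch_roots

        os_hi = os_branch_roots(ref)[-1]
        e_star = ref.s7 * hill(os_hi, ref.k, ref.n) / ref.d_E
        roots = np.sort(brute_force_nanog_roots(ref, os_hi, e_star))
        assert boundary == pytest.approx(roots[1], rel=1e-6)


class TestNlFractionSweep:
    def test_noise_free_nh_cells_never_escape(self, ref):
        mat = nl_fraction_sweep(ref, s4_grid=[43.0], sigma_grid=[0.0],
                                n_cells=20, duration=720.0, dt=0.2,
                                init_policy="at_NH", master_seed=0)
        assert mat[0, 0] == 0.0

    def test_nl_only_regime_is_all_nl(self, ref):
        # s4 = 1 removes the NH state entirely
        mat = nl_fraction_sweep(ref, s4_grid=[1.0], sigma_grid=[0.0, 0.1],
                                n_cells=20, duration=720.0, dt=0.2,
                                master_seed=0)
        assert np.all(mat == 1.0)

    def test_empty_grid_rejected(self, ref):
        with pytest.raises(ValueError):
            nl_fraction_sweep(ref, s4_grid=[], sigma_grid=[0.1])
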