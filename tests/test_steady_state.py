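import numpy as np
import pytest
from scipy.optimize import brentq

from mescnet.params import ParameterSet
from mescnet.steady_state import (
    bifurcation_scan,
    classify_stability,
    find_fixed_points,
    os_branch_roots,
    reduced_nanog_rhs,
    stable_branch_states,
)


def brute_force_nanog_roots(params, os_star, e_star, n_grid=4000):
    """Sign-change scan of the 1-D Nanog reduction on an OS/E branch."""
    upper = 10.0 * (params.s3 + params.s4) / params.d_N
    grid = np.linspace(0.0, upper, n_grid)
    vals = np.array([reduced_nanog_rhs(n, params, os_star, e_star)
                     for n in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(
                lambda n: reduced_nanog_rhs(n, params, os_star, e_star), a, b))
    return np.array(roots)


def random_parameter_set(rng):
    return ParameterSet(
        s12=rng.uniform(8, 20),
        s3=rng.uniform(0.1, 3),
        s4=rng.uniform(10, 60),
        s5=rng.uniform(0.1, 5),
        s6=rng.uniform(1, 20),
        s7=rng.uniform(0.5, 4),
        k=rng.uniform(30, 80),
        p=rng.uniform(0, 30),
        d_OS=rng.uniform(0.05, 0.2),
        d_N=rng.uniform(0.05, 0.2),
        d_R=rng.uniform(0.05, 0.2),
        d_E=rng.uniform(0.05, 0.2),
    )


def nanog_oracle_agrees(params, rel_tol=1e-4):
    """Fixed points on the self-sustained OS branch match the 1-D scan."""
    os_roots = os_branch_roots(params)
    if os_roots.size == 0:
        return True
    os_hi = os_roots[-1]
    from mescnet.model import hill

    e_star = params.s7 * hill(os_hi, params.k, params.n) / params.d_E
    expected = brute_force_nanog_roots(params, os_hi, e_star)
    fps = find_fixed_points(params)
    found = np.sort([
        fp.state.N for fp in fps
        if abs(fp.state.OS - os_hi) <= 1e-3 * (1 + os_hi)
    ])
    if found.size != expected.size:
        return False
    return np.allclose(found, np.sort(expected),
                       rtol=rel_tol, atol=rel_tol * params.k)


class TestFindFixedPoints:
    def test_decay_only_system_has_single_stable_origin(self):
        params = ParameterSet(s12=0, s3=0, s4=0, s5=0, s6=0, s7=0, k=50)
        fps = find_fixed_points(params)
        assert len(fps) == 1
        assert fps[0].branch == "origin"
        assert fps[0].stability == "stable"

    def test_lif_serum_reference_is_bistable_with_saddle(self, ref):
        fps = find_fixed_points(ref)
        branches = stable_branch_states(fps)
        assert set(branches) == {"NL", "NH"}
        n_lo, n_hi = branches["NL"][1], branches["NH"][1]
        saddles = [fp for fp in fps
                   if fp.stability == "saddle" and n_lo < fp.state.N < n_hi
                   and fp.state.OS > 1]
        assert saddles, "stable states must be separated by an unstable one"

    def test_two_i_reference_is_monostable_nh(self, ref_2i):
        branches = stable_branch_states(find_fixed_points(ref_2i))
        assert set(branches) == {"NH"}

    def test_rejects_nonzero_Y(self, ref):
        with pytest.raises(ValueError, match="Y = 0"):
            find_fixed_points(ref.replace(Y=1.0))

    def test_oracle_equivalence_on_random_sets(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 5:
            params = random_parameter_set(rng)
            if os_branch_roots(params).size == 0:
                continue
            assert nanog_oracle_agrees(params)
            checked += 1


class TestReducedNanogRhs:
    def test_positive_at_zero_nanog(self, ref):
        os_hi = os_branch_roots(ref)[-1]
        assert reduced_nanog_rhs(0.0, ref, os_hi, 15.5) > 0

    def test_negative_at_large_nanog(self, ref):
        os_hi = os_branch_roots(ref)[-1]
        big = 100.0 * (ref.s3 + ref.s4) / ref.d_N
        assert reduced_nanog_rhs(big, ref, os_hi, 15.5) < 0

    def test_requires_Y_zero(self, ref):
        with pytest.raises(ValueError):
            reduced_nanog_rhs(1.0, ref.replace(Y=0.5), 90.0, 15.0)


class TestStability:
    def test_origin_eigenvalues_are_negative_degradation_rates(self):
        params = ParameterSet(s12=0, s3=0, s4=0, s5=0, s6=0, s7=0, k=50,
                              d_OS=0.07, d_N=0.11, d_R=0.13, d_E=0.17)
        label, max_real = classify_stability(np.zeros(4), params)
        assert label == "stable"
        assert max_real == pytest.approx(-0.07, rel=1e-4)

    def test_middle_branch_matches_reduced_map_derivative(self, ref):
        from mescnet.model import hill

        os_hi = os_branch_roots(ref)[-1]
        e_star = ref.s7 * hill(os_hi, ref.k, ref.n) / ref.d_E
        roots = brute_force_nanog_roots(ref, os_hi, e_star)
        assert roots.size == 3
        eps = 1e-4
        for n_root in roots:
            slope = (reduced_nanog_rhs(n_root + eps, ref, os_hi, e_star)
                     - reduced_nanog_rhs(n_root - eps, ref, os_hi, e_star)) / (2 * eps)
            fp = min(
                (f for f in find_fixed_points(ref)
                 if abs(f.state.OS - os_hi) < 1),
                key=lambda f: abs(f.state.N - n_root),
            )
            if slope > 0:
                assert fp.stability != "stable"
            else:
                assert fp.stability == "stable"


class TestBifurcationScan:
    def test_low_s4_has_only_the_low_branch(self, ref):
        diagram = bifurcation_scan(ref, "s4", np.array([1.0, 5.0, 10.0]),
                                   n_per_axis=4)
        for value, fp in diagram.points:
            if fp.is_stable and fp.branch in ("NL", "NH"):
                assert fp.branch == "NL"
        assert diagram.bistable_interval is None

    def test_p_scan_interval_contains_15_not_0(self, ref):
        diagram = bifurcation_scan(ref, "p", np.arange(0.0, 32.0, 4.0),
                                   n_per_axis=4)
        lo, hi = diagram.bistable_interval
        assert lo <= 15.0 <= hi
        assert lo > 0.0

    def test_grid_must_be_sorted(self, ref):
        with pytest.raises(ValueError):
            bifurcation_scan(ref, "p", np.array([10.0, 5.0]))

    def test_unknown_parameter_rejected(self, ref):
        with pytest.raises(ValueError):
            bifurcation_scan(ref, "k", np.array([1.0, 2.0]))

    def test_csv_export_round_trips(self, ref, tmp_path):
        import pandas as pd

        diagram = bifurcation_scan(ref, "p", np.array([0.0, 15.0]),
                                   n_per_axis=4)
        path = tmp_path / "diagram.csv"
        diagram.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["parameter", "branch", "stability",
                                       "OS", "N", "R", "E"]
        assert (frame.parameter == 15.0).any()
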