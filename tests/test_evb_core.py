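"""EVB energetics, FEP/umbrella profile construction, replica statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evbcat import (
    EVBParams,
    FreeEnergyProfile,
    MappingSchedule,
    WindowLog,
    aggregate_replicas,
    build_free_energy_profile,
    extract_barrier,
    fep_increment,
    ground_state_energy,
    mapping_potential,
)
from evbcat.constants import R_KCAL
from evbcat.synthetic_data import exact_profile_oracle, sample_windows

finite = st.floats(min_value=-500, max_value=500, allow_nan=False)


class TestMappingPotential:
    @pytest.mark.parametrize(
        "eps1,eps2,lam,expected",
        [(10, 20, 0.0, 10.0), (10, 20, 1.0, 20.0), (10, 20, 0.5, 15.0)],
    )
    def test_endpoints_and_midpoint(self, eps1, eps2, lam, expected):
        assert mapping_potential(eps1, eps2, lam) == pytest.approx(expected)

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range_coupling_rejected(self, lam):
        with pytest.raises(ValueError):
            mapping_potential(1.0, 2.0, lam)

    @given(e1=finite, e2=finite, lam=st.floats(0, 1))
    def test_convex_combination_bounds(self, e1, e2, lam):
        val = mapping_potential(e1, e2, lam)
        lo, hi = min(e1, e2), max(e1, e2)
        assert lo - 1e-9 <= val <= hi + 1e-9


class TestGroundState:
    @pytest.mark.parametrize(
        "e1,e2,h12,expected",
        [(0, 0, 44.28, -44.28), (0, 100, 0, 0.0), (0, 10, 5, -2.0710678)],
    )
    def test_known_eigenvalues(self, e1, e2, h12, expected):
        assert ground_state_energy(e1, e2, h12) == pytest.approx(expected, abs=1e-6)

    @given(e1=finite, e2=finite, h12=st.floats(0, 100))
    def test_matches_numeric_eigensolver(self, e1, e2, h12):
        ours = ground_state_energy(e1, e2, h12)
        ref = np.linalg.eigvalsh(np.array([[e1, h12], [h12, e2]]))[0]
        assert ours == pytest.approx(ref, abs=1e-8)

    @given(e1=finite, e2=finite, h12=st.floats(1e-3, 100))
    def test_coupling_lowers_below_both_diabats(self, e1, e2, h12):
        assert ground_state_energy(e1, e2, h12) < min(e1, e2) + 1e-12

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            ground_state_energy(0.0, 1.0, -1.0)


class TestFepIncrement:
    def test_constant_gap_identity(self):
        assert fep_increment([3.2, 3.2, 3.2], 300.0) == pytest.approx(3.2, abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            fep_increment([], 300.0)

    def test_huge_gaps_stay_finite(self):
        assert np.isfinite(fep_increment([1e4, 2e4], 300.0))

    def test_gaussian_cumulant_identity(self):
        # For Gaussian gaps, dG = mu - sigma^2 / (2 RT); RT=0.6 here.
        rng = np.random.default_rng(123)
        temperature = 0.6 / R_KCAL
        n = 200_000
        samples = rng.normal(2.0, 1.0, size=n)
        blocks = [
            fep_increment(chunk, temperature) for chunk in np.split(samples, 10)
        ]
        est = fep_increment(samples, temperature)
        se = np.std(blocks, ddof=1) / np.sqrt(len(blocks))
        expected = 2.0 - 1.0 / (2 * 0.6)
        assert est == pytest.approx(expected, abs=3 * se)


class TestWindowLog:
    def test_inconsistent_mapping_energy_rejected(self):
        with pytest.raises(ValueError, match="eps_map inconsistent"):
            WindowLog(lam=0.5, eps1=[1.0], eps2=[3.0], eps_map=[2.5])

    def test_sampled_logs_regenerate_mapping_energy(
        self, toy_symmetric, params_uncoupled
    ):
        sched = MappingSchedule.uniform(11)
        logs = sample_windows(toy_symmetric, sched, params_uncoupled, 50, seed=5)
        for w in logs:
            regen = mapping_potential(w.eps1, w.eps2, w.lam)
            assert np.max(np.abs(regen - w.eps_map)) <= 1e-6


class TestExtractBarrier:
    def test_simple_three_bin_well(self):
        prof = FreeEnergyProfile([-1.0, 0.0, 1.0], [0.0, 5.0, 2.0], [10, 10, 10])
        assert extract_barrier(prof) == pytest.approx((5.0, 2.0))

    def test_monotone_profile_has_no_transition_state(self):
        prof = FreeEnergyProfile([0, 1, 2, 3], [0.0, 1.0, 2.0, 3.0], [9, 9, 9, 9])
        with pytest.raises(ValueError, match="no transition state"):
            extract_barrier(prof)

    def test_too_few_bins_rejected(self):
        prof = FreeEnergyProfile([0, 1], [0.0, 1.0], [5, 5])
        with pytest.raises(ValueError):
            extract_barrier(prof)

    def test_agrees_with_grid_oracle(self, toy_symmetric, params_uncoupled):
        prof = exact_profile_oracle(toy_symmetric, params_uncoupled)
        barrier, dg_rxn = extract_barrier(prof)
        assert barrier == pytest.approx(prof.barrier)
        assert dg_rxn == pytest.approx(prof.reaction_free_energy)


class TestProfileConstruction:
    def test_requires_two_windows(self, toy_symmetric, params_uncoupled):
        sched = MappingSchedule.uniform(11)
        logs = sample_windows(toy_symmetric, sched, params_uncoupled, 50, seed=1)
        with pytest.raises(ValueError, match="two lambda windows"):
            build_free_energy_profile(logs[:1], params_uncoupled)

    def test_min_count_filter_can_empty_profile(self, toy_symmetric, params_uncoupled):
        sched = MappingSchedule.uniform(5)
        logs = sample_windows(toy_symmetric, sched, params_uncoupled, 5, seed=1)
        with pytest.raises(ValueError, match="min_count"):
            build_free_energy_profile(logs, params_uncoupled, min_count=1000)

    def test_profile_tracks_grid_oracle(self, toy_symmetric):
        params = EVBParams(off_diagonal=1.0, gas_shift=0.0)
        sched = MappingSchedule.uniform(51)
        logs = sample_windows(toy_symmetric, sched, params, 3000, seed=7)
        prof = build_free_energy_profile(logs, params)
        oracle = exact_profile_oracle(toy_symmetric, params)
        ref = np.interp(prof.bin_centers, oracle.bin_centers, oracle.free_energy)
        mad = float(np.mean(np.abs(prof.free_energy - ref)))
        assert mad <= 0.25
        assert prof.barrier == pytest.approx(oracle.barrier, abs=0.3)

    def test_asymmetric_reaction_free_energy(self, params_uncoupled):
        from evbcat import ToyDiabaticSystem

        system = ToyDiabaticSystem(dg0=-4.0)
        sched = MappingSchedule.uniform(51)
        logs = sample_windows(system, sched, params_uncoupled, 3000, seed=9)
        prof = build_free_energy_profile(logs, params_uncoupled)
        oracle = exact_profile_oracle(system, params_uncoupled)
        assert prof.reaction_free_energy == pytest.approx(
            oracle.reaction_free_energy, abs=0.3
        )

    def test_coupling_never_raises_barrier(self, toy_symmetric):
        barriers = []
        for h12 in (0.0, 0.5, 1.0, 2.0, 3.0):
            oracle = exact_profile_oracle(
                toy_symmetric, EVBParams(off_diagonal=h12, gas_shift=0.0)
            )
            barriers.append(oracle.barrier)
        assert np.all(np.diff(barriers) <= 1e-9)

    def test_cumulative_fep_invariant_to_schedule_density(
        self, toy_symmetric, params_uncoupled
    ):
        """Total dG over lambda in [0,1] equals the diabat offset regardless
        of window density (harmonic diabats with equal k: dG_total = dg0)."""

        def total_dg(n_windows: int, seed: int) -> float:
            sched = MappingSchedule.uniform(n_windows)
            logs = sample_windows(toy_symmetric, sched, params_uncoupled, 2000, seed=seed)
            total = 0.0
            for m in range(len(logs) - 1):
                delta = logs[m].energy_at(logs[m + 1].lam) - logs[m].eps_map
                total += fep_increment(delta, params_uncoupled.temperature)
            return total

        dense = np.array([total_dg(51, s) for s in (1, 2, 3)])
        coarse = np.array([total_dg(26, s) for s in (4, 5, 6)])
        se = np.hypot(dense.std(ddof=1) / np.sqrt(3), coarse.std(ddof=1) / np.sqrt(3))
        assert abs(dense.mean() - coarse.mean()) <= max(3 * se, 0.05)
        assert dense.mean() == pytest.approx(toy_symmetric.dg0, abs=0.1)


class TestReplicaAggregation:
    def test_two_point_sample(self):
        summary = aggregate_replicas([17.0, 17.2])
        assert summary.mean_barrier == pytest.approx(17.1)
        assert summary.sem_barrier == pytest.approx(0.1, abs=1e-12)
        assert summary.sem_defined

    def test_degenerate_sample_has_zero_sem(self):
        assert aggregate_replicas([5, 5, 5]).sem_barrier == 0.0

    def test_single_replica_flags_sem_undefined(self):
        summary = aggregate_replicas([17.0])
        assert not summary.sem_defined
        assert np.isnan(summary.sem_barrier)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicas([])

    def test_sem_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        values = rng.normal(17.0, 0.5, size=400)
        sem_small = aggregate_replicas(values[:100]).sem_barrier
        sem_large = aggregate_replicas(values).sem_barrier
        assert sem_large / sem_small == pytest.approx(0.5, rel=0.3)

    def test_replica_means_bracket_oracle(self, toy_symmetric):
        params = EVBParams(off_diagonal=1.0, gas_shift=0.0)
        sched = MappingSchedule.uniform(21)
        barriers = []
        for seed in range(6):
            logs = sample_windows(toy_symmetric, sched, params, 2000, seed=seed)
            prof = build_free_energy_profile(logs, params, n_bins=100, min_count=5)
            barriers.append(prof.barrier)
        summary = aggregate_replicas(barriers)
        oracle = exact_profile_oracle(toy_symmetric, params)
        # Binned estimates smooth the peak slightly, so allow a floor too.
        tol = max(3 * summary.sem_barrier, 0.15)
        assert summary.mean_barrier == pytest.approx(oracle.barrier, abs=tol)
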