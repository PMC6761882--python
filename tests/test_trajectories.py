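"""Trajectory analytics: unwrapping, MSD estimators against brute force,
autocorrelation against the closed-form FBM law, encounter counting
against a naive O(N^2) scan, and the collision-theory rate bridge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import Avogadro as N_A

from tta2d.simulate import SimulationConfig, simulate_brownian, simulate_fbm
from tta2d.trajectories import (
    EncounterResult,
    MSDResult,
    Trajectory2D,
    count_new_encounters,
    displacement_autocorrelation,
    encounter_rate_to_reaction_rate,
    ensemble_msd,
    ergodicity_check,
    fbm_increment_autocorrelation,
    fit_msd_exponent,
    time_averaged_msd,
    unwrap_trajectory,
)
from tta2d.validation import brute_force_new_encounters


def make_traj(positions, dt=1.0, box=(10.0, 10.0), wrapped=True):
    p = np.asarray(positions, dtype=float)
    times = np.arange(p.shape[1]) * dt
    return Trajectory2D(times=times, positions=p, box=box, wrapped=wrapped)


def brute_tmsd(x, max_lag):
    out = np.zeros(max_lag + 1)
    n = x.shape[0]
    for lag in range(1, max_lag + 1):
        d = x[lag:] - x[:-lag]
        out[lag] = np.mean(np.sum(d * d, axis=1))
    return out


class TestUnwrap:
    def test_single_boundary_crossing(self):
        xs = np.array([[[9.5, 5.0], [0.2, 5.0], [0.9, 5.0]]])
        traj = make_traj(xs)
        un = unwrap_trajectory(traj)
        np.testing.assert_allclose(un.positions[0, :, 0], [9.5, 10.2, 10.9])

    def test_idempotent_on_unwrapped(self):
        xs = np.array([[[1.0, 1.0], [25.0, -3.0]]])
        traj = make_traj(xs, wrapped=False)
        assert unwrap_trajectory(traj) is traj

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_telescoping_sum(self, seed):
        # sum of minimum-image steps equals unwrapped end-minus-start
        rng = np.random.default_rng(seed)
        L = 10.0
        steps = rng.uniform(-4.0, 4.0, size=(1, 30, 2))
        true = np.concatenate([np.zeros((1, 1, 2)), np.cumsum(steps, axis=1)],
                              axis=1) + 5.0
        wrapped = np.mod(true, L)
        un = unwrap_trajectory(make_traj(wrapped))
        end_to_end = un.positions[0, -1] - un.positions[0, 0]
        np.testing.assert_allclose(end_to_end, true[0, -1] - true[0, 0],
                                   atol=1e-9)

    def test_ambiguous_step_rejected(self):
        # a step landing exactly at L/2 cannot be assigned an image
        xs = np.array([[[0.0, 0.0], [5.0, 0.0]]])
        with pytest.raises(ValueError, match="ambiguous"):
            unwrap_trajectory(make_traj(xs, box=(10.0, 10.0)))


class TestTimeAveragedMSD:
    def test_stationary_particle(self):
        xs = np.full((1, 20, 2), 3.0)
        res = time_averaged_msd(make_traj(xs, wrapped=False))
        np.testing.assert_allclose(res.temsd, 0.0, atol=1e-12)

    def test_ballistic_closed_form(self):
        v = np.array([0.3, -0.4])  # speed 0.5
        t = np.arange(40.0)
        xs = (t[:, None] * v)[None]
        res = time_averaged_msd(make_traj(xs, wrapped=False))
        np.testing.assert_allclose(res.temsd, 0.25 * res.lags**2, rtol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        xs = np.cumsum(rng.standard_normal((3, 64, 2)), axis=1)
        res = time_averaged_msd(make_traj(xs, wrapped=False), max_lag=30)
        for i in range(3):
            np.testing.assert_allclose(res.tmsd[i], brute_tmsd(xs[i], 30),
                                       rtol=1e-10, atol=1e-12)

    def test_brownian_ensemble_law(self):
        D, dt = 2e-9, 2e-11
        cfg = SimulationConfig(seed=123, n_particles=500, n_steps=400,
                               D=D, dt=dt, L=50e-9)
        traj = unwrap_trajectory(simulate_brownian(cfg))
        res = time_averaged_msd(traj, max_lag=100)
        lag = res.lags[1:]
        expected = 4 * D * lag
        se = res.tmsd[:, 1:].std(axis=0, ddof=1) / np.sqrt(res.tmsd.shape[0])
        assert np.all(np.abs(res.temsd[1:] - expected) < 3 * se + 1e-30)

    def test_refuses_wrapped(self, brownian_traj):
        with pytest.raises(ValueError, match="unwrap"):
            time_averaged_msd(brownian_traj)


class TestEnsembleMSD:
    def test_identical_particles(self):
        tm = np.tile(np.arange(5.0), (4, 1))
        res = ensemble_msd(tm, np.arange(5.0))
        np.testing.assert_allclose(res.temsd, tm[0])

    def test_hand_computed_two_particles(self):
        # 3-frame trajectories: p1 moves +1/frame in x, p2 static
        tm = np.array([[0.0, 1.0, 4.0], [0.0, 0.0, 0.0]])
        res = ensemble_msd(tm, np.arange(3.0))
        np.testing.assert_allclose(res.temsd, [0.0, 0.5, 2.0])

    def test_matches_double_average_brute_force(self):
        rng = np.random.default_rng(8)
        xs = np.cumsum(rng.standard_normal((4, 32, 2)), axis=1)
        res = time_averaged_msd(make_traj(xs, wrapped=False), max_lag=10)
        comb = ensemble_msd(res.tmsd, res.lags)
        for lag in range(1, 11):
            acc = [np.sum((xs[i, o + lag] - xs[i, o]) ** 2)
                   for i in range(4) for o in range(32 - lag)]
            np.testing.assert_allclose(comb.temsd[lag], np.mean(acc),
                                       rtol=1e-10)

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd(np.zeros((1, 5)), np.arange(5.0))


class TestFitMSDExponent:
    def test_exact_linear_law(self):
        lags = np.linspace(0, 10, 51)
        D = 0.7
        msd = MSDResult(lags=lags, temsd=4 * D * lags,
                        tmsd=np.tile(4 * D * lags, (2, 1)))
        d, Di = fit_msd_exponent(msd, (lags[1], lags[-1]))
        assert d == pytest.approx(1.0, abs=1e-3)
        assert Di == pytest.approx(4 * D, rel=1e-6)

    def test_fbm_short_lag_exponent(self):
        cfg = SimulationConfig(seed=21, n_particles=200, n_steps=1024,
                               D=2e-9, dt=2e-11, motion="fbm", hurst=0.4,
                               L=100e-9)
        traj = unwrap_trajectory(simulate_fbm(cfg))
        res = time_averaged_msd(traj, max_lag=256)
        d, _ = fit_msd_exponent(res, (res.lags[1], res.lags[64]))
        assert d == pytest.approx(0.80, abs=0.03)

    def test_brownian_exponent_all_windows(self):
        cfg = SimulationConfig(seed=22, n_particles=300, n_steps=800,
                               D=2e-9, dt=2e-11, L=100e-9)
        traj = unwrap_trajectory(simulate_brownian(cfg))
        res = time_averaged_msd(traj, max_lag=400)
        for win in [(res.lags[1], res.lags[40]),
                    (res.lags[40], res.lags[400])]:
            d, _ = fit_msd_exponent(res, win)
            assert d == pytest.approx(1.00, abs=0.03)

    def test_short_window_rejected(self):
        lags = np.arange(6.0)
        msd = MSDResult(lags=lags, temsd=lags + 1,
                        tmsd=np.tile(lags + 1, (2, 1)))
        with pytest.raises(ValueError):
            fit_msd_exponent(msd, (1.0, 3.0))


class TestDisplacementAutocorrelation:
    def test_ballistic_is_one(self):
        t = np.arange(50.0)
        xs = (t[:, None] * np.array([1.0, 0.5]))[None]
        res = displacement_autocorrelation(
            make_traj(xs, wrapped=False), delta=5.0, max_lag=20)
        np.testing.assert_allclose(res.corr, 1.0, rtol=1e-12)
        assert res.corr[0] == pytest.approx(1.0)

    def test_brownian_uncorrelated_beyond_delta(self):
        cfg = SimulationConfig(seed=31, n_particles=200, n_steps=500,
                               D=2e-9, dt=2e-11, L=100e-9)
        traj = unwrap_trajectory(simulate_brownian(cfg))
        delta = 5 * traj.dt
        res = displacement_autocorrelation(traj, delta=delta, max_lag=30)
        beyond = res.lags >= delta
        assert np.all(np.abs(res.corr[beyond]) < 3 * res.stderr[beyond])

    def test_fbm_matches_closed_form(self):
        H = 0.4
        cfg = SimulationConfig(seed=32, n_particles=300, n_steps=512,
                               D=2e-9, dt=2e-11, motion="fbm", hurst=H,
                               L=100e-9)
        traj = unwrap_trajectory(simulate_fbm(cfg))
        m = 10
        delta = m * traj.dt
        res = displacement_autocorrelation(traj, delta=delta, max_lag=4 * m)
        ref = fbm_increment_autocorrelation(res.lags / delta, H)
        # negative dip near tau = delta, matching the FBM/FLE closed form
        i_delta = m
        assert res.corr[i_delta] < 0
        assert np.all(np.abs(res.corr - ref) < 3 * res.stderr + 0.02)

    def test_delta_must_be_multiple_of_step(self, brownian_traj):
        traj = unwrap_trajectory(brownian_traj)
        with pytest.raises(ValueError):
            displacement_autocorrelation(traj, delta=1.5 * traj.dt)


class TestErgodicity:
    def test_identical_particles_zero_scatter(self):
        tm = np.tile(np.arange(1.0, 6.0), (6, 1))
        msd = ensemble_msd(tm, np.arange(5.0))
        np.testing.assert_allclose(ergodicity_check(msd), 0.0, atol=1e-28)

    def test_scatter_decreases_with_ensemble_size(self):
        # ergodic FBM: relative tMSD scatter shrinks as trajectories lengthen
        # the ensemble statistics; compare small vs large ensembles
        ebs = []
        for n in (10, 80):
            cfg = SimulationConfig(seed=41, n_particles=n, n_steps=256,
                                   D=2e-9, dt=2e-11, motion="fbm",
                                   hurst=0.4, L=100e-9)
            traj = unwrap_trajectory(simulate_fbm(cfg))
            res = time_averaged_msd(traj, max_lag=64)
            eb = ergodicity_check(res)
            # standard error of the teMSD relative to its value
            ebs.append(np.mean(np.sqrt(eb[1:] / n)))
        assert ebs[1] < ebs[0]

    def test_frozen_plus_mobile_flags_heterogeneity(self):
        rng = np.random.default_rng(44)
        mobile = np.cumsum(rng.standard_normal((5, 100, 2)), axis=1)
        frozen = np.zeros((5, 100, 2))
        xs = np.concatenate([mobile, frozen])
        res = time_averaged_msd(make_traj(xs, wrapped=False), max_lag=30)
        eb = ergodicity_check(res)
        assert np.all(eb[1:] > 0.5)  # order-one scatter


class TestNewEncounters:
    def test_single_particle_zero(self):
        xs = np.zeros((1, 10, 2)) + 1.0
        res = count_new_encounters(make_traj(xs), radius=1.0)
        np.testing.assert_allclose(res.counts, 0.0)

    def test_no_double_counting(self):
        # two particles oscillate in and out of contact: count stays 1
        a = np.array([[1.0, 5.0], [1.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        b = np.array([[8.0, 5.0], [1.4, 5.0], [8.0, 5.0], [1.2, 5.0]])
        xs = np.stack([a, b])
        res = count_new_encounters(make_traj(xs), radius=1.0)
        np.testing.assert_allclose(res.counts, [0.0, 1.0, 1.0, 1.0])

    def test_initial_neighbors_not_counted(self):
        a = np.tile([1.0, 5.0], (3, 1))
        b = np.tile([1.5, 5.0], (3, 1))  # within radius from the start
        res = count_new_encounters(make_traj(np.stack([a, b])), radius=1.0)
        np.testing.assert_allclose(res.counts, 0.0)
        assert res.initial_neighbors == pytest.approx(1.0)

    def test_cell_list_equals_brute_force(self, brownian_traj):
        r = 1.5e-9
        cell = count_new_encounters(brownian_traj, r, method="cell")
        brute = count_new_encounters(brownian_traj, r, method="brute")
        np.testing.assert_array_equal(cell.counts, brute.counts)
        naive = brute_force_new_encounters(brownian_traj, r)
        np.testing.assert_allclose(cell.counts, naive, atol=1e-12)

    def test_permutation_invariance(self, brownian_traj):
        rng = np.random.default_rng(1)
        perm = rng.permutation(brownian_traj.n_particles)
        shuffled = Trajectory2D(times=brownian_traj.times,
                                positions=brownian_traj.positions[perm],
                                box=brownian_traj.box, wrapped=True)
        a = count_new_encounters(brownian_traj, 1.5e-9)
        b = count_new_encounters(shuffled, 1.5e-9)
        np.testing.assert_allclose(a.counts, b.counts)

    def test_sublinear_growth_brownian(self, brownian_traj):
        # 2D compact exploration: distinct encounters grow sublinearly
        res = count_new_encounters(brownian_traj, 1.5e-9)
        assert res.exponent < 1.0

    def test_radius_exceeding_half_box_rejected(self, brownian_traj):
        with pytest.raises(ValueError):
            count_new_encounters(brownian_traj, radius=20e-9)


class TestRateBridge:
    def _enc(self, n_end, duration):
        t = np.linspace(0.0, duration, 11)
        return EncounterResult(times=t, counts=np.linspace(0, n_end, 11),
                               radius=1.5e-9)

    def test_triplet_multiplier(self):
        # 15% triplets -> both-triplet probability 0.15^2 = 0.0225
        enc = self._enc(10.0, 100e-9)
        full = encounter_rate_to_reaction_rate(enc, 1.0, 225e-18, 100e-9)
        part = encounter_rate_to_reaction_rate(enc, 0.15, 225e-18, 100e-9)
        assert part / full == pytest.approx(0.0225, rel=1e-12)

    def test_zero_fraction(self):
        enc = self._enc(10.0, 100e-9)
        assert encounter_rate_to_reaction_rate(enc, 0.0, 225e-18, 100e-9) == 0

    def test_dimensional_oracle(self):
        # 10 encounters, 15% triplets, 225 nm^2, 100 ns:
        # 0.225 events / (225 nm^2 * 100 ns) = 1e22 m^-2 s^-1 = 1.66e-2 mol m^-2 s^-1
        enc = self._enc(10.0, 100e-9)
        rate = encounter_rate_to_reaction_rate(enc, 0.15, 225e-18, 100e-9)
        expected = (10 * 0.15**2) / (225e-18 * 100e-9) / N_A
        assert rate == pytest.approx(expected, rel=1e-12)
        assert rate == pytest.approx(1.66e-2, rel=0.01)

    def test_frequency_exponent_chain(self):
        # N_enc ~ t^0.87 implies encounter frequency f ~ t^(0.87-1) = t^-0.13
        enc = EncounterResult(times=np.arange(5.0), counts=np.arange(5.0),
                              radius=1.0, exponent=0.87)
        assert enc.frequency_exponent == pytest.approx(-0.13)
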