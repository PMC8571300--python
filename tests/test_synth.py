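import numpy as np
import pytest

from xrfret import synth
from xrfret.synth import (
    EmissionModel,
    GeneratorRates,
    MgRateLaw,
    MovieSpec,
    StatePath,
    render_trace,
    simulate_ctmc_path,
    simulate_decay_trace,
    simulate_guinier_curve,
    simulate_movie,
    simulate_titration,
)


class TestCtmcPath:
    def test_unreachable_state_never_visited(self):
        with pytest.warns(UserWarning, match="absorbing"):
            rates = GeneratorRates(k_li=1.0, k_lh=0, k_il=1.0, k_ih=0, k_hl=0, k_hi=0)
        path = simulate_ctmc_path(rates, duration=10.0, initial_state="L", seed=0)
        assert set(path.labels) <= {"L", "I"}
        assert len(path.states) > 2  # actually alternates

    def test_reachable_absorbing_state_ends_path(self):
        with pytest.warns(UserWarning, match="absorbing"):
            rates = GeneratorRates(k_li=5.0, k_lh=0, k_il=0, k_ih=0, k_hl=0, k_hi=0)
        path = simulate_ctmc_path(rates, duration=50.0, initial_state="L", seed=0)
        assert path.labels[-1] == "I"
        assert np.isclose(path.t_end[-1], 50.0)

    def test_absorbing_initial_state_rejected(self):
        with pytest.warns(UserWarning, match="absorbing"):
            rates = GeneratorRates(k_li=1.0, k_lh=0, k_il=1.0, k_ih=0, k_hl=0, k_hi=0)
        with pytest.raises(ValueError, match="absorbing state"):
            simulate_ctmc_path(rates, duration=1.0, initial_state="H", seed=0)

    def test_dwell_mean_matches_exit_rate(self):
        with pytest.warns(UserWarning, match="absorbing"):
            rates = GeneratorRates(k_li=2.0, k_lh=0, k_il=2.0, k_ih=0, k_hl=0, k_hi=0)
        path = simulate_ctmc_path(rates, duration=1e4, initial_state="L", seed=3)
        dur = path.dwell_times()[1:-1]  # interior (uncensored) dwells
        st = path.states[1:-1]
        mean_l = dur[st == 0].mean()
        assert mean_l == pytest.approx(0.5, rel=0.05)

    def test_seed_reproducibility(self, bench_rates):
        p1 = simulate_ctmc_path(bench_rates, 100.0, seed=42)
        p2 = simulate_ctmc_path(bench_rates, 100.0, seed=42)
        assert np.array_equal(p1.states, p2.states)
        assert np.array_equal(p1.t_start, p2.t_start)

    def test_occupancy_matches_stationary_distribution(self, bench_rates):
        """Long-run state occupancy equals the generator's stationary law."""
        path = simulate_ctmc_path(bench_rates, duration=2e4, seed=11)
        occ = np.zeros(3)
        for s, d in zip(path.states, path.dwell_times()):
            occ[s] += d
        occ /= occ.sum()
        pi = bench_rates.stationary_distribution()
        n_dwells = len(path.states)
        se = np.sqrt(pi * (1 - pi) / n_dwells) * 3  # crude 3 s.e. per state
        assert np.all(np.abs(occ - pi) < np.maximum(se * 3, 0.02))

    def test_dwell_means_converge_for_all_states(self, bench_rates):
        """Gillespie dwell means match 1/(exit-rate sum) over >=1e4 dwells."""
        path = simulate_ctmc_path(bench_rates, duration=1e4, seed=5)
        assert len(path.states) >= 1e4
        exits = bench_rates.exit_rates()
        dur = path.dwell_times()[1:-1]
        st = path.states[1:-1]
        for s in range(3):
            d = dur[st == s]
            mean, se = d.mean(), d.std(ddof=1) / np.sqrt(len(d))
            assert abs(mean - 1 / exits[s]) < 3 * se + 1e-9


class TestRenderTrace:
    def _path_single(self, state, duration):
        return StatePath(
            states=np.array([state]), t_start=np.array([0.0]),
            t_end=np.array([duration]), duration=duration,
        )

    def test_noiseless_high_state_split(self):
        em = EmissionModel(total_intensity=1000.0, channel_noise_sd=0.0)
        tr = render_trace(self._path_single(2, 1.0), em, 0.025, seed=0)
        assert np.allclose(tr.acceptor, 900.0)
        assert np.allclose(tr.donor, 100.0)

    def test_midframe_jump_gives_occupancy_weighted_fret(self):
        path = StatePath(
            states=np.array([0, 2]), t_start=np.array([0.0, 0.0125]),
            t_end=np.array([0.0125, 0.025]), duration=0.025,
        )
        em = EmissionModel(channel_noise_sd=0.0)
        tr = render_trace(path, em, 0.025, seed=0)
        assert tr.acceptor[0] == pytest.approx(600.0)  # E = (0.3+0.9)/2

    def test_instantaneous_sampling_ignores_blur(self):
        path = StatePath(
            states=np.array([0, 2]), t_start=np.array([0.0, 0.0125]),
            t_end=np.array([0.0125, 0.025]), duration=0.025,
        )
        em = EmissionModel(channel_noise_sd=0.0)
        tr = render_trace(path, em, 0.025, seed=0, integrate_frames=False)
        assert tr.acceptor[0] == pytest.approx(300.0)  # state at frame start

    def test_donor_bleach_extinguishes_both_channels(self):
        em = EmissionModel(channel_noise_sd=0.0, donor_bleach_rate=2.0)
        tr = render_trace(self._path_single(2, 20.0), em, 0.025, seed=4)
        assert tr.truth_bleach_time is not None
        after = tr.time >= tr.truth_bleach_time
        assert after.any()
        assert np.allclose(tr.acceptor[after], 0.0)
        assert np.allclose(tr.donor[after], 0.0)

    def test_acceptor_bleach_unquenches_donor(self):
        em = EmissionModel(channel_noise_sd=0.0, acceptor_bleach_rate=2.0)
        tr = render_trace(self._path_single(2, 20.0), em, 0.025, seed=4)
        after = tr.time >= tr.truth_bleach_time
        assert np.allclose(tr.acceptor[after], 0.0)
        assert np.allclose(tr.donor[after], 1000.0)


class TestTitration:
    def test_single_condition_wraps_path_and_render(self, bench_rates):
        ds = simulate_titration(bench_rates, [1.0], n_traces=1, duration=5.0, seed=0)
        assert len(ds) == 1
        tr = ds.conditions[0].traces[0]
        assert tr.n_frames == 200
        assert tr.truth_state is not None

    def test_zero_traces_gives_empty_set(self, bench_rates):
        ds = simulate_titration(bench_rates, [1.0], n_traces=0, seed=0)
        assert ds.conditions[0].traces == []

    def test_equilibrium_h_fraction_monotone_in_mg(self):
        """Stationary H occupancy of the default law rises with Mg2+."""
        law = MgRateLaw.default()
        concs = [0.001, 0.01, 0.1, 1.0, 10.0, 100.0]
        h_frac = [law.at(c).stationary_distribution()[2] for c in concs]
        assert np.all(np.diff(h_frac) > 0)
        assert h_frac[0] < 0.1 and h_frac[-1] > 0.6

    def test_ground_truth_rates_stored(self):
        law = MgRateLaw.default()
        ds = simulate_titration(law, [0.1, 10.0], n_traces=1, duration=2.0, seed=0)
        for cond in ds:
            assert cond.truth_rates == law.at(cond.mg_mM)

    def test_reproducible_under_seed(self, bench_rates):
        a = simulate_titration(bench_rates, [1.0], 3, duration=3.0, seed=9)
        b = simulate_titration(bench_rates, [1.0], 3, duration=3.0, seed=9)
        for ta, tb in zip(a.conditions[0].traces, b.conditions[0].traces):
            assert np.array_equal(ta.donor, tb.donor)
            assert np.array_equal(ta.acceptor, tb.acceptor)

    def test_fast_rates_trigger_frame_guard(self):
        fast = GeneratorRates(k_li=20.0, k_lh=0.1, k_il=20.0, k_ih=1, k_hl=1, k_hi=1)
        with pytest.warns(UserWarning, match="idealization will be unreliable"):
            simulate_titration(fast, [1.0], n_traces=1, duration=1.0, seed=0)


class TestMovie:
    def test_single_spot_volume_matches_gaussian_integral(self):
        spec = MovieSpec(
            shape=(40, 40), psf_sigma=1.5, positions=[(20.0, 20.0)],
            amplitudes=[300.0], background=0.0, n_frames=1,
        )
        movie = simulate_movie(spec, seed=0)
        total = movie.donor[0].sum()
        assert total == pytest.approx(2 * np.pi * 1.5**2 * 300.0, rel=1e-3)

    def test_zero_spots_background_only(self):
        spec = MovieSpec(shape=(16, 16), background=7.0, n_frames=2)
        movie = simulate_movie(spec, seed=0)
        assert np.allclose(movie.donor, 7.0)
        assert np.allclose(movie.acceptor, 7.0)

    def test_acceptor_positions_follow_transform(self):
        spec = MovieSpec(
            shape=(64, 64), positions=[(10.0, 12.0), (30.0, 40.0)],
            shift=(5.0, -3.0),
        )
        assert np.allclose(
            spec.acceptor_positions(), np.array([[15.0, 9.0], [35.0, 37.0]])
        )

    def test_spot_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            MovieSpec(shape=(32, 32), positions=[(40.0, 10.0)])


class TestDecaySim:
    def test_zero_rate_channels_identical(self):
        tr = simulate_decay_trace(0.0, duration_min=30, noise_sd=0.0, seed=0)
        assert np.allclose(tr.f_exp, tr.f_con)

    def test_noiseless_flat_control_gives_exact_exponential(self):
        tr = simulate_decay_trace(0.1, duration_min=60, noise_sd=0.0, seed=0)
        from xrfret.decay import normalize_decay

        f = normalize_decay(tr)
        assert np.allclose(f, np.exp(-0.1 * tr.time_min))

    def test_shared_drift_cancels_in_normalization(self):
        """Decay rate recovered within 1% despite a strong shared drift."""
        from xrfret.decay import fit_decay_rate, normalize_decay

        drift = lambda t: 1.0 + 0.01 * t  # +60% over the run
        tr = simulate_decay_trace(0.1, duration_min=60, noise_sd=0.0, drift=drift)
        fit = fit_decay_rate(tr.time_min, normalize_decay(tr))
        assert fit.rate == pytest.approx(0.1, rel=0.01)


class TestGuinierSim:
    def test_forward_scattering_limit(self):
        c = simulate_guinier_curve(20.0, 5.0, np.array([1e-6, 0.01, 0.02]))
        assert c.intensity[0] == pytest.approx(5.0, rel=1e-6)

    def test_direct_evaluation(self):
        c = simulate_guinier_curve(20.0, 5.0, np.array([0.05]))
        assert c.intensity[0] == pytest.approx(5.0 * np.exp(-0.05**2 * 400 / 3))

    def test_larger_rg_decays_faster(self):
        q = np.array([0.05])
        small = simulate_guinier_curve(20.0, 5.0, q).intensity[0]
        large = simulate_guinier_curve(40.0, 5.0, q).intensity[0]
        assert large < small
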