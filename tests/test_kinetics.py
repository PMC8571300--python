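import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xrfret.kinetics import (
    KB_KCAL,
    CriticalMg,
    DwellRecord,
    HillFit,
    LifetimeSet,
    TransitionCounts,
    barrier_height,
    build_tdp,
    critical_mg,
    extract_dwells,
    fit_hill,
    fit_lifetimes,
    fractional_populations,
    free_energy_landscape,
    transition_rates,
)
from xrfret.trace import IdealizedTrace


def make_ideal(states, fret=None, dt=0.025, trace_id="t"):
    states = np.asarray(states)
    if fret is None:
        means = np.array([0.3, 0.5, 0.9])
        fret = means[np.clip(states, 0, 2)].astype(float)
    return IdealizedTrace(
        states=states, fret=np.asarray(fret, dtype=float),
        state_means=np.array([0.3, 0.5, 0.9]), frame_interval=dt, trace_id=trace_id,
    )


def oracle_scan(traces):
    """Independent run-length scanner: plain-python recount of transitions."""
    counts = np.zeros((3, 3), dtype=int)
    for tr in traces:
        prev = None
        for s in tr.states:
            if s < 0:
                prev = None
                continue
            if prev is not None and s != prev:
                counts[prev, s] += 1
            prev = s
    return counts


class TestExtractDwells:
    def test_hand_counted_example(self):
        tr = make_ideal([0] * 10 + [1] * 5 + [0] * 8)
        dwells, counts = extract_dwells([tr])
        assert [d.state for d in dwells] == [0, 1, 0]
        assert dwells[0].censored_start and not dwells[0].censored_end
        assert not dwells[1].censored
        assert dwells[1].duration == pytest.approx(5 * 0.025)
        assert dwells[2].censored_end
        assert counts.n("L", "I") == 1 and counts.n("I", "L") == 1
        assert counts.total == 2

    def test_constant_trace_fully_censored(self):
        dwells, counts = extract_dwells([make_ideal([2] * 50)])
        assert len(dwells) == 1
        assert dwells[0].censored_start and dwells[0].censored_end
        assert counts.total == 0

    def test_counts_match_independent_scanner(self, small_fit):
        _, counts = extract_dwells(small_fit.idealized)
        assert np.array_equal(counts.matrix, oracle_scan(small_fit.idealized))

    def test_invalid_frames_split_and_censor(self):
        states = np.array([0] * 10 + [-1] * 3 + [1] * 10)
        tr = make_ideal(states, fret=np.where(states < 0, np.nan, 0.4))
        dwells, counts = extract_dwells([tr])
        assert counts.total == 0  # the gap breaks the L->I adjacency
        assert all(d.censored for d in dwells)


class TestLifetimes:
    def test_exponential_sample_within_3se(self, rng):
        durs = rng.exponential(0.5, 10_000)
        dwells = [DwellRecord(state=0, duration=d) for d in durs]
        lt = fit_lifetimes(dwells)
        assert abs(lt.tau[0] - 0.5) < 3 * lt.se[0]

    def test_single_uncensored_dwell_mle(self):
        with pytest.warns(UserWarning, match="noisy"):
            lt = fit_lifetimes([DwellRecord(state=1, duration=2.0)])
        assert lt.tau[1] == 2.0

    def test_resolution_limited_flagged(self):
        dwells = [DwellRecord(state=0, duration=0.025) for _ in range(100)]
        lt = fit_lifetimes(dwells)
        assert lt.tau[0] == pytest.approx(0.025)
        assert "resolution_limited_L" in lt.flags

    def test_censored_dwells_excluded(self):
        dwells = [DwellRecord(state=0, duration=1.0) for _ in range(50)]
        dwells += [
            DwellRecord(state=0, duration=99.0, censored_start=True)
            for _ in range(50)
        ]
        lt = fit_lifetimes(dwells)
        assert lt.tau[0] == pytest.approx(1.0)
        assert lt.n_dwells[0] == 50

    def test_binned_estimator_agrees_with_mle(self, rng):
        durs = rng.exponential(0.4, 5000)
        dwells = [DwellRecord(state=2, duration=d) for d in durs]
        mle = fit_lifetimes(dwells, method="mle")
        binned = fit_lifetimes(dwells, method="binned")
        assert binned.tau[2] == pytest.approx(mle.tau[2], rel=0.1)


def lifetimes_from_tau(tau_l=np.nan, tau_i=np.nan, tau_h=np.nan):
    tau = np.array([tau_l, tau_i, tau_h], dtype=float)
    return LifetimeSet(tau=tau, se=np.abs(tau) * 0.0, n_dwells=np.array([1, 1, 1]))


def counts_from(**kw):
    order = {"li": (0, 1), "lh": (0, 2), "il": (1, 0),
             "ih": (1, 2), "hl": (2, 0), "hi": (2, 1)}
    m = np.zeros((3, 3), dtype=int)
    for name, val in kw.items():
        m[order[name]] = val
    return TransitionCounts(matrix=m)


class TestTransitionRates:
    def test_pure_branch_to_intermediate(self):
        rs = transition_rates(lifetimes_from_tau(tau_l=1.0), counts_from(li=10))
        assert rs.k("L", "I") == pytest.approx(1.0)
        assert rs.k("L", "H") == 0.0

    def test_hand_evaluated_high_state_branching(self):
        rs = transition_rates(
            lifetimes_from_tau(tau_h=2.0), counts_from(hl=1, hi=3)
        )
        assert rs.k("H", "L") == pytest.approx(0.125)
        assert rs.k("H", "I") == pytest.approx(0.375)

    def test_no_exits_flagged_with_zero_rates(self):
        rs = transition_rates(lifetimes_from_tau(tau_l=1.0), counts_from(li=5))
        assert "no_exits_I" in rs.flags and "no_exits_H" in rs.flags
        assert rs.k("I", "L") == 0.0 and rs.k("H", "I") == 0.0

    def test_missing_lifetime_with_counts_raises(self):
        with pytest.raises(ValueError, match="lifetime of state I"):
            transition_rates(lifetimes_from_tau(tau_l=1.0), counts_from(li=5, il=5))

    @given(
        tau=st.tuples(*[st.floats(0.01, 100)] * 3),
        counts=st.tuples(*[st.integers(0, 1000)] * 6),
    )
    def test_exit_rate_identity(self, tau, counts):
        """k_XY + k_XZ = 1/tau_X exactly, for every state with exits."""
        lt = lifetimes_from_tau(*tau)
        cs = counts_from(
            li=counts[0], lh=counts[1], il=counts[2],
            ih=counts[3], hl=counts[4], hi=counts[5],
        )
        rs = transition_rates(lt, cs)
        for x in range(3):
            if cs.matrix[x].sum() > 0:
                total = rs.matrix[x].sum()
                assert total == pytest.approx(1.0 / tau[x], rel=1e-12)


class TestTdp:
    def test_hand_counted_two_bins(self):
        tr = make_ideal([0] * 10 + [1] * 10 + [0] * 10)
        tdp = build_tdp([tr])
        assert tdp.n_transitions == 2
        nz = np.argwhere(tdp.density > 0)
        assert len(nz) == 2
        assert tdp.density.sum() == pytest.approx(1.0)
        # (0.3 -> 0.5) and (0.5 -> 0.3), up to bin-edge rounding
        centers = 0.5 * (tdp.edges[:-1] + tdp.edges[1:])
        coords = sorted((centers[i], centers[j]) for i, j in nz)
        assert coords[0] == pytest.approx((0.3, 0.5), abs=0.011)
        assert coords[1] == pytest.approx((0.5, 0.3), abs=0.011)

    def test_density_sums_to_one(self, small_fit):
        assert small_fit.tdp.density.sum() == pytest.approx(1.0)

    def test_zero_transitions_warns_empty(self):
        with pytest.warns(UserWarning, match="no transitions"):
            tdp = build_tdp([make_ideal([1] * 30)])
        assert tdp.n_transitions == 0
        assert tdp.density.sum() == 0.0

    def test_event_total_matches_transition_counts(self, small_fit):
        """TDP and TransitionCounts are two views of the same events."""
        _, counts = extract_dwells(small_fit.idealized)
        assert small_fit.tdp.n_transitions == counts.total


class TestFreeEnergy:
    def _rateset(self, k):
        """RateSet with exact rate values via integer-consistent counts."""
        tau = np.array(
            [1.0 / (k["li"] + k["lh"]), 1.0 / (k["il"] + k["ih"]),
             1.0 / (k["hl"] + k["hi"])]
        )
        lt = LifetimeSet(tau=tau, se=tau * 0.0, n_dwells=np.ones(3, int))
        scale = 100_000
        cs = counts_from(**{n: int(round(v * scale)) for n, v in k.items()})
        return transition_rates(lt, cs)

    def test_equal_rates_give_zero_free_energy(self):
        rs = self._rateset(dict(li=1, lh=0.5, il=1, ih=1, hl=0.5, hi=1))
        land = free_energy_landscape(rs)
        assert land.dg[1] == pytest.approx(0.0, abs=1e-9)
        assert land.dg[2] == pytest.approx(0.0, abs=1e-9)

    def test_two_to_one_rates_closed_form(self):
        """k_LI/k_IL = 2 at 298 K gives dG_I = -kBT ln 2 ~ -0.411 kcal/mol."""
        rs = self._rateset(dict(li=2, lh=0.1, il=1, ih=1, hl=0.1, hi=1))
        land = free_energy_landscape(rs, temperature=298.0)
        kbt = KB_KCAL * 298.0
        assert land.dg[1] == pytest.approx(-kbt * math.log(2), abs=1e-9)
        assert land.dg[1] == pytest.approx(-0.411, abs=1e-3)

    def test_antisymmetry_under_rate_swap(self):
        a = self._rateset(dict(li=3, lh=0.1, il=1, ih=1, hl=0.1, hi=1))
        b = self._rateset(dict(li=1, lh=0.1, il=3, ih=1, hl=0.1, hi=1))
        la = free_energy_landscape(a)
        lb = free_energy_landscape(b)
        assert la.dg[1] == pytest.approx(-lb.dg[1], rel=1e-9)

    def test_unit_rate_barrier_is_1p8_kbt(self):
        land = free_energy_landscape(
            self._rateset(dict(li=1, lh=0.1, il=1, ih=1, hl=0.1, hi=1))
        )
        assert land.barriers["L->I"] == pytest.approx(1.8 * land.kbt)
        assert barrier_height(1.0, 298.15) == pytest.approx(1.8 * KB_KCAL * 298.15)

    def test_direct_lh_barrier_not_reported(self):
        land = free_energy_landscape(
            self._rateset(dict(li=1, lh=0.1, il=1, ih=1, hl=0.1, hi=1))
        )
        assert "L->H" not in land.barriers
        assert set(land.barriers) == {"L->I", "I->L", "I->H", "H->L", "H->I"}

    def test_missing_required_rate_raises_by_name(self):
        rs = self._rateset(dict(li=1, lh=0.1, il=1, ih=1, hl=0.1, hi=1))
        rs.matrix[2, 1] = 0.0
        with pytest.raises(ValueError, match="k_hi"):
            free_energy_landscape(rs)

    def test_closure_residual_zero_iff_detailed_balance(self):
        balanced = dict(li=2.0, lh=0.05, il=1.0, ih=0.8, hi=0.4, hl=0.0125)
        # cycle condition: li*ih*hl == lh*hi*il
        assert balanced["li"] * balanced["ih"] * balanced["hl"] == pytest.approx(
            balanced["lh"] * balanced["hi"] * balanced["il"]
        )
        land = free_energy_landscape(self._rateset(balanced))
        assert land.closure_residual == pytest.approx(0.0, abs=1e-6)

        violating = dict(balanced, hl=0.1)
        land2 = free_energy_landscape(self._rateset(violating))
        assert abs(land2.closure_residual) > 0.5  # ~kBT*ln(10)


class TestFractionalPopulations:
    def test_all_high_state(self):
        frac, src = fractional_populations([make_ideal([2] * 40)])
        assert np.allclose(frac, [0, 0, 1])
        assert src == "frame_occupancy"

    def test_equal_thirds(self):
        frac, _ = fractional_populations([make_ideal([0] * 10 + [1] * 10 + [2] * 10)])
        assert np.allclose(frac, [1 / 3, 1 / 3, 1 / 3])

    def test_matches_generator_stationary_distribution(
        self, small_fit, bench_rates
    ):
        frac, _ = fractional_populations(small_fit.idealized)
        assert np.allclose(frac, bench_rates.stationary_distribution(), atol=0.03)

    def test_mixture_source(self, small_fit):
        frac, src = fractional_populations(small_fit.populations)
        assert src == "mixture_weights"
        assert frac.sum() == pytest.approx(1.0)


class TestHill:
    def test_self_generated_curve_recovered(self):
        c = np.geomspace(1e-3, 100, 12)
        truth = HillFit(amplitude=0.9, k_mid=1.5, n_hill=1.0, baseline=0.05, se={})
        fit = fit_hill(c, truth(c), state="H")
        assert fit.amplitude == pytest.approx(0.9, rel=0.01)
        assert fit.k_mid == pytest.approx(1.5, rel=0.01)
        assert fit.n_hill == pytest.approx(1.0, rel=0.01)
        assert fit.baseline == pytest.approx(0.05, abs=0.001)

    def test_decreasing_titration_fitted_with_negative_amplitude(self):
        c = np.geomspace(1e-3, 100, 10)
        truth = HillFit(amplitude=-0.7, k_mid=0.8, n_hill=1.2, baseline=0.8, se={})
        fit = fit_hill(c, truth(c), state="L")
        assert fit.amplitude == pytest.approx(-0.7, rel=0.02)

    def test_flat_data_flagged(self):
        c = np.geomspace(1e-3, 100, 8)
        fit = fit_hill(c, np.full(8, 0.4))
        assert abs(fit.amplitude) < 1e-3
        assert any("flat" in f or "amplitude" in f for f in fit.flags)

    def test_intermediate_state_refused_by_default(self):
        c = np.geomspace(0.01, 10, 6)
        with pytest.raises(ValueError, match="intermediate"):
            fit_hill(c, np.linspace(0.2, 0.4, 6), state="I")
        fit_hill(c, np.linspace(0.2, 0.4, 6), state="I", allow_intermediate=True)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 concentrations"):
            fit_hill([0.1, 1, 10], [0.1, 0.5, 0.9])


class TestCriticalMg:
    def test_constructed_crossing_at_1p5(self):
        hill_h = HillFit(amplitude=1.0, k_mid=1.5, n_hill=1.0, baseline=0.0, se={})
        hill_l = HillFit(amplitude=0.0, k_mid=1.0, n_hill=1.0, baseline=0.5, se={})
        crit = critical_mg(hill_h, hill_l, mg_range=(1e-3, 100))
        assert crit.value == pytest.approx(1.5, abs=1e-3)
        assert crit.flag is None

    def test_h_above_l_everywhere_returns_range_minimum(self):
        hill_h = HillFit(amplitude=0.0, k_mid=1, n_hill=1, baseline=0.9, se={})
        hill_l = HillFit(amplitude=0.0, k_mid=1, n_hill=1, baseline=0.1, se={})
        crit = critical_mg(hill_h, hill_l, mg_range=(1e-3, 100))
        assert crit.value == pytest.approx(1e-3)
        assert crit.flag == "H_exceeds_L_at_range_minimum"

    def test_no_crossing_returns_infinity(self):
        hill_h = HillFit(amplitude=0.0, k_mid=1, n_hill=1, baseline=0.1, se={})
        hill_l = HillFit(amplitude=0.0, k_mid=1, n_hill=1, baseline=0.9, se={})
        crit = critical_mg(hill_h, hill_l, mg_range=(1e-3, 100))
        assert math.isinf(crit.value)
        assert crit.flag == "no_crossing_in_range"
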