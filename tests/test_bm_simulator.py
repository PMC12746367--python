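"""Bloch-McConnell propagator, lineshapes, isochromats, and trajectories."""

import math

import numpy as np
import pytest

from stmrf.bm_simulator import (
    SUPERLORENTZIAN_CUTOFF,
    _superlorentzian_quad,
    apply_lineshape,
    build_propagator,
    equilibrium_state,
    make_isochromats,
    propagate_interval,
    simulate_schedule,
    single_isochromat,
)
from stmrf.sequence_model import (
    AcquisitionSchedule,
    Lineshape,
    Pool,
    PoolSystem,
    SaturationEvent,
    ut_to_rad,
)


def rad_to_ut(w1):
    return w1 / ut_to_rad(1.0)


class TestBuildPropagator:
    def test_single_pool_relaxation_eigenvalues(self, single_pool_system):
        """Without RF the eigenvalues are -1/T2 (twice) and -1/T1."""
        pieces = build_propagator(single_pool_system, 0.0, 5.0)
        eig = np.sort(np.linalg.eigvals(pieces.A).real)
        assert eig == pytest.approx([-10.0, -10.0, -1.0], rel=1e-12)

    def test_exchange_conserves_magnetization(self, two_pool_system):
        """Column sums of the Mz block leave only relaxation: the exchange
        contributions cancel (what leaves one pool enters the other)."""
        pieces = build_propagator(two_pool_system, 0.0, 0.0)
        A = pieces.A
        wz, sz = 2, 5
        w, s = two_pool_system.water, two_pool_system.solutes[0]
        assert A[wz, wz] + A[sz, wz] == pytest.approx(-1.0 / w.t1, rel=1e-12)
        assert A[sz, sz] + A[wz, sz] == pytest.approx(-1.0 / s.t1, rel=1e-12)

    def test_on_resonance_nutation_matches_hand_built_bloch(self):
        """On resonance the matrix reduces to the textbook 3x3 Bloch form."""
        sys = PoolSystem(water=Pool("water", t1=1.0, t2=0.1), solutes=(), b0=7.0)
        w1 = 2 * math.pi * 100.0
        pieces = build_propagator(sys, rad_to_ut(w1), 0.0)
        expected = np.array(
            [[-10.0, 0.0, 0.0],
             [0.0, -10.0, w1],
             [0.0, -w1, -1.0]]
        )
        np.testing.assert_allclose(pieces.A, expected, rtol=1e-12, atol=1e-9)

    def test_eigenvalues_nonpositive_real_parts(self, two_pool_system):
        pieces = build_propagator(two_pool_system, 3.0, 3.0)
        assert np.all(np.linalg.eigvals(pieces.A).real <= 1e-10)

    def test_rate_pool_gets_mz_only_slot(self):
        water = Pool("water", t1=1.3, t2=0.075)
        mt = Pool("mt", t1=1.0, t2=1e-5, f=0.1, k=30.0,
                  lineshape=Lineshape.SUPERLORENTZIAN_RATE)
        sys = PoolSystem(water=water, solutes=(mt,), b0=3.0)
        pieces = build_propagator(sys, 2.0, 20.0)
        assert pieces.A.shape == (4, 4)
        # saturation rate strictly increases the Mz decay with B1 on
        off = build_propagator(sys, 0.0, 20.0)
        assert pieces.A[3, 3] < off.A[3, 3]


class TestPropagateInterval:
    def test_fixed_point_is_stationary(self, two_pool_system):
        pieces = build_propagator(two_pool_system, 2.0, 3.0)
        mss = pieces.fixed_point
        np.testing.assert_allclose(
            propagate_interval(mss, pieces, 0.7), mss, rtol=0, atol=1e-12
        )

    def test_t1_recovery_closed_form(self, single_pool_system):
        """From Mz=0 with no RF, Mz(T1) = 1 - 1/e."""
        pieces = build_propagator(single_pool_system, 0.0, 0.0)
        state = np.zeros(3)
        out = propagate_interval(state, pieces, single_pool_system.water.t1)
        assert out[2] == pytest.approx(1.0 - math.exp(-1.0), abs=1e-9)

    def test_cw_saturation_steady_state(self, single_pool_system):
        """On-resonance CW: Mz/M0 -> 1/(1 + w1^2 T1 T2)."""
        w1 = 267.5
        pieces = build_propagator(single_pool_system, rad_to_ut(w1), 0.0)
        out = propagate_interval(equilibrium_state(single_pool_system), pieces, 10.0)
        assert out[2] == pytest.approx(1.0 / (1.0 + w1**2 * 1.0 * 0.1), abs=1e-6)

    def test_step_splitting_exactness(self, two_pool_system):
        """One dt step equals two dt/2 steps when A is constant."""
        pieces = build_propagator(two_pool_system, 1.7, 3.0)
        m0 = equilibrium_state(two_pool_system)
        one = propagate_interval(m0, pieces, 0.8)
        two = propagate_interval(propagate_interval(m0, pieces, 0.4), pieces, 0.4)
        np.testing.assert_allclose(one, two, rtol=1e-10, atol=1e-14)


class TestLineshapes:
    def test_lorentzian_at_origin(self):
        t2s = 0.04
        assert apply_lineshape("lorentzian", t2s, 0.0) == pytest.approx(t2s / math.pi)

    def test_lorentzian_integrates_to_one(self):
        from scipy.integrate import quad

        t2s = 0.01
        val, _ = quad(lambda d: apply_lineshape("lorentzian", t2s, d), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_superlorentzian_matches_high_order_quadrature(self):
        """Fixed-order value vs a 10x-node quadrature oracle off resonance."""
        t2s = 1e-5
        delta = 50.0 / t2s  # delta * t2s = 50
        oracle = _superlorentzian_quad(t2s, delta, order=1280)
        assert apply_lineshape("superlorentzian", t2s, delta) == pytest.approx(
            oracle, rel=1e-8
        )

    def test_superlorentzian_gap_is_bridged_continuously(self):
        t2s = 1e-5
        c = SUPERLORENTZIAN_CUTOFF
        inside = apply_lineshape("superlorentzian", t2s, 0.99 * c)
        edge = apply_lineshape("superlorentzian", t2s, c)
        assert inside > 0 and abs(inside - edge) / edge < 0.05

    def test_negative_t2s_rejected(self):
        with pytest.raises(ValueError):
            apply_lineshape("lorentzian", -0.1, 0.0)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            apply_lineshape("gaussian", 0.01, 0.0)


class TestIsochromats:
    def test_single_isochromat_is_on_resonance(self):
        ens = make_isochromats(1, t2=0.1, t2star=0.1)
        assert ens.db0_offsets == pytest.approx([0.0])
        assert ens.lorentz_scale == 0.0

    def test_scale_collapses_when_t2star_equals_t2(self):
        ens = make_isochromats(33, t2=0.1, t2star=0.1)
        np.testing.assert_allclose(ens.db0_offsets, 0.0)

    def test_offsets_symmetric_and_weights_normalized(self):
        ens = make_isochromats(33, t2=0.1, t2star=0.04)
        np.testing.assert_allclose(ens.db0_offsets + ens.db0_offsets[::-1], 0, atol=1e-9)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_t2star_longer_than_t2_rejected(self):
        with pytest.raises(ValueError):
            make_isochromats(33, t2=0.1, t2star=0.2)

    def test_even_count_rejected(self):
        with pytest.raises(ValueError):
            make_isochromats(32, t2=0.1, t2star=0.05)

    def test_free_decay_follows_t2star_envelope(self):
        """Summed isochromat FID decays as exp(-t/T2*) (Lorentzian ΔB0)."""
        t2, t2star = 0.2, 0.05
        ens = make_isochromats(101, t2, t2star)
        ts = np.linspace(1e-3, t2star, 20)
        fid = np.array(
            [np.sum(ens.weights * np.cos(ens.db0_offsets * t)) * math.exp(-t / t2)
             for t in ts]
        )
        np.testing.assert_allclose(fid, np.exp(-ts / t2star), rtol=0.02)


class TestSimulateSchedule:
    def test_no_saturation_gives_flat_sin_fa(self, two_pool_system, cw_schedule):
        zeros = cw_schedule.with_values(b1=[0, 0, 0, 0])
        traj = simulate_schedule(two_pool_system, zeros)
        np.testing.assert_allclose(
            traj.values, math.sin(math.radians(60.0)), rtol=1e-10
        )

    def test_zero_flip_angle_gives_zero_signal(self, two_pool_system, cw_schedule):
        s = AcquisitionSchedule(events=cw_schedule.events, t_rec=1.0, flip_angle=0.0)
        assert np.all(simulate_schedule(two_pool_system, s).values == 0.0)

    def test_signal_bounded_by_water_m0(self, two_pool_system, cw_schedule):
        traj = simulate_schedule(two_pool_system, cw_schedule)
        assert np.all(traj.values >= 0) and np.all(traj.values <= 1 + 1e-6)

    def test_decoupled_limit_matches_closed_form(self):
        """f -> 0 solute: long CW saturation reproduces the single-pool
        on-resonance steady state of water within 1e-6."""
        water = Pool("water", t1=1.0, t2=0.1)
        ghost = Pool("ghost", t1=1.0, t2=0.04, f=1e-12, k=100.0, delta=0.0)
        sys = PoolSystem(water=water, solutes=(ghost,), b0=7.0)
        w1 = 267.5
        ev = SaturationEvent(b1=rad_to_ut(w1), offset=0.0, t_sat=20.0)
        s = AcquisitionSchedule(events=(ev,), t_rec=0.0, flip_angle=90.0)
        traj = simulate_schedule(sys, s)
        assert traj.values[0] == pytest.approx(1.0 / (1.0 + w1**2 * 0.1), abs=1e-6)

    def test_saturation_monotone_in_b1_single_pool(self, single_pool_system):
        """More on-resonance CW power never increases the signal."""
        vals = []
        for b1 in np.linspace(0.0, 4.0, 9):
            ev = SaturationEvent(b1=b1, offset=0.0, t_sat=3.0)
            s = AcquisitionSchedule(events=(ev,), t_rec=0.0, flip_angle=60.0)
            vals.append(simulate_schedule(single_pool_system, s).values[0])
        assert np.all(np.diff(vals) <= 1e-12)

    def test_equilibrium_restoration_after_long_recovery(self, two_pool_system):
        ev = SaturationEvent(b1=4.0, offset=3.0, t_sat=3.0)
        long_rec = AcquisitionSchedule(
            events=(ev, ev), t_rec=10 * 2.8, flip_angle=60.0
        )
        traj = simulate_schedule(two_pool_system, long_rec)
        # second image starts from a fully recovered state -> same signal
        assert traj.values[1] == pytest.approx(traj.values[0], abs=1e-4)

    def test_pool_relabeling_invariance(self):
        """Reordering solute pools leaves the water trajectory unchanged."""
        water = Pool("water", t1=2.8, t2=0.6)
        a = Pool("a", t1=2.8, t2=0.04, f=1e-3, k=300.0, delta=3.0)
        b = Pool("b", t1=1.0, t2=0.01, f=5e-3, k=50.0, delta=-2.5)
        ev = SaturationEvent(b1=2.0, offset=3.0, t_sat=2.0)
        sch = AcquisitionSchedule(events=(ev,) * 3, t_rec=1.0, flip_angle=60.0)
        t_ab = simulate_schedule(PoolSystem(water, (a, b), b0=7.0), sch)
        t_ba = simulate_schedule(PoolSystem(water, (b, a), b0=7.0), sch)
        np.testing.assert_allclose(t_ab.values, t_ba.values, rtol=1e-12)

    def test_pulsed_train_differs_from_cw_at_same_t_sat(self, two_pool_system):
        cw = SaturationEvent(b1=2.0, offset=3.0, t_sat=2.6)
        pw = SaturationEvent(b1=2.0, offset=3.0, t_sat=2.6, pulse_count=13,
                             pulse_duration=0.1, duty_cycle=0.5)
        s_cw = AcquisitionSchedule(events=(cw,), t_rec=1.0, flip_angle=60.0)
        s_pw = AcquisitionSchedule(events=(pw,), t_rec=1.0, flip_angle=60.0)
        v_cw = simulate_schedule(two_pool_system, s_cw).values[0]
        v_pw = simulate_schedule(two_pool_system, s_pw).values[0]
        assert v_pw > v_cw  # 50% duty saturates less

    def test_consuming_readout_reduces_later_signal(self, two_pool_system, cw_schedule):
        zeros = cw_schedule.with_values(b1=[0, 0, 0, 0])
        snap = simulate_schedule(two_pool_system, zeros)
        consume = simulate_schedule(two_pool_system, zeros, excitation_consumes_mz=True)
        assert consume.values[1] < snap.values[1]

    def test_empty_schedule_rejected(self, two_pool_system):
        empty = AcquisitionSchedule(events=(), t_rec=1.0, flip_angle=60.0)
        with pytest.raises(ValueError):
            simulate_schedule(two_pool_system, empty)

    def test_ensemble_signal_is_weighted_isochromat_sum(self, two_pool_system, cw_schedule):
        """The ensemble trajectory equals the weight-convex combination of
        per-isochromat trajectories."""
        from stmrf.bm_simulator import IsochromatEnsemble

        ens = make_isochromats(9, t2=0.6, t2star=0.1)
        t_ens = simulate_schedule(two_pool_system, cw_schedule, ens)
        acc = np.zeros(len(cw_schedule))
        for db0, w in zip(ens.db0_offsets, ens.weights):
            one = IsochromatEnsemble(
                db0_offsets=np.array([db0]), weights=np.ones(1),
                lorentz_scale=ens.lorentz_scale,
            )
            acc += w * simulate_schedule(two_pool_system, cw_schedule, one).values
        np.testing.assert_allclose(t_ens.values, acc, rtol=1e-12)
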