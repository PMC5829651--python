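"""Integrator, swivel driving, threading/drag rules and CTCF events."""

import numpy as np
import pytest

from twistloop.dynamics import (
    DynamicsConfig,
    Trajectory,
    advance_active_swivels,
    ctcf_rule,
    make_state,
    run,
    step,
    update_threading_and_drag,
)
from twistloop.forcefield import Forcefield, ForceFieldParams
from twistloop.model import (
    Fiber,
    add_active_swivel,
    add_ctcf,
    build_fiber,
    build_handcuff,
    thread_handcuff,
)
from twistloop.scenarios import threaded_loop_conformation


def threaded_state(n=80, a=20, b=60, swivel=40, ctcf=None, seed=0):
    pos = threaded_loop_conformation(n, a, b, swivel)
    f = Fiber(pos, circular=True)
    add_active_swivel(f, swivel)
    if ctcf:
        for bead, orientation in ctcf:
            add_ctcf(f, bead, orientation=orientation)
    hc = thread_handcuff(f, build_handcuff(), a, b)
    return make_state(f, [hc], seed=seed)


class TestStep:
    def test_zero_temperature_zero_force_is_identity(self):
        f = build_fiber(n_beads=20, circular=True)
        st = make_state(f, seed=0)
        cfg = DynamicsConfig(temperature=0.0)
        ff = Forcefield(st, ForceFieldParams())
        before = st.X.copy()
        step(st, cfg, ff)
        # relaxed ring: all forces vanish identically
        assert np.allclose(st.X, before, atol=1e-12)

    def test_same_seed_bit_identical_trajectory(self):
        def go():
            f = build_fiber(n_beads=30, circular=True)
            add_active_swivel(f, 15, rate_omega=0.2)
            st = make_state(f, seed=7)
            traj = run(st, DynamicsConfig(seed=7, n_steps=500, observe_every=100))
            return st.X.copy(), traj.observables

        x1, o1 = go()
        x2, o2 = go()
        assert np.array_equal(x1, x2)
        assert o1.equals(o2)

    def test_free_bead_diffusion_obeys_einstein_relation(self):
        """With all interactions off, MSD grows as 6 (kT/gamma) t within 5%."""
        f = build_fiber(n_beads=400, circular=False)
        st = make_state(f, seed=1)
        # free particles: negligible bond/excluded-volume scales, no
        # extensibility limit in reach, bending/twist stiffness zeroed
        zero = ForceFieldParams(k_fene=1e-12, r_fene_max=1e9, eps_wca=1e-12)
        cfg = DynamicsConfig(seed=1, n_steps=400, observe_every=100, dt=1e-3)
        ff = Forcefield(st, zero)
        ff.k_bend_arr[:] = 0.0
        ff.k_twist_arr[:] = 0.0
        window = 100  # independent displacement windows sharpen the estimate
        sq, n_win = 0.0, 0
        x_ref = st.X.copy()
        for k in range(1, cfg.n_steps + 1):
            step(st, cfg, ff)
            if k % window == 0:
                sq += np.mean(np.sum((st.X - x_ref) ** 2, axis=1))
                n_win += 1
                x_ref = st.X.copy()
        msd = sq / n_win
        expected = 6.0 * cfg.temperature / cfg.gamma_t * (window * cfg.dt)
        assert msd == pytest.approx(expected, rel=0.05)

    def test_gross_bond_overextension_aborts(self):
        f = build_fiber(n_beads=20, circular=False)
        f.positions[10] += np.array([5.0, 0.0, 0.0])
        st = make_state(f, seed=0)
        with pytest.raises(FloatingPointError, match="blow-up"):
            Forcefield(st, ForceFieldParams()).forces(st)


class TestSwivelDriving:
    def test_zero_rate_injects_nothing(self):
        f = build_fiber(n_beads=20)
        add_active_swivel(f, 5, rate_omega=0.0)
        st = make_state(f)
        advance_active_swivels(st, 1.0)
        assert f.active_swivels[0].injected_R == 0.0
        assert np.all(f.joint_twist0 == 0.0)

    def test_injected_R_is_exact_bookkeeping(self):
        f = build_fiber(n_beads=20)
        add_active_swivel(f, 5, rate_omega=0.3)
        st = make_state(f)
        for _ in range(1000):
            advance_active_swivels(st, 1e-3)
        assert f.active_swivels[0].injected_R == pytest.approx(0.3, abs=1e-12)
        assert f.joint_twist0[5] == pytest.approx(2 * np.pi * 0.3, abs=1e-9)

    def test_frozen_positions_twist_changes_by_injected_turns(self):
        """With positions frozen (no writhe channel) the elastic twist ledger
        absorbs exactly the injected rotations."""
        from twistloop.topology import twist

        f = build_fiber(n_beads=40, circular=True)
        add_active_swivel(f, 20, rate_omega=0.1, sign=-1)
        st = make_state(f, seed=3)
        cfg = DynamicsConfig(seed=3, freeze_positions=True, temperature=0.0,
                             n_steps=300_000, observe_every=100_000)
        run(st, cfg, stop_injected_R=3.0)
        assert twist(f) == pytest.approx(-3.0, abs=0.05)

    def test_injection_sign_convention(self):
        """sign=-1 drives the measured Tw+Wr ledger negative (negative
        supercoiling), sign=+1 positive."""
        from twistloop.topology import twist, writhe

        for sign in (-1, +1):
            f = build_fiber(n_beads=30, circular=True)
            add_active_swivel(f, 15, rate_omega=0.2, sign=sign)
            st = make_state(f, seed=2)
            run(st, DynamicsConfig(seed=2, n_steps=30000, observe_every=30000),
                stop_injected_R=1.0)
            ledger = twist(f) + writhe(f.positions, True)
            assert np.sign(ledger) == sign
            assert abs(ledger) == pytest.approx(1.0, abs=0.05)


class TestThreadingAndDrag:
    def test_fresh_threading_detected_and_drag_applied(self):
        st = threaded_state()
        cfg = DynamicsConfig()
        update_threading_and_drag(st, cfg)
        hc = st.handcuffs[0]
        assert hc.threaded_bead_a == 20
        assert hc.threaded_bead_b == 60
        assert st.drag_mult[20] == 10.0
        assert st.drag_mult[60] == 10.0
        sl = st.handcuff_bead_slice(0)
        assert np.all(st.drag_mult[sl] == 2.0)
        others = np.ones(st.n_total, dtype=bool)
        others[[20, 60]] = False
        others[sl] = False
        assert np.all(st.drag_mult[: st.n_fiber][others[: st.n_fiber]] == 1.0)

    def test_drag_restored_when_bead_exits(self):
        st = threaded_state()
        cfg = DynamicsConfig()
        update_threading_and_drag(st, cfg)
        assert st.drag_mult[20] == 10.0
        # drag the fibre far away: ring empties, multiplier reverts
        st.X[: st.n_fiber] += np.array([0.0, 50.0, 0.0])
        update_threading_and_drag(st, cfg)
        assert st.handcuffs[0].threaded_bead_a is None
        assert st.drag_mult[20] == 1.0
        assert any("unthreaded" in m for _, m in st.events)

    def test_effective_drag_combines_size_and_multiplier(self):
        st = threaded_state(ctcf=[(14, "convergent")])
        cfg = DynamicsConfig()
        update_threading_and_drag(st, cfg)
        gam = st.effective_gamma_t(cfg)
        assert gam[20] == pytest.approx(10.0 * cfg.gamma_t)
        assert gam[st.ctcf_offset] == pytest.approx(3.5 * cfg.gamma_t)  # 1.75/0.5


class TestCTCFRule:
    def test_no_contact_no_change(self):
        st = threaded_state(ctcf=[(14, "convergent")])
        cfg = DynamicsConfig()
        ctcf_rule(st, cfg)
        assert st.handcuffs[0].state == "active"
        assert st.anchor_bonds == []

    def test_convergent_contact_anchors(self):
        st = threaded_state(ctcf=[(14, "convergent")])
        cfg = DynamicsConfig()
        hc = st.handcuffs[0]
        out = hc.ring_centre("a") - hc.ring_centre("b")
        out /= np.linalg.norm(out)
        st.X[st.ctcf_offset] = hc.ring_centre("a") + 2.0 * out  # touches ring a only
        ctcf_rule(st, cfg)
        assert hc.state == "anchored"
        assert "a" in hc.anchored_rings
        assert len(st.anchor_bonds) == 3
        assert any("anchored" in m for _, m in st.events)

    def test_divergent_contact_dissociates_after_dwell(self):
        st = threaded_state(ctcf=[(14, "divergent")])
        cfg = DynamicsConfig(ctcf_dwell=5.0)
        hc = st.handcuffs[0]
        st.X[st.ctcf_offset] = hc.ring_centre("a") + np.array([1.0, 0.0, 0.0])
        ctcf_rule(st, cfg)
        assert hc.state == "active"  # dwell clock just started
        st.time += 6.0
        ctcf_rule(st, cfg)
        assert hc.state == "dissociated"
        assert hc.threaded_bead_a is None
        sl = st.handcuff_bead_slice(0)
        assert np.all(st.frozen[sl])
        assert any("dissociated" in m for _, m in st.events)

    def test_contact_clock_resets_when_ring_leaves(self):
        st = threaded_state(ctcf=[(14, "divergent")])
        cfg = DynamicsConfig(ctcf_dwell=5.0)
        hc = st.handcuffs[0]
        st.X[st.ctcf_offset] = hc.ring_centre("a") + np.array([1.0, 0.0, 0.0])
        ctcf_rule(st, cfg)
        st.X[st.ctcf_offset] += np.array([50.0, 0.0, 0.0])
        st.time += 6.0
        ctcf_rule(st, cfg)  # contact broken: clock must reset
        st.X[st.ctcf_offset] = hc.ring_centre("a") + np.array([1.0, 0.0, 0.0])
        st.time += 1.0
        ctcf_rule(st, cfg)
        assert hc.state == "active"


class TestRun:
    def test_zero_steps_single_frame(self):
        f = build_fiber(n_beads=20)
        st = make_state(f)
        traj = run(st, DynamicsConfig(n_steps=0))
        assert traj.n_frames == 1
        assert traj.observables.shape[0] == 1

    def test_stop_on_injected_R(self):
        f = build_fiber(n_beads=30, circular=True)
        add_active_swivel(f, 15, rate_omega=1.0)
        st = make_state(f, seed=0)
        traj = run(st, DynamicsConfig(seed=0, n_steps=100000, observe_every=1000),
                   stop_injected_R=0.5)
        assert f.active_swivels[0].injected_R == pytest.approx(0.5, abs=0.01)
        assert traj.observables["injected_R"].iloc[-1] == pytest.approx(0.5, abs=0.01)

    def test_observables_columns_present(self):
        st = threaded_state()
        traj = run(st, DynamicsConfig(n_steps=20, observe_every=10))
        for col in ("time", "Tw", "Wr", "lk_deficit", "free_twist",
                    "injected_R", "min_nb_dist", "loop_extent_0"):
            assert col in traj.observables.columns


class TestEquilibriumRecovery:
    def test_bond_length_and_persistence_at_default_parameters(self):
        """A short thermal run of a linear fibre: mean bond length 1 sigma
        within 2%; handcuff rigidity contract checked on a separate run."""
        f = build_fiber(n_beads=50, circular=False)
        st = make_state(f, seed=4)
        traj = run(st, DynamicsConfig(seed=4, n_steps=20000, observe_every=1000))
        bonds = []
        for k in range(10, traj.n_frames):
            p = traj.fiber_positions(k)
            bonds.append(np.linalg.norm(np.diff(p, axis=0), axis=1).mean())
        assert np.mean(bonds) == pytest.approx(1.0, rel=0.02)

    def test_handcuff_shape_contract_under_thermal_motion(self):
        """Thermalised handcuff stays within 0.2 sigma RMSD of its reference
        figure-eight (rigidity is tested, not assumed)."""
        st = threaded_state(seed=5)
        run(st, DynamicsConfig(seed=5, n_steps=20000, observe_every=5000))
        assert st.handcuffs[0].shape_rmsd() < 0.2


class TestBarrierMotor:
    def test_barrier_injects_into_one_flank_only(self):
        """A barrier motor (continuously transcribing polymerase) exchanges
        no twist between its flanks: with positions frozen and no noise, the
        downstream flank stays torsionally silent to machine precision while
        the upstream flank absorbs the (negative) injection."""
        from twistloop.model import add_passive_swivel

        f = build_fiber(n_beads=40, circular=True)
        add_passive_swivel(f, 0)              # torsional sink opposite the motor
        add_active_swivel(f, 20, rate_omega=0.2, sign=-1, barrier=True)
        st = make_state(f, seed=9)
        cfg = DynamicsConfig(seed=9, freeze_positions=True, temperature=0.0,
                             n_steps=10_000, observe_every=10_000)
        run(st, cfg)
        assert f.active_swivels[0].injected_R == pytest.approx(4.0, abs=1e-9)
        dev = f.joint_twist - f.joint_twist0
        upstream = dev[1:20]    # between the sink (joint 0) and the motor (20)
        downstream = dev[21:40]
        assert np.abs(downstream).max() < 1e-9
        # the upstream flank carries the steady negative twist-flux profile
        # toward the border sink: strictly negative, growing toward the motor
        assert np.all(upstream < 0)
        assert abs(upstream[-1]) > abs(upstream[0])
        assert upstream.sum() < -0.1
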