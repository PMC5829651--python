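"""Topological observables against independent oracles."""

import numpy as np
import pytest

from twistloop.dynamics import make_state
from twistloop.model import (
    Fiber,
    add_active_swivel,
    add_passive_swivel,
    build_fiber,
    build_handcuff,
    thread_handcuff,
)
from twistloop.scenarios import threaded_loop_conformation
from twistloop.topology import (
    PersistenceFit,
    contact_map,
    detect_plectonemes,
    fit_persistence_length,
    free_twist,
    lk_deficit,
    loop_extent,
    min_nonbonded_distance,
    segment_writhe_density,
    twist,
    writhe,
    writhe_pair_matrix,
)


def brute_force_writhe(positions, circular):
    """Independent loop-based Gauss sum (dihedral/atan2 formulation).

    Uses the signed solid angle of the tetrahedron spanned by each segment
    pair, evaluated via the van-Oosterom/Strackee triangle formula -- a
    different algebraic route from the production asin-based expression.
    """
    p = np.asarray(positions, float)
    if circular:
        a = p
        b = np.roll(p, -1, axis=0)
    else:
        a, b = p[:-1], p[1:]
    n = len(a)

    def solid_angle_tri(r1, r2, r3):
        n1, n2, n3 = np.linalg.norm(r1), np.linalg.norm(r2), np.linalg.norm(r3)
        num = np.dot(r1, np.cross(r2, r3))
        den = (n1 * n2 * n3 + np.dot(r1, r2) * n3
               + np.dot(r1, r3) * n2 + np.dot(r2, r3) * n1)
        return 2.0 * np.arctan2(num, den)

    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if circular and i == 0 and j == n - 1:
                continue
            # solid angle subtended: split quad (p3-p1, p4-p1 ...) into triangles
            r13 = a[j] - a[i]
            r14 = b[j] - a[i]
            r23 = a[j] - b[i]
            r24 = b[j] - b[i]
            om = solid_angle_tri(r13, r14, r24) + solid_angle_tri(r13, r24, r23)
            total += om
    # orientation of the triangle split is opposite the Gauss-kernel
    # convention (right-handed crossings positive, as fixed by the
    # White's-theorem conservation tests); flip accordingly
    return -total / (4.0 * np.pi) * 2.0


def torus_curve(n, q=3, R=3.0, a=1.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([
        (R + a * np.cos(q * th)) * np.cos(th),
        (R + a * np.cos(q * th)) * np.sin(th),
        a * np.sin(q * th),
    ])


class TestWrithe:
    def test_planar_circle_is_zero(self):
        for n in (8, 50, 200):
            f = build_fiber(n_beads=n, circular=True)
            assert abs(writhe(f.positions, True)) < 1e-10

    def test_mirror_antisymmetry(self):
        p = torus_curve(120)
        pm = p * np.array([1.0, 1.0, -1.0])
        assert writhe(p, True) == pytest.approx(-writhe(pm, True), abs=1e-12)

    def test_matches_brute_force_on_random_configs(self):
        """Vectorised Gauss sum vs an independent loop/atan2 oracle."""
        rng = np.random.default_rng(42)
        for _ in range(12):
            n = rng.integers(8, 30)
            steps = rng.standard_normal((n, 3))
            p = np.cumsum(steps / np.linalg.norm(steps, axis=1, keepdims=True), axis=0)
            for circ in (True, False):
                assert writhe(p, circ) == pytest.approx(
                    brute_force_writhe(p, circ), abs=1e-9
                )

    def test_discretisation_convergence_on_analytic_curve(self):
        """A fixed closed helical curve: 400 points vs a 10x finer sampling."""
        w_coarse = writhe(torus_curve(400), True)
        w_fine = writhe(torus_curve(4000), True)
        assert w_coarse == pytest.approx(w_fine, abs=1e-3)

    def test_degenerate_segment_rejected(self):
        p = np.zeros((5, 3))
        with pytest.raises(ValueError):
            writhe(p, True)
        with pytest.raises(ValueError):
            writhe(np.zeros((3, 3)), False)

    def test_pair_matrix_sums_to_writhe(self):
        p = torus_curve(60)
        m = writhe_pair_matrix(p, True)
        assert np.allclose(m, m.T)
        assert 0.5 * m.sum() == pytest.approx(writhe(p, True), abs=1e-12)
        assert segment_writhe_density(p, True).sum() == pytest.approx(
            writhe(p, True), abs=1e-12
        )


class TestTwist:
    def test_zero_twist(self):
        f = build_fiber(n_beads=30)
        assert twist(f) == 0.0

    def test_one_full_turn(self):
        f = build_fiber(n_beads=30)
        f.joint_twist[4] = 2 * np.pi
        assert twist(f) == pytest.approx(1.0)

    def test_passive_joint_reported_separately(self):
        f = build_fiber(n_beads=30)
        add_passive_swivel(f, 3)
        f.joint_twist[3] = 2 * np.pi
        f.joint_twist[10] = np.pi
        assert twist(f) == pytest.approx(0.5)
        assert free_twist(f) == pytest.approx(1.0)

    def test_active_joint_counts_elastic_deviation_only(self):
        f = build_fiber(n_beads=30)
        add_active_swivel(f, 5)
        f.joint_twist0[5] = -4 * np.pi  # motor rotated twice
        f.joint_twist[5] = -4 * np.pi + 0.1  # elastic lag 0.1 rad
        assert twist(f) == pytest.approx(0.1 / (2 * np.pi))


class TestLkDeficit:
    def test_initial_relaxed_state_is_zero(self):
        f = build_fiber(n_beads=40)
        st = make_state(f)
        assert lk_deficit(st) == pytest.approx(0.0, abs=1e-10)

    def test_phantom_passage_moves_ledger_by_two(self):
        """Flipping one lobe of a figure-eight through the other changes Wr
        by ~2 at fixed twist: the ledger jump that detect_passages flags."""
        th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        eight = np.column_stack([np.sin(2 * th), 2.0 * np.sin(th), 0.12 * np.cos(th)])
        mirrored = eight * np.array([1.0, 1.0, -1.0])
        d = writhe(eight, True) - writhe(mirrored, True)
        assert abs(d) == pytest.approx(2.0, abs=0.25)


class TestLoopExtent:
    def make_state_threaded(self, n, a, b, swivel):
        pos = threaded_loop_conformation(n, a, b, swivel)
        f = Fiber(pos, circular=True)
        add_active_swivel(f, swivel)
        hc = thread_handcuff(f, build_handcuff(), a, b)
        return make_state(f, [hc]), hc

    def test_symmetric_case(self):
        st, hc = self.make_state_threaded(300, 140, 160, 150)
        assert loop_extent(st, hc) == 20

    def test_whole_tad_limit(self):
        """Rings at the two borders of the TAD span (almost) the whole fibre."""
        st, hc = self.make_state_threaded(300, 140, 160, 150)
        hc.threaded_bead_a, hc.threaded_bead_b = 1, 299
        assert loop_extent(st, hc) == 298

    def test_unthreaded_ring_gives_none_and_logs(self):
        st, hc = self.make_state_threaded(300, 140, 160, 150)
        hc.threaded_bead_b = None
        assert loop_extent(st, hc) is None
        assert any("unthreaded" in m for _, m in st.events)


class TestContactMap:
    def make_traj(self, frames):
        from twistloop.dynamics import Trajectory

        traj = Trajectory(n_fiber=len(frames[0]), circular=False)
        for k, p in enumerate(frames):
            traj.times.append(float(k))
            traj.positions.append(np.asarray(p, float))
        return traj

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        frames = [np.cumsum(rng.standard_normal((30, 3)), axis=0) for _ in range(5)]
        m = contact_map(self.make_traj(frames), cutoff=3.0)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_straight_rod_band_structure(self):
        rod = np.column_stack([np.arange(40.0), np.zeros(40), np.zeros(40)])
        m = contact_map(self.make_traj([rod]), cutoff=4.5)
        i, j = np.nonzero(m)
        assert np.abs(i - j).max() <= 4

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        frames = [np.cumsum(rng.standard_normal((25, 3)), axis=0) for _ in range(3)]
        traj = self.make_traj(frames)
        m1 = contact_map(traj, cutoff=2.0)
        m2 = contact_map(traj, cutoff=4.0)
        assert np.all(m2 >= m1)

    def test_empty_trajectory_rejected(self):
        from twistloop.dynamics import Trajectory

        with pytest.raises(ValueError):
            contact_map(Trajectory(n_fiber=10))


class TestPlectonemes:
    def test_relaxed_circle_has_none(self):
        f = build_fiber(n_beads=80)
        assert detect_plectonemes(f.positions, circular=True) == []

    def test_two_synthetic_hairpins(self):
        """Two glued hairpins: exactly two stems, apexes at the fold points."""

        def hairpin(x0, n_arm=12, dy=1.2):
            out = [np.array([x0 + k, 0.0, 0.0]) for k in range(n_arm)]
            out.append(np.array([x0 + n_arm, dy / 2, 0.0]))
            out += [np.array([x0 + k, dy, 0.0]) for k in range(n_arm - 1, -1, -1)]
            return out

        pts = hairpin(0.0) + hairpin(-14.0)[::-1]
        p = np.array(pts)
        found = detect_plectonemes(p, circular=False, cutoff=1.5, min_stem=3)
        assert len(found) == 2
        found.sort(key=lambda pl: pl.apex)
        mids = sorted(pl.apex for pl in found)
        assert abs(mids[0] - 12) <= 2          # first fold
        assert abs(mids[1] - (25 + 12)) <= 3   # second fold
        for pl in found:
            assert pl.start <= pl.apex <= pl.end
            assert pl.n_rungs >= 3

    def test_segments_disjoint_and_ordered(self):
        rng = np.random.default_rng(9)
        p = np.cumsum(rng.standard_normal((100, 3)) * 0.8, axis=0)
        found = detect_plectonemes(p, circular=False, cutoff=2.0, min_stem=2)
        starts = [pl.start for pl in found]
        assert starts == sorted(starts)


class TestPersistenceLength:
    def test_frozen_rod_flagged_divergent(self):
        rod = np.column_stack([np.arange(50.0), np.zeros(50), np.zeros(50)])
        fit = fit_persistence_length([rod] * 20)
        assert fit.diverged
        assert fit.lp_nm == np.inf

    def test_too_short_trajectory_rejected(self):
        rod = np.column_stack([np.arange(50.0), np.zeros(50), np.zeros(50)])
        with pytest.raises(ValueError, match="frames"):
            fit_persistence_length([rod] * 3)

    def test_recovers_known_correlation_decay(self):
        """Synthetic freely-rotating chains with <cos theta> = exp(-1/5)
        must fit to Lp = 5 sigma = 50 nm."""
        rng = np.random.default_rng(1)
        target = np.exp(-1.0 / 5.0)
        theta = np.arccos(target)
        frames = []
        for _ in range(150):
            t = np.empty((60, 3))
            t[0] = [1.0, 0.0, 0.0]
            for k in range(1, 60):
                prev = t[k - 1]
                a = np.cross(prev, rng.standard_normal(3))
                a /= np.linalg.norm(a)
                phi = rng.uniform(0, 2 * np.pi)
                perp = a * np.cos(phi) + np.cross(prev, a) * np.sin(phi)
                t[k] = prev * np.cos(theta) + perp * np.sin(theta)
            frames.append(np.vstack([[0, 0, 0], np.cumsum(t, axis=0)]))
        fit = fit_persistence_length(frames, seed=0, s_max=8)
        assert fit.lp_nm == pytest.approx(50.0, rel=0.1)
        assert fit.ci_nm[0] < 50.0 < fit.ci_nm[1] or abs(fit.lp_nm - 50) < 5


def test_min_nonbonded_distance_ignores_neighbours():
    rod = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
    assert min_nonbonded_distance(rod, circular=False) == 3.0


class TestWritheInvariances:
    """Property tests: writhe is a rigid-motion invariant pseudo-scalar."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def random_chain(seed, n=14):
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n, 3))
        return np.cumsum(steps / np.linalg.norm(steps, axis=1, keepdims=True), axis=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        p = self.random_chain(seed)
        w0 = writhe(p, True)
        # translate
        assert writhe(p + np.array([3.0, -1.0, 7.0]), True) == pytest.approx(w0, abs=1e-10)
        # rotate about z by an arbitrary angle
        a = 0.7
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        assert writhe(p @ rot.T, True) == pytest.approx(w0, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mirror_flips_sign(self, seed):
        p = self.random_chain(seed)
        assert writhe(p * np.array([1.0, -1.0, 1.0]), True) == pytest.approx(
            -writhe(p, True), abs=1e-10
        )
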