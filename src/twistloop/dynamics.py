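"""Overdamped Langevin dynamics of positions and twist variables.

Positions follow Euler-Maruyama updates (force / gamma * dt plus Gaussian
noise of variance 2 kT dt / gamma per bead, using that bead's effective
drag); material-frame angles follow the analogous rotational update driven
by the torsional torques. Active swivels advance their rest angle each step
(count-exact supercoil injection); the threading detector keeps the drag
rules of the model honest (10x on the fibre bead inside a cohesin ring, 2x
on every cohesin bead); and the CTCF event rule anchors or dissociates
handcuffs at TAD borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import Forcefield, ForceFieldParams
from .geometry import fast_cross, parallel_transport, unit_tangents, unwrap_angles, wrapped_joint_angles
from .model import CohesinHandcuff, Fiber

__all__ = [
    "DynamicsConfig",
    "SimulationState",
    "Trajectory",
    "make_state",
    "step",
    "run",
    "advance_active_swivels",
    "update_threading_and_drag",
    "ctcf_rule",
]

THREADED_PLANE_SLAB = 1.0  # sigma; threading detector tolerance normal to ring plane


@dataclass
class DynamicsConfig:
    """Integration and drag parameters, in reduced units.

    ``gamma_t`` is the base translational friction of a generic fibre bead
    (kT tau / sigma^2; defines tau); ``gamma_r`` the axial rotational
    friction of one segment (kT tau per rad^2), chosen so twist transport is
    faster than injection at the default swivel rate. Threaded fibre beads
    get a 10x drag multiplier (both drags), cohesin beads 2x.
    """

    dt: float = 2e-3
    gamma_t: float = 1.0
    gamma_r: float = 0.1
    threaded_drag_multiplier: float = 10.0
    cohesin_drag_multiplier: float = 2.0
    temperature: float = 1.0
    seed: int = 0
    n_steps: int = 10000
    observe_every: int = 200
    event_every: int = 10
    ctcf_contact_dist: float = 3.0
    ctcf_dwell: float = 10.0
    ctcf_contour_range: int = 10
    max_force_displacement: float = 0.1
    freeze_positions: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.threaded_drag_multiplier < 1 or self.cohesin_drag_multiplier < 1:
            raise ValueError("drag multipliers must be >= 1")


class SimulationState:
    """One time point of the full system: fibre + handcuffs + CTCF obstacles.

    All bead coordinates live in one (N, 3) array ``X``; the fibre, handcuff
    and CTCF objects hold views into it, so model-level accessors stay in
    sync with the integrator. Layout: fibre beads first, then 29 beads per
    handcuff, then one obstacle bead per CTCF site.
    """

    def __init__(
        self,
        fiber: Fiber,
        handcuffs: list[CohesinHandcuff] | None = None,
        seed: int = 0,
    ):
        self.fiber = fiber
        self.handcuffs = handcuffs or []
        nf = fiber.n_beads
        self.n_fiber = nf
        nh = sum(h.n_beads for h in self.handcuffs)
        nc = len(fiber.ctcf_sites)
        self.n_total = nf + nh + nc

        X = np.empty((self.n_total, 3))
        X[:nf] = fiber.positions
        off = nf
        self.handcuff_offsets = []
        for h in self.handcuffs:
            X[off:off + h.n_beads] = h.positions
            self.handcuff_offsets.append(off)
            off += h.n_beads
        self.ctcf_offset = off
        for k, site in enumerate(fiber.ctcf_sites):
            X[off + k] = site.position if site.position is not None else fiber.positions[site.fibre_bead]
        self.X = X
        # rebind model arrays as views into X
        fiber.positions = X[:nf]
        for h, o in zip(self.handcuffs, self.handcuff_offsets):
            h.positions = X[o:o + h.n_beads]

        self.radii = np.empty(self.n_total)
        self.radii[:nf] = fiber.bead_radius
        for h, o in zip(self.handcuffs, self.handcuff_offsets):
            self.radii[o:o + h.n_beads] = h.bead_radius
        for k, site in enumerate(fiber.ctcf_sites):
            self.radii[self.ctcf_offset + k] = site.radius

        self.drag_mult = np.ones(self.n_total)
        self.frozen = np.zeros(self.n_total, dtype=bool)
        self.anchor_bonds: list[tuple[int, int, float, float]] = []
        self.topology_version = 0
        self.time = 0.0
        self.rng = np.random.default_rng(seed)
        self.events: list[tuple[float, str]] = []
        self._ctcf_contact_since: dict[tuple[int, int], float] = {}
        self._noise_prev = None
        self._rnoise_prev = None
        self.lk0 = 0.0  # set by make_state once twist/writhe are initialised

    # -- bookkeeping ---------------------------------------------------------

    def log_event(self, message: str) -> None:
        self.events.append((self.time, message))

    def handcuff_bead_slice(self, h_index: int) -> slice:
        off = self.handcuff_offsets[h_index]
        return slice(off, off + self.handcuffs[h_index].n_beads)

    def effective_gamma_t(self, config: DynamicsConfig) -> np.ndarray:
        """Per-bead translational friction: base drag scaled by bead radius
        (Stokes-like) times the threading/cohesin multipliers."""
        size_scale = self.radii / 0.5
        return config.gamma_t * size_scale * self.drag_mult

    def segment_gamma_r(self, config: DynamicsConfig) -> np.ndarray:
        """Per-segment rotational friction, using the lower bead's multiplier."""
        mult = self.drag_mult[: self.fiber.n_segments]
        return config.gamma_r * mult


@dataclass
class Trajectory:
    """Observation frames plus the per-frame observables table."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)      # (N, 3) per frame
    fiber_slices: slice | None = None
    roles: np.ndarray | None = None                    # per-bead role labels
    observables: pd.DataFrame | None = None
    events: list = field(default_factory=list)
    n_fiber: int = 0
    circular: bool = True

    def fiber_positions(self, frame: int) -> np.ndarray:
        return self.positions[frame][: self.n_fiber]

    @property
    def n_frames(self) -> int:
        return len(self.times)


def make_state(
    fiber: Fiber,
    handcuffs: list[CohesinHandcuff] | None = None,
    seed: int = 0,
) -> SimulationState:
    """Assemble a simulation state and record the reference linking number."""
    from .topology import twist, writhe

    state = SimulationState(fiber, handcuffs, seed=seed)
    if fiber.circular:
        tw = twist(fiber)
        wr = writhe(fiber.positions, circular=True)
        state.lk0 = round(tw + wr)
    return state


# -- elementary updates -----------------------------------------------------


def advance_active_swivels(state: SimulationState, dt: float) -> SimulationState:
    """Advance every motor's rest angle; count-exact injection bookkeeping.

    A non-barrier motor advances the rest angle phi0 of its (elastic) joint
    by -sign * 2 pi * rate * dt: the joint angle follows the motor, pushing
    the opposite twist into the flanking fibre. A barrier motor's joint is
    torsionally free (no twist exchanged between flanks); instead the
    material frame of the upstream segment is rotated directly, so all
    injection lands in one flank.
    """
    fib = state.fiber
    for sw in fib.active_swivels:
        if sw.rate_omega == 0.0:
            continue
        dturns = sw.rate_omega * dt
        dphi = 2.0 * np.pi * dturns
        ji = fib.joint_index(sw.joint)
        if sw.barrier:
            seg = (ji - 1) % fib.n_segments if fib.circular else ji  # upstream segment
            t = fib.tangents()[seg]
            ang = sw.sign * dphi
            m = fib.frames[seg]
            fib.frames[seg] = (
                m * np.cos(ang) + np.cross(t, m) * np.sin(ang) + t * np.dot(t, m) * (1 - np.cos(ang))
            )
        else:
            fib.joint_twist0[ji] += -sw.sign * dphi
        sw.injected_R += dturns
    return state


def update_threading_and_drag(state: SimulationState, config: DynamicsConfig) -> SimulationState:
    """Identify the fibre bead inside each cohesin ring; apply drag rules.

    A bead is threaded if it is the nearest fibre bead to the ring centre,
    lies within the inner aperture radially, and within +-1 sigma of the
    ring plane. Ties go to the lowest index. Threaded beads get the 10x
    multiplier, all cohesin beads 2x, everything else 1x.
    """
    state.drag_mult[:] = 1.0
    fib = state.fiber
    for hi, (h, off) in enumerate(zip(state.handcuffs, state.handcuff_offsets)):
        if h.state == "dissociated":
            continue
        state.drag_mult[off:off + h.n_beads] = config.cohesin_drag_multiplier
        aperture = h.aperture_radius_sigma()
        for which in ("a", "b"):
            centre = h.ring_centre(which)
            normal = h.ring_normal(which)
            rel = fib.positions - centre
            z = rel @ normal
            radial = np.linalg.norm(rel - np.outer(z, normal), axis=1)
            ok = (np.abs(z) <= THREADED_PLANE_SLAB) & (radial <= aperture)
            prev = h.threaded_bead_a if which == "a" else h.threaded_bead_b
            if not np.any(ok):
                bead = None
                if prev is not None:
                    state.log_event(f"handcuff {hi} ring {which} unthreaded")
            else:
                dist = np.linalg.norm(rel, axis=1)
                dist[~ok] = np.inf
                bead = int(np.argmin(dist))  # argmin takes the lowest index on ties
            if which == "a":
                h.threaded_bead_a = bead
            else:
                h.threaded_bead_b = bead
            if bead is not None:
                state.drag_mult[bead] = config.threaded_drag_multiplier
    return state


def ctcf_rule(state: SimulationState, config: DynamicsConfig) -> SimulationState:
    """Anchor or dissociate handcuffs on CTCF contact.

    Convergent CTCF exposes its cohesin-binding C terminus: a ring arriving
    within ``ctcf_contact_dist`` anchors (harmonic bonds ring-to-obstacle).
    Divergent CTCF offers no stabilising contact: after ``ctcf_dwell`` time
    in continuous contact the whole handcuff dissociates (restraints,
    excluded volume and drag couplings removed; beads frozen in place).
    """
    fib = state.fiber
    for hi, (h, off) in enumerate(zip(state.handcuffs, state.handcuff_offsets)):
        if h.state == "dissociated":
            continue
        for wi, which in enumerate(("a", "b")):
            if which in h.anchored_rings:
                continue
            centre = h.ring_centre(which)
            threaded = h.threaded_bead_a if which == "a" else h.threaded_bead_b
            for ci, site in enumerate(fib.ctcf_sites):
                # the orientation-specific C-terminal contact happens for the
                # ring that has arrived at the site along the chromatin, not
                # for a ring that merely drifts past in space
                if threaded is None:
                    continue
                if fib.contour_distance(threaded, site.fibre_bead) > config.ctcf_contour_range:
                    continue
                gi = state.ctcf_offset + ci
                d = float(np.linalg.norm(centre - state.X[gi]))
                key = (hi * 2 + wi, ci)
                if d > config.ctcf_contact_dist:
                    # thermal bouncing must not reset the dwell clock: the
                    # clock survives until the ring truly leaves the obstacle
                    if d > 2.0 * config.ctcf_contact_dist:
                        state._ctcf_contact_since.pop(key, None)
                    continue
                if site.orientation == "convergent":
                    ring_idx = (h.ring_a if which == "a" else h.ring_b) + off
                    rel = np.linalg.norm(state.X[ring_idx] - state.X[gi], axis=1)
                    for bi in ring_idx[np.argsort(rel)[:3]]:
                        r0 = float(np.linalg.norm(state.X[bi] - state.X[gi]))
                        state.anchor_bonds.append((int(bi), gi, r0, 50.0))
                    h.anchored_rings.add(which)
                    h.state = "anchored"
                    state.log_event(
                        f"handcuff {hi} ring {which} anchored at CTCF bead {site.fibre_bead}"
                    )
                else:
                    t0 = state._ctcf_contact_since.setdefault(key, state.time)
                    if state.time - t0 >= config.ctcf_dwell:  # pressed long enough
                        h.state = "dissociated"
                        h.threaded_bead_a = None
                        h.threaded_bead_b = None
                        sl = state.handcuff_bead_slice(hi)
                        state.frozen[sl] = True
                        state.drag_mult[sl] = 1.0
                        state.anchor_bonds = [
                            (i, j, r0, k) for (i, j, r0, k) in state.anchor_bonds
                            if not (sl.start <= i < sl.stop or sl.start <= j < sl.stop)
                        ]
                        state.topology_version += 1
                        state.log_event(
                            f"handcuff {hi} dissociated at divergent CTCF bead {site.fibre_bead}"
                        )
                        break
            if h.state == "dissociated":
                break
    return state


def step(state: SimulationState, config: DynamicsConfig, ff: Forcefield) -> SimulationState:
    """One Euler-Maruyama step of positions and twist variables."""
    fib = state.fiber
    kT = config.temperature
    dt = config.dt

    F, tau, _ = ff.forces(state)

    moving = ~state.frozen
    if not config.freeze_positions:
        t_old = getattr(fib, "frames_tangent_cache", None)
        if t_old is None:
            t_old = unit_tangents(fib.positions, fib.circular)
        gamma = state.effective_gamma_t(config)
        disp = F * (dt / gamma)[:, None]
        # cap the force-driven displacement per bead: steep WCA/FENE walls
        # otherwise overshoot under explicit Euler (equivalent to sub-stepping
        # hard collisions; thermal noise is left untouched)
        norms = np.linalg.norm(disp, axis=1)
        big = norms > config.max_force_displacement
        if np.any(big):
            disp[big] *= (config.max_force_displacement / norms[big])[:, None]
        if kT > 0:
            # Leimkuhler-Matthews update: averaging successive Gaussians gives
            # second-order configurational sampling at Euler cost
            noise = state.rng.standard_normal(state.X.shape)
            prev = state._noise_prev if state._noise_prev is not None else noise
            disp += np.sqrt(2.0 * kT * dt / gamma)[:, None] * 0.5 * (prev + noise)
            state._noise_prev = noise
        state.X[moving] += disp[moving]

        # transport material frames to the new tangents (holonomy tracking)
        t_new = unit_tangents(fib.positions, fib.circular)
        fib.frames = parallel_transport(fib.frames, t_old, t_new)
        # re-orthonormalise against accumulated drift
        fib.frames -= np.einsum("ij,ij->i", fib.frames, t_new)[:, None] * t_new
        fib.frames /= np.linalg.norm(fib.frames, axis=1)[:, None]
        fib.frames_tangent_cache = t_new
    else:
        t_new = unit_tangents(fib.positions, fib.circular)
        fib.frames_tangent_cache = t_new

    # rotational update of segment frames about their tangents
    gamma_r = state.segment_gamma_r(config)
    dpsi = tau * (dt / gamma_r)
    if kT > 0:
        rnoise = state.rng.standard_normal(fib.n_segments)
        rprev = state._rnoise_prev if state._rnoise_prev is not None else rnoise
        dpsi += np.sqrt(2.0 * kT * dt / gamma_r) * 0.5 * (rprev + rnoise)
        state._rnoise_prev = rnoise
    if np.any(dpsi):
        c = np.cos(dpsi)[:, None]
        s = np.sin(dpsi)[:, None]
        m = fib.frames
        tdotm = np.einsum("ij,ij->i", t_new, m)[:, None]
        fib.frames = m * c + fast_cross(t_new, m) * s + t_new * tdotm * (1.0 - c)

    advance_active_swivels(state, dt)

    # refresh unwrapped twist angles from the frames
    wrapped = wrapped_joint_angles(fib.frames, t_new, fib.circular)
    fib.joint_twist = unwrap_angles(wrapped, fib.joint_twist)

    state.time += dt
    return state


def run(
    state: SimulationState,
    config: DynamicsConfig,
    params: ForceFieldParams | None = None,
    stop_injected_R: float | None = None,
    observer=None,
) -> Trajectory:
    """Integrate; record observables every ``observe_every`` steps.

    Stops after ``config.n_steps`` or once the first active swivel's
    rotation counter reaches ``stop_injected_R``, whichever comes first.
    Fully reproducible from (state geometry, config, seed).
    """
    from .topology import frame_observables

    params = params or ForceFieldParams()
    ff = Forcefield(state, params)
    fib = state.fiber

    traj = Trajectory(n_fiber=state.n_fiber, circular=fib.circular)
    traj.roles = _role_labels(state)

    update_threading_and_drag(state, config)
    rows = []

    def observe():
        traj.times.append(state.time)
        traj.positions.append(state.X.copy())
        rows.append(frame_observables(state))
        if observer is not None:
            observer(state)

    observe()
    n = 0
    while n < config.n_steps:
        step(state, config, ff)
        n += 1
        if n % config.event_every == 0:
            update_threading_and_drag(state, config)
            if fib.ctcf_sites and state.handcuffs:
                ctcf_rule(state, config)
        if n % config.observe_every == 0:
            observe()
        if stop_injected_R is not None and fib.active_swivels:
            if fib.active_swivels[0].injected_R >= stop_injected_R:
                break
    if not traj.times or traj.times[-1] != state.time:
        update_threading_and_drag(state, config)
        observe()
    traj.observables = pd.DataFrame(rows)
    traj.events = list(state.events)
    return traj


def _role_labels(state: SimulationState) -> np.ndarray:
    roles = np.empty(state.n_total, dtype="<U1")
    roles[: state.n_fiber] = "F"
    roles[: state.n_fiber][state.fiber.phantom_beads] = "P"
    for h, off in zip(state.handcuffs, state.handcuff_offsets):
        roles[off:off + h.n_beads] = "C"
    roles[state.ctcf_offset:] = "X"
    return roles
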