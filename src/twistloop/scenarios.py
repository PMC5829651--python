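"""Programmatic builders for every simulated experiment.

Each scenario configures a TAD-sized circular chromatin fibre with the
machinery of one figure-level experiment: a central or off-centre torsional
motor, passive swivels flanked by phantom regions at the TAD borders
(topoisomerase II), optionally a threaded cohesin handcuff and CTCF
obstacle beads. Placements are expressed as fractions of the fibre length,
so every scenario also runs at reduced bead counts for desk-scale testing.

The canonical system is a 300-bead (120 kb) circle. Border machinery sits
diametrically opposite the motor: the two TAD borders are brought together
at bead 0 of the circle, which is how a circular construct represents one
TAD with its flanks glued.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dynamics import DynamicsConfig, SimulationState, make_state
from .forcefield import ForceFieldParams
from .model import (
    RING_CENTRE_DIAMETER,
    Fiber,
    add_active_swivel,
    add_ctcf,
    add_passive_swivel,
    add_phantom_region,
    build_fiber,
    build_handcuff,
    thread_handcuff,
)
from .units import UnitSystem

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "build_scenario_state",
           "run_scenario", "reference_outcome", "threaded_loop_conformation",
           "sample_equilibrium_linear_fiber", "persistence_length_experiment"]

SCENARIO_NAMES = (
    "fig1",
    "fig2_free",
    "fig2_handcuffed",
    "fig3",
    "fig4_asymmetric",
    "fig5_convergent",
    "fig5_divergent",
    "supp_low_twist",
    "supp_barrier",
)


@dataclass
class Scenario:
    """Fully serialisable description of one experiment."""

    name: str
    n_beads: int = 300
    circular: bool = True
    swivel_joint: int = 150
    swivel_rate: float = 0.05
    swivel_sign: int = -1
    swivel_barrier: bool = False
    passive_swivels: list = field(default_factory=list)
    phantom_regions: list = field(default_factory=list)   # [start, stop) pairs
    thread_beads: list | None = None                      # [bead_a, bead_b]
    ctcf_sites: list = field(default_factory=list)        # [bead, orientation]
    lt_scale: float = 1.0
    stop_injected_R: float | None = None
    n_steps: int = 200_000
    equilibrate_steps: int = 2_000
    outcome: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)


def make_scenario(name: str, n_beads: int = 300, **overrides) -> Scenario:
    """Build the named scenario, with placements scaled to ``n_beads``.

    Unknown names are rejected with the list of valid ones. ``overrides``
    replace any Scenario field after placement computation.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    n = int(n_beads)
    mid = n // 2
    gap = max(3, round(n / 60))            # border half-gap, beads
    borders = [n - gap, gap]               # passive-swivel joints (TAD borders)
    phantoms = [[n - gap - 1, n - gap + 2], [gap - 1, gap + 2]]

    sc = Scenario(name=name, n_beads=n, swivel_joint=mid)
    # keep the injected turns per bead per unit time fixed across system
    # sizes, so reduced desk-scale fibres stay in the same transport-limited
    # regime as the canonical 300-bead TAD
    sc.swivel_rate = 0.05 * 300.0 / n
    sc.stop_injected_R = 10.0

    if name == "fig1":
        sc.outcome = "plectoneme formation; |Tw+Wr| change equals injected rotations"
    elif name in ("fig2_free", "fig2_handcuffed", "fig3", "supp_low_twist", "supp_barrier"):
        sc.passive_swivels = borders
        sc.phantom_regions = phantoms
        if name != "fig2_free":
            sc.thread_beads = [n // 4, 3 * n // 4]
        if name == "fig2_free":
            sc.outcome = "supercoiling dissipates at borders; low steady |Wr|"
        elif name == "fig2_handcuffed":
            sc.outcome = "supercoiling localises in the handcuff-enclosed loop"
        else:
            sc.outcome = "loop extent grows to the whole TAD"
        if name in ("fig3", "supp_low_twist", "supp_barrier"):
            sc.stop_injected_R = None
            sc.n_steps = 400_000
        if name == "supp_low_twist":
            sc.lt_scale = 0.1
        if name == "supp_barrier":
            sc.swivel_barrier = True
            sc.outcome = "hemi-plectoneme: one flank torsionally relaxed"
    else:  # fig4 / fig5 family: off-centre motor, CTCF obstacles at borders
        sc.swivel_joint = n // 4
        sc.passive_swivels = borders
        sc.phantom_regions = phantoms
        # keep the 1:4 threading asymmetry; at reduced bead counts enforce a
        # minimum loop size able to nucleate a pushing plectoneme (~5 turns)
        target_loop = max(30, round(n / 6))
        d_near = max(4, round(target_loop / 5))
        d_far = target_loop - d_near
        sc.thread_beads = [sc.swivel_joint - d_near, sc.swivel_joint + d_far]
        orient = {"fig4_asymmetric": ("convergent", "convergent"),
                  "fig5_convergent": ("convergent", "convergent"),
                  "fig5_divergent": ("divergent", "divergent")}[name]
        sc.ctcf_sites = [[gap + 1, orient[0]], [n - gap - 1, orient[1]]]
        sc.stop_injected_R = None
        sc.n_steps = 400_000
        sc.outcome = ("near ring anchors first, far ring continues"
                      if name == "fig4_asymmetric"
                      else "border-border contact frequency set by CTCF orientation")

    for k, v in overrides.items():
        if not hasattr(sc, k):
            raise ValueError(f"unknown scenario field {k!r}")
        setattr(sc, k, v)
    return sc


def sample_equilibrium_linear_fiber(
    n_beads: int,
    params: ForceFieldParams | None = None,
    seed: int = 0,
    units: UnitSystem | None = None,
) -> Fiber:
    """Linear fibre drawn from the ideal-chain equilibrium ensemble.

    Joint angles are sampled from the Boltzmann distribution of the harmonic
    bending potential (P(theta) ~ exp(-k theta^2/2) sin(theta), rejection
    sampling under a Rayleigh envelope), azimuths uniformly. Starting from
    such a conformation, the slow long-wavelength bending modes are already
    at their equilibrium amplitude, so only short local equilibration is
    needed before measuring tangent correlations.
    """
    units = units or UnitSystem()
    params = params or ForceFieldParams(units=units)
    rng = np.random.default_rng(seed)
    k = params.k_bend

    def draw_theta(size):
        out = np.empty(size)
        filled = 0
        while filled < size:
            cand = rng.rayleigh(1.0 / np.sqrt(k), size=2 * (size - filled))
            cand = cand[cand < np.pi]
            acc = cand[rng.random(len(cand)) < np.sin(cand) / cand]
            take = min(len(acc), size - filled)
            out[filled:filled + take] = acc[:take]
            filled += take
        return out

    n = int(n_beads)
    t = np.empty((n - 1, 3))
    t[0] = (0.0, 0.0, 1.0)
    thetas = draw_theta(n - 2)
    phis = rng.uniform(0.0, 2.0 * np.pi, n - 2)
    for i in range(1, n - 1):
        prev = t[i - 1]
        a = np.cross(prev, (1.0, 0.0, 0.0))
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(prev, (0.0, 1.0, 0.0))
        a /= np.linalg.norm(a)
        b = np.cross(prev, a)
        th, ph = thetas[i - 1], phis[i - 1]
        t[i] = prev * np.cos(th) + (a * np.cos(ph) + b * np.sin(ph)) * np.sin(th)
    pos = np.vstack([np.zeros(3), np.cumsum(t * params.l0, axis=0)])
    return Fiber(pos, circular=False, units=units)


def persistence_length_experiment(
    seed: int = 0,
    n_beads: int = 100,
    n_replicas: int = 40,
    equil_steps: int = 5_000,
    production_steps: int = 15_000,
    observe_every: int = 1_500,
    s_max: int = 8,
    params: ForceFieldParams | None = None,
):
    """Recover the bending persistence length from simulated trajectories.

    Runs ``n_replicas`` independent linear-fibre simulations (equilibrium
    starting conformations, local re-equilibration, then production), pools
    all observation frames and fits the tangent-correlation decay out to
    ``s_max`` bonds (~1.5 Lp at the defaults). Many short replicas beat one
    long run: the large-scale conformation decorrelates over ~1e3 tau, so a
    single trajectory holds only a handful of independent samples of the
    tangent-correlation tail, while every replica contributes a fresh
    equilibrium draw.
    """
    from .dynamics import run
    from .topology import fit_persistence_length

    params = params or ForceFieldParams()
    frames = []
    for rep in range(n_replicas):
        fiber = sample_equilibrium_linear_fiber(n_beads, params, seed=seed + rep)
        state = make_state(fiber, seed=seed + rep)
        run(state, DynamicsConfig(seed=seed + rep, n_steps=equil_steps,
                                  observe_every=equil_steps or 1), params)
        traj = run(state, DynamicsConfig(seed=seed + 1000 + rep, n_steps=production_steps,
                                         observe_every=observe_every), params)
        frames += [traj.fiber_positions(k) for k in range(1, traj.n_frames)]
    return fit_persistence_length(frames, units=params.units, s_max=s_max, seed=seed)


def threaded_loop_conformation(n: int, bead_a: int, bead_b: int, swivel: int) -> np.ndarray:
    """Deterministic circular-fibre conformation prepared for threading.

    The arc from ``bead_a`` to ``bead_b`` that contains ``swivel`` (the
    future supercoiled loop) runs through a stadium-shaped path above the
    handcuff plane; the rest of the circle runs through a mirrored stadium
    below it. Beads ``a`` and ``b`` sit one ring-spacing apart with parallel
    tangents perpendicular to the handcuff plane, exactly where the two
    cohesin rings will be centred.
    """
    rho = 0.5 * RING_CENTRE_DIAMETER
    d_ab = (bead_b - bead_a) % n
    swivel_on_ab = (swivel - bead_a) % n <= d_ab
    loop_len = d_ab if swivel_on_ab else n - d_ab
    # walk the loop forward from a to b if it contains the swivel, else from b
    start, end = (bead_a, bead_b) if swivel_on_ab else (bead_b, bead_a)
    if loop_len < int(np.ceil(np.pi * rho)) + 2 or n - loop_len < int(np.ceil(np.pi * rho)) + 2:
        raise ValueError("arcs too short to lay out a threaded conformation")

    def stadium(length: int, sign_z: float, x0: float) -> np.ndarray:
        """Unit-arclength samples along straight-up/semicircle/straight-down."""
        h = (length - np.pi * rho) / 2.0
        s = np.arange(length + 1, dtype=float)
        pts = np.empty((length + 1, 3))
        pts[:, 1] = 0.0
        up = s <= h
        arc = (s > h) & (s <= h + np.pi * rho)
        down = s > h + np.pi * rho
        pts[up, 0] = x0
        pts[up, 2] = sign_z * s[up]
        alpha = (s[arc] - h) / rho
        pts[arc, 0] = x0 * np.cos(alpha)
        pts[arc, 2] = sign_z * (h + rho * np.sin(alpha))
        pts[down, 0] = -x0
        pts[down, 2] = sign_z * (length - s[down])
        return pts

    pos = np.empty((n, 3))
    loop_pts = stadium(loop_len, +1.0, -rho if swivel_on_ab else rho)
    for k in range(loop_len + 1):
        pos[(start + k) % n] = loop_pts[k]
    outer_len = n - loop_len
    outer_pts = stadium(outer_len, -1.0, rho if swivel_on_ab else -rho)
    for k in range(outer_len + 1):
        pos[(end + k) % n] = outer_pts[k]
    return pos


def build_scenario_state(
    scenario: Scenario,
    seed: int = 0,
    units: UnitSystem | None = None,
) -> tuple[SimulationState, ForceFieldParams, DynamicsConfig]:
    """Instantiate the scenario: fibre + annotations + handcuff + CTCF.

    Deterministic: identical (scenario, seed) give identical states.
    """
    units = units or UnitSystem()
    sc = scenario
    fiber = build_fiber(n_beads=sc.n_beads, circular=sc.circular, units=units)

    if sc.thread_beads is not None:
        pos = threaded_loop_conformation(
            sc.n_beads, sc.thread_beads[0], sc.thread_beads[1], sc.swivel_joint
        )
        fiber = Fiber(pos, sc.circular, units)

    add_active_swivel(
        fiber, sc.swivel_joint, rate_omega=sc.swivel_rate,
        sign=sc.swivel_sign, barrier=sc.swivel_barrier,
    )
    for j in sc.passive_swivels:
        add_passive_swivel(fiber, j)
    for start, stop in sc.phantom_regions:
        add_phantom_region(fiber, start, stop)
    for bead, orientation in sc.ctcf_sites:
        add_ctcf(fiber, bead, orientation=orientation)

    handcuffs = []
    if sc.thread_beads is not None:
        hc = thread_handcuff(fiber, build_handcuff(units=units), *sc.thread_beads)
        handcuffs.append(hc)

    params = ForceFieldParams(units=units)
    if sc.lt_scale != 1.0:
        params = ForceFieldParams(lt_nm=params.lt_nm * sc.lt_scale, units=units)
    config = DynamicsConfig(seed=seed, n_steps=sc.n_steps)
    state = make_state(fiber, handcuffs, seed=seed)
    return state, params, config


def run_scenario(
    scenario: Scenario,
    seed: int = 0,
    config: DynamicsConfig | None = None,
    params: ForceFieldParams | None = None,
):
    """Equilibrate (motor off), then run the scenario to its stop condition."""
    from .dynamics import run

    state, p0, c0 = build_scenario_state(scenario, seed=seed)
    params = params or p0
    config = config or c0

    if scenario.equilibrate_steps > 0:
        rates = [(sw, sw.rate_omega) for sw in state.fiber.active_swivels]
        for sw, _ in rates:
            sw.rate_omega = 0.0
        eq_cfg = DynamicsConfig(
            seed=config.seed, n_steps=scenario.equilibrate_steps,
            observe_every=max(scenario.equilibrate_steps, 1), dt=config.dt,
        )
        run(state, eq_cfg, params)
        for sw, rate in rates:
            sw.rate_omega = rate
        state.time = 0.0
        state.events.clear()

    return run(state, config, params, stop_injected_R=scenario.stop_injected_R)


def reference_outcome(name: str) -> dict:
    """The assertable property bundle for each scenario (acceptance suite)."""
    outcomes = {
        "fig1": {"abs_delta_tw_wr_equals_R": 10.0, "tolerance_turns": 0.05,
                 "final_abs_wr_min": 5.0},
        "fig2_free": {"steady_abs_wr_max": 2.0},
        "fig2_handcuffed": {"enclosed_wr_fraction_min": 0.8},
        "fig3": {"final_loop_fraction_min": 0.8, "smoothing_window": 10},
        "fig4_asymmetric": {"near_ring_anchors_first": True},
        "fig5_convergent": {"corner_contact_exceeds": "fig5_divergent"},
        "fig5_divergent": {"corner_contact_below": "fig5_convergent"},
        "supp_low_twist": {"lt_scale": 0.1, "final_loop_fraction_min": 0.8},
        "supp_barrier": {"flank_twist_asymmetry": True},
    }
    if name not in outcomes:
        raise ValueError(f"no registered outcome for {name!r}")
    return outcomes[name]
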