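"""Domain types and constructors: fibres, cohesin handcuffs, swivels, CTCF.

The modelled system is a TAD-sized 10-nm chromatin fibre represented as a
bead-spring twistable worm-like chain. Annotations on the fibre encode the
biological machinery:

* active swivels -- RNA polymerase plus co-travelling TOP1, injecting net
  negative supercoiling by enforced relative axial rotation of the flanking
  fibre segments;
* passive swivels -- joints with zero torsional stiffness, emulating local
  torsional relaxation by topoisomerase II at TAD borders;
* phantom regions -- fibre stretches without excluded volume, permitting
  intersegmental strand passage (TOP2B action);
* CTCF sites -- bulky obstacle beads at TAD borders, larger than the
  aperture of a cohesin ring, whose orientation (convergent/divergent)
  decides whether an arriving cohesin ring anchors or the handcuff
  dissociates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import initial_frames, unit_tangents
from .units import UnitSystem

__all__ = [
    "ActiveSwivel",
    "CTCFSite",
    "PhantomRegion",
    "Fiber",
    "CohesinHandcuff",
    "build_fiber",
    "build_handcuff",
    "thread_handcuff",
    "add_active_swivel",
    "add_passive_swivel",
    "add_phantom_region",
    "add_ctcf",
]

def supercoils_per_transcript(transcript_nt: float, bases_per_supercoil: float = 10.0) -> float:
    """Net negative supercoils injected by one transcription round.

    RNA polymerase with TOP1 positioned ahead of it leaves one unrelaxed
    negative supercoil behind per ~10 transcribed bases, so a single round
    over an average 350-nt eRNA injects 35 supercoils -- more than enough to
    drive plectoneme growth between rounds.
    """
    if transcript_nt <= 0 or bases_per_supercoil <= 0:
        raise ValueError("transcript length and pitch must be positive")
    return transcript_nt / bases_per_supercoil


#: default diameter of the circle traced by the bead centres of one cohesin
#: ring, in sigma. With a 1-sigma bead cross-section this gives the ring an
#: external diameter of 4.5 sigma (45 nm) and an inner aperture of 2.5 sigma
#: (25 nm).
RING_CENTRE_DIAMETER = 3.5
BEADS_PER_RING = 15
#: cohesin beads share the generic fibre bead cross-section (1 sigma diameter);
#: the printed 45 nm / 25 nm ring diameters are only mutually consistent with
#: this choice.
COHESIN_BEAD_RADIUS = 0.5


@dataclass
class ActiveSwivel:
    """Torsional motor at one fibre joint (RNA polymerase + TOP1).

    ``rate_omega`` is in full turns per tau; ``sign`` is -1 for net negative
    supercoil injection. ``injected_R`` accumulates the rotations performed.
    If ``barrier`` is set the motor is a topological barrier (continuously
    transcribing polymerase): no twist is exchanged between the two flanking
    segments and all injection goes into the upstream flank.
    """

    joint: int
    rate_omega: float = 0.05
    sign: int = -1
    injected_R: float = 0.0
    barrier: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"swivel sign must be -1 or +1, got {self.sign}")
        if self.rate_omega < 0:
            raise ValueError("swivel rate must be >= 0")


@dataclass
class CTCFSite:
    """Bulky CTCF obstacle attached to one fibre bead.

    The obstacle is a single large bead tied to its attachment bead; its
    diameter (default 3.5 sigma = 35 nm) exceeds the 25 nm ring aperture, so
    blocking of cohesin rings is purely geometric.
    """

    fibre_bead: int
    orientation: str = "convergent"
    obstacle_diameter: float = 3.5
    bound_topo2: bool = False
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("convergent", "divergent"):
            raise ValueError(
                f"orientation must be 'convergent' or 'divergent', got {self.orientation!r}"
            )
        if self.obstacle_diameter <= 0:
            raise ValueError("obstacle_diameter must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.obstacle_diameter


@dataclass(frozen=True)
class PhantomRegion:
    """Contiguous bead interval [start, stop) with excluded volume disabled."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("phantom region must be a non-empty half-open interval")

    def beads(self) -> range:
        return range(self.start, self.stop)


class Fiber:
    """Twistable bead-spring chromatin fibre.

    Positions are in sigma. Material frames live on segments (bonds); twist
    angles live on the joints between consecutive segments: n joints for a
    circular chain of n beads, n - 2 interior joints for a linear chain.
    Joints are identified by the bead index at which they sit.
    """

    def __init__(
        self,
        positions: np.ndarray,
        circular: bool,
        units: UnitSystem | None = None,
        bead_radius: float = 0.5,
    ):
        self.positions = np.asarray(positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        self.circular = bool(circular)
        self.units = units or UnitSystem()
        self.bead_radius = float(bead_radius)
        self.frames = initial_frames(self.positions, self.circular)
        nj = self.n_joints
        self.joint_twist = np.zeros(nj)       # unwrapped material twist, rad
        self.joint_twist0 = np.zeros(nj)      # rest (motor-driven) angle, rad
        self.phantom_beads = np.zeros(self.n_beads, dtype=bool)
        self.active_swivels: list[ActiveSwivel] = []
        self.passive_swivels: set[int] = set()
        self.ctcf_sites: list[CTCFSite] = []

    # -- sizes and index conventions ---------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_segments(self) -> int:
        return self.n_beads if self.circular else self.n_beads - 1

    @property
    def n_joints(self) -> int:
        return self.n_beads if self.circular else self.n_beads - 2

    def joint_beads(self) -> np.ndarray:
        """Bead index at which each joint sits, in joint-array order."""
        if self.circular:
            return np.arange(self.n_beads)
        return np.arange(1, self.n_beads - 1)

    def joint_index(self, bead: int) -> int:
        """Position of the joint at ``bead`` in the joint arrays."""
        if self.circular:
            if not 0 <= bead < self.n_beads:
                raise IndexError(f"joint bead {bead} out of range")
            return bead
        if not 1 <= bead <= self.n_beads - 2:
            raise IndexError(f"linear fibre has interior joints 1..{self.n_beads - 2}")
        return bead - 1

    def tangents(self) -> np.ndarray:
        return unit_tangents(self.positions, self.circular)

    # -- masks used by the force field and observables ---------------------

    def passive_joint_mask(self) -> np.ndarray:
        """True at joints with zero torsional stiffness (passive swivels and
        the slip face of barrier motors)."""
        mask = np.zeros(self.n_joints, dtype=bool)
        for j in self.passive_swivels:
            mask[self.joint_index(j)] = True
        for sw in self.active_swivels:
            if sw.barrier:
                mask[self.joint_index(sw.joint)] = True
        return mask

    def contour_distance(self, a: int, b: int, through_joint: int | None = None) -> int:
        """Contour distance (in bonds) between beads a and b.

        For circular fibres, ``through_joint`` selects the arc that contains
        the given joint bead; otherwise the shorter arc is returned.
        """
        n = self.n_beads
        if not self.circular:
            return abs(b - a)
        d_fwd = (b - a) % n
        if through_joint is None:
            return min(d_fwd, n - d_fwd)
        on_fwd = (through_joint - a) % n <= d_fwd
        return d_fwd if on_fwd else n - d_fwd

    def copy_geometry(self) -> "Fiber":
        f = Fiber(self.positions.copy(), self.circular, self.units, self.bead_radius)
        f.frames = self.frames.copy()
        f.joint_twist = self.joint_twist.copy()
        f.joint_twist0 = self.joint_twist0.copy()
        f.phantom_beads = self.phantom_beads.copy()
        return f


def build_fiber(
    length_bp: int | None = None,
    n_beads: int | None = None,
    circular: bool = True,
    units: UnitSystem | None = None,
) -> Fiber:
    """Construct an equilateral ring (circular) or straight rod (linear).

    Exactly one of ``length_bp`` / ``n_beads`` must be given. Bond length is
    1 sigma; twist angles start at zero; construction is deterministic.
    """
    units = units or UnitSystem()
    if (length_bp is None) == (n_beads is None):
        raise ValueError("give exactly one of length_bp or n_beads")
    n = units.n_beads_for(length_bp) if length_bp is not None else int(n_beads)
    if circular and n < 8:
        raise ValueError(
            f"a closed chain with bending and torsion terms needs >= 8 beads, got {n}"
        )
    if not circular and n < 2:
        raise ValueError("a linear fibre needs at least 2 beads")
    if circular:
        radius = 0.5 / np.sin(np.pi / n)
        theta = 2.0 * np.pi * np.arange(n) / n
        pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
    else:
        pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    return Fiber(pos, circular, units)


# -- cohesin handcuff ------------------------------------------------------


@dataclass
class CohesinHandcuff:
    """Two tangent 15-bead cohesin rings sharing one bead (planar figure eight).

    Rigidity is realised as a stiff all-pairs harmonic distance-restraint
    network over the 29 beads rather than a rigid body, so a single
    overdamped integrator moves every bead; the shape contract (RMSD from the
    reference figure-eight < 0.2 sigma under thermal motion) is tested, not
    assumed. The shared bead plus the restraint network is what prevents the
    two rings from rotating with respect to each other.
    """

    positions: np.ndarray                 # (29, 3), sigma
    ring_a: np.ndarray                    # 15 indices into positions
    ring_b: np.ndarray                    # 15 indices into positions
    shared_index: int
    restraint_pairs: np.ndarray           # (P, 2) int
    restraint_rest: np.ndarray            # (P,) rest lengths, sigma
    units: UnitSystem = field(default_factory=UnitSystem)
    bead_radius: float = COHESIN_BEAD_RADIUS
    threaded_bead_a: int | None = None
    threaded_bead_b: int | None = None
    state: str = "active"                 # active | anchored | dissociated
    anchored_rings: set = field(default_factory=set)
    reference_positions: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def ring_positions(self, which: str) -> np.ndarray:
        idx = self.ring_a if which == "a" else self.ring_b
        return self.positions[idx]

    def ring_centre(self, which: str) -> np.ndarray:
        return self.ring_positions(which).mean(axis=0)

    def ring_normal(self, which: str) -> np.ndarray:
        """Unit normal of the best-fit plane of one ring (SVD)."""
        p = self.ring_positions(which)
        c = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[2]

    def ring_radius_fit(self, which: str) -> float:
        """Mean distance of ring-bead centres from the ring centroid, sigma."""
        p = self.ring_positions(which)
        return float(np.linalg.norm(p - p.mean(axis=0), axis=1).mean())

    def outer_diameter_nm(self, which: str = "a") -> float:
        """External ring diameter: bead-centre circle plus one bead diameter."""
        d_centre = 2.0 * self.ring_radius_fit(which)
        return self.units.to_nm(d_centre + 2.0 * self.bead_radius)

    def inner_aperture_nm(self, which: str = "a") -> float:
        """Inner aperture: bead-centre circle minus one bead diameter."""
        d_centre = 2.0 * self.ring_radius_fit(which)
        return self.units.to_nm(d_centre - 2.0 * self.bead_radius)

    def aperture_radius_sigma(self) -> float:
        """Half the inner aperture, in sigma (threading acceptance radius)."""
        return 0.5 * (2.0 * self.ring_radius_fit("a") - 2.0 * self.bead_radius)

    def shape_rmsd(self) -> float:
        """RMSD from the reference figure-eight after optimal superposition."""
        if self.reference_positions is None:
            return 0.0
        x = self.positions - self.positions.mean(axis=0)
        y = self.reference_positions - self.reference_positions.mean(axis=0)
        h = x.T @ y
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        r = u @ np.diag([1.0, 1.0, d]) @ vt
        return float(np.sqrt(np.mean(np.sum((x @ r - y) ** 2, axis=1))))


def build_handcuff(
    centre: np.ndarray | None = None,
    normal: np.ndarray | None = None,
    units: UnitSystem | None = None,
    ring_centre_diameter: float = RING_CENTRE_DIAMETER,
    axis: np.ndarray | None = None,
) -> CohesinHandcuff:
    """Build the planar figure-eight: two tangent 15-bead rings, one shared bead.

    ``normal`` is the common plane normal (the local fibre tangent direction
    once threaded); ``axis`` is the in-plane direction from ring A's centre to
    ring B's centre. 29 distinct beads in total.
    """
    units = units or UnitSystem()
    centre = np.zeros(3) if centre is None else np.asarray(centre, dtype=float)
    normal = np.array([0.0, 0.0, 1.0]) if normal is None else np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if axis is None:
        axis = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(axis, normal)) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis - np.dot(axis, normal) * normal
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(normal, axis)

    rho = 0.5 * ring_centre_diameter
    m = BEADS_PER_RING
    centre_a = centre - rho * axis
    centre_b = centre + rho * axis

    # ring A: bead 0 at +axis from its centre (= the shared bead at `centre`)
    ang = 2.0 * np.pi * np.arange(m) / m
    ring_a_pts = centre_a + rho * (np.outer(np.cos(ang), axis) + np.outer(np.sin(ang), perp))
    # ring B: bead 0 at -axis from its centre (= the same shared bead)
    ring_b_pts = centre_b + rho * (np.outer(np.cos(ang), -axis) + np.outer(np.sin(ang), perp))

    positions = np.vstack([ring_a_pts, ring_b_pts[1:]])  # drop duplicate shared bead
    ring_a = np.arange(m)
    ring_b = np.concatenate([[0], np.arange(m, 2 * m - 1)])
    shared_index = 0

    iu, ju = np.triu_indices(len(positions), k=1)
    pairs = np.column_stack([iu, ju])
    rest = np.linalg.norm(positions[iu] - positions[ju], axis=1)

    hc = CohesinHandcuff(
        positions=positions,
        ring_a=ring_a,
        ring_b=ring_b,
        shared_index=shared_index,
        restraint_pairs=pairs,
        restraint_rest=rest,
        units=units,
    )
    hc.reference_positions = positions.copy()
    return hc


def thread_handcuff(
    fiber: Fiber,
    handcuff: CohesinHandcuff,
    bead_a: int,
    bead_b: int,
    min_separation: int = 4,
    placement_tolerance: float = 0.75,
) -> CohesinHandcuff:
    """Place the handcuff so ring A encircles fibre bead_a and ring B bead_b.

    The fibre must already present the two beads roughly one ring-spacing
    apart in space with tangents perpendicular to the common ring plane (the
    scenario builders construct such conformations). Each ring is centred on
    its fibre bead with the ring plane perpendicular to the local tangent.
    """
    n = fiber.n_beads
    if bead_a == bead_b:
        raise ValueError("threading beads must differ")
    for b in (bead_a, bead_b):
        if not 0 <= b < n:
            raise IndexError(f"threading bead {b} out of range")
    sep = fiber.contour_distance(bead_a, bead_b)
    if sep < min_separation:
        raise ValueError(
            f"threading beads {bead_a}/{bead_b} are {sep} bonds apart; "
            f"minimum separation is {min_separation}"
        )
    ra, rb = fiber.positions[bead_a], fiber.positions[bead_b]
    gap = np.linalg.norm(rb - ra)
    rho2 = 2.0 * 0.5 * RING_CENTRE_DIAMETER
    if abs(gap - rho2) > placement_tolerance:
        raise ValueError(
            f"fibre beads {bead_a}/{bead_b} are {gap:.2f} sigma apart in space; "
            f"threading needs ~{rho2:.2f} sigma (fibre not prepared for threading)"
        )
    t = fiber.tangents()
    ta = t[bead_a % fiber.n_segments]
    axis = (rb - ra) / gap
    normal = ta - np.dot(ta, axis) * axis
    nn = np.linalg.norm(normal)
    if nn < 1e-8:
        raise ValueError("fibre tangent is parallel to the threading axis")
    normal /= nn
    centre = 0.5 * (ra + rb)

    placed = build_handcuff(centre=centre, normal=normal, units=handcuff.units, axis=axis)
    for site in fiber.ctcf_sites:
        obst = fiber.positions[site.fibre_bead] if site.position is None else site.position
        for which in ("a", "b"):
            d = np.linalg.norm(placed.ring_centre(which) - obst)
            if d < placed.ring_radius_fit(which) + site.radius:
                raise ValueError(
                    f"ring {which} would overlap the CTCF obstacle at bead {site.fibre_bead}"
                )
    placed.threaded_bead_a = bead_a
    placed.threaded_bead_b = bead_b
    return placed


# -- fibre annotations -----------------------------------------------------


def add_active_swivel(
    fiber: Fiber,
    joint: int,
    rate_omega: float = 0.05,
    sign: int = -1,
    barrier: bool = False,
) -> Fiber:
    """Attach a torsional motor at ``joint`` (bead index of the joint)."""
    fiber.joint_index(joint)  # validates
    if joint in fiber.passive_swivels:
        raise ValueError(f"joint {joint} is already a passive swivel")
    if any(sw.joint == joint for sw in fiber.active_swivels):
        raise ValueError(f"joint {joint} already has an active swivel")
    fiber.active_swivels.append(
        ActiveSwivel(joint=joint, rate_omega=rate_omega, sign=sign, barrier=barrier)
    )
    return fiber


def add_passive_swivel(fiber: Fiber, joint: int) -> Fiber:
    """Zero the torsional stiffness at ``joint`` (topoisomerase relaxation site)."""
    fiber.joint_index(joint)
    if any(sw.joint == joint for sw in fiber.active_swivels):
        raise ValueError(f"joint {joint} already has an active swivel")
    if joint in fiber.passive_swivels:
        raise ValueError(f"joint {joint} is already a passive swivel")
    fiber.passive_swivels.add(joint)
    return fiber


def add_phantom_region(fiber: Fiber, start: int, stop: int) -> Fiber:
    """Disable fibre-fibre excluded volume for beads in [start, stop)."""
    region = PhantomRegion(start, stop)
    for b in region.beads():
        if not 0 <= b < fiber.n_beads:
            raise IndexError(f"phantom bead {b} out of range")
    fiber.phantom_beads[list(region.beads())] = True
    return fiber


def add_ctcf(
    fiber: Fiber,
    fibre_bead: int,
    orientation: str = "convergent",
    obstacle_diameter: float = 3.5,
) -> Fiber:
    """Attach a bulky CTCF obstacle bead at ``fibre_bead``."""
    if not 0 <= fibre_bead < fiber.n_beads:
        raise IndexError(f"CTCF bead {fibre_bead} out of range")
    if any(s.fibre_bead == fibre_bead for s in fiber.ctcf_sites):
        raise ValueError(f"bead {fibre_bead} already carries a CTCF site")
    aperture = RING_CENTRE_DIAMETER - 2.0 * COHESIN_BEAD_RADIUS
    if obstacle_diameter <= aperture:
        raise ValueError(
            f"CTCF obstacle diameter {obstacle_diameter} sigma does not exceed the "
            f"ring aperture ({aperture} sigma); blocking is geometric"
        )
    site = CTCFSite(
        fibre_bead=fibre_bead,
        orientation=orientation,
        obstacle_diameter=obstacle_diameter,
        position=fiber.positions[fibre_bead].copy(),
    )
    fiber.ctcf_sites.append(site)
    return fiber
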