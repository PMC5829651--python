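"""Potential-energy terms and their forces/torques.

Terms: FENE bonds centred at the 1-sigma bond length, harmonic bending with a
persistence length of 50 nm, joint twist elasticity with passive-swivel
exceptions, purely repulsive (WCA) excluded volume with phantom masking and
mixed radii, the stiff handcuff restraint network, CTCF attachment bonds and
anchoring bonds created by the CTCF event rule.

Torsional stress couples to bead positions through the gradient of the
parallel-transport holonomy (the discrete curvature binormal), which is what
lets injected twist buckle the fibre into plectonemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .geometry import curvature_binormals
from .units import UnitSystem

__all__ = [
    "ForceFieldParams",
    "Forcefield",
    "bond_energy",
    "bond_force",
    "wca_energy",
    "wca_force",
    "k_bend_for_persistence_length",
]


@lru_cache(maxsize=32)
def k_bend_for_persistence_length(lp_sigma: float, l0: float = 1.0) -> float:
    """Harmonic bending stiffness (kT) giving a fitted persistence length
    ``lp_sigma`` on the discrete chain.

    The tangent correlation of a discrete chain decays as <cos(theta)>^s, so
    the stiffness is found by solving <cos(theta)>_k = exp(-l0/Lp) with the
    Boltzmann average over exp(-k theta^2 / 2) sin(theta). The naive
    continuum ratio k = Lp/l0 underestimates the fitted Lp by roughly half a
    bond length.
    """
    target = np.exp(-l0 / lp_sigma)

    def mean_cos(k: float) -> float:
        num = quad(lambda t: np.cos(t) * np.exp(-0.5 * k * t * t) * np.sin(t), 0, np.pi)[0]
        den = quad(lambda t: np.exp(-0.5 * k * t * t) * np.sin(t), 0, np.pi)[0]
        return num / den

    return float(brentq(lambda k: mean_cos(k) - target, 0.1, 100.0 * lp_sigma / l0, xtol=1e-10))


@dataclass
class ForceFieldParams:
    """All elastic and excluded-volume constants, in reduced units.

    Lengths in sigma, energies in kT. ``lp_nm`` / ``lt_nm`` are the bending
    and torsional persistence lengths; the derived stiffnesses are
    ``k_bend`` (calibrated so the fitted Lp of the discrete chain matches
    ``lp_nm``) and the torsional modulus ``C = kT * Lt``.
    """

    l0: float = 1.0                  # equilibrium bond length, sigma
    k_fene: float = 100.0            # FENE stiffness, kT/sigma^2
    r_fene_max: float = 1.5          # maximum bond extension, sigma
    lp_nm: float = 50.0              # bending persistence length, nm
    lt_nm: float = 75.0              # torsional persistence length, nm
    eps_wca: float = 1.0             # excluded-volume energy scale, kT
    k_restraint: float = 300.0       # handcuff shape-restraint stiffness, kT/sigma^2
    k_attach: float = 50.0           # CTCF-to-fibre attachment, kT/sigma^2
    k_anchor: float = 50.0           # ring-to-CTCF anchor bonds, kT/sigma^2
    units: UnitSystem = field(default_factory=UnitSystem)

    def __post_init__(self) -> None:
        if self.r_fene_max <= self.l0:
            raise ValueError("r_fene_max must exceed l0")
        for name in ("k_fene", "lp_nm", "lt_nm", "eps_wca", "k_restraint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def lp_sigma(self) -> float:
        return self.units.to_sigma(self.lp_nm)

    @property
    def lt_sigma(self) -> float:
        return self.units.to_sigma(self.lt_nm)

    @property
    def k_bend(self) -> float:
        """Bending stiffness in kT (discretisation-corrected)."""
        return k_bend_for_persistence_length(self.lp_sigma, self.l0) * self.units.kT

    @property
    def twist_modulus(self) -> float:
        """Torsional modulus C in kT * sigma; joint energy is C/(2 l0) phi^2."""
        return self.units.kT * self.lt_sigma


# -- closed-form pair terms (also the unit-test oracles' target) -----------


def bond_energy(r: float | np.ndarray, params: ForceFieldParams) -> float | np.ndarray:
    """FENE energy of a bond of length r, minimum at l0, diverging at r_fene_max."""
    delta = params.r_fene_max - params.l0
    x = (np.asarray(r, dtype=float) - params.l0) / delta
    with np.errstate(divide="ignore", invalid="ignore"):
        e = -0.5 * params.k_fene * delta**2 * np.log(1.0 - x * x)
    e = np.where(np.abs(x) >= 1.0, np.inf, e)
    return e if np.ndim(r) else float(e)


def bond_force(r: float | np.ndarray, params: ForceFieldParams) -> float | np.ndarray:
    """Scalar bond force -dE/dr (negative = pulls back toward l0 when r > l0)."""
    delta = params.r_fene_max - params.l0
    x = (np.asarray(r, dtype=float) - params.l0) / delta
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -params.k_fene * (np.asarray(r) - params.l0) / (1.0 - x * x)
        f = np.where(np.abs(x) >= 1.0, -np.sign(x) * np.inf, f)
    return f if np.ndim(r) else float(f)


def wca_energy(r, contact: float, eps: float = 1.0):
    """Purely repulsive WCA energy; zero at and beyond the contact distance."""
    s = contact / 2.0 ** (1.0 / 6.0)
    r = np.asarray(r, dtype=float)
    sr6 = (s / r) ** 6
    e = np.where(r < contact, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    return e if e.ndim else float(e)


def wca_force(r, contact: float, eps: float = 1.0):
    """Scalar repulsive force magnitude -dE/dr (>= 0); zero beyond contact."""
    s = contact / 2.0 ** (1.0 / 6.0)
    r = np.asarray(r, dtype=float)
    sr6 = (s / r) ** 6
    f = np.where(r < contact, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    return f if f.ndim else float(f)


class Forcefield:
    """Evaluates all forces, torsional torques and energies for one system.

    Built once per run from a :class:`~twistloop.dynamics.SimulationState`;
    static structure (bonds, restraint pairs, exclusion rules, per-pair
    contact distances) is precomputed, and rebuilt if the interaction
    topology changes (handcuff dissociation).
    """

    def __init__(self, state, params: ForceFieldParams):
        self.params = params
        self._version = -1
        self.n_overextended = 0
        self._nl_age = 0
        self._nl_rebuild_every = 8
        self._nl = (np.zeros(0, dtype=int), np.zeros(0, dtype=int))
        self._build(state)

    # -- static structure ---------------------------------------------------

    def _build(self, state) -> None:
        fib = state.fiber
        n = fib.n_beads
        nf = state.n_fiber
        p = self.params

        self.circular = fib.circular
        # FENE bonds on the fibre
        i = np.arange(fib.n_segments)
        self.bond_i = i
        self.bond_j = (i + 1) % n if fib.circular else i + 1

        # bending / twist joints: stencil beads (prev, this, next)
        jb = fib.joint_beads()
        self.joint_prev = (jb - 1) % n
        self.joint_this = jb
        self.joint_next = (jb + 1) % n
        self.seg_in = (jb - 1) % n if fib.circular else jb - 1   # segment entering the joint
        self.seg_out = jb % n if fib.circular else jb            # segment leaving the joint
        self.k_bend_arr = np.full(fib.n_joints, p.k_bend)
        c_over_l0 = p.twist_modulus / p.l0
        self.k_twist_arr = np.where(fib.passive_joint_mask(), 0.0, c_over_l0)

        # harmonic restraint pairs: CTCF attachments (handcuff rigidity is a
        # body-frame shape restraint, evaluated separately)
        ri, rj, rr, rk = [], [], [], []
        for k, site in enumerate(fib.ctcf_sites):
            ri.append(np.array([state.ctcf_offset + k]))
            rj.append(np.array([site.fibre_bead]))
            rr.append(np.array([0.0]))
            rk.append(np.array([p.k_attach]))
        if ri:
            self.res_i = np.concatenate(ri)
            self.res_j = np.concatenate(rj)
            self.res_r0 = np.concatenate(rr)
            self.res_k = np.concatenate(rk)
        else:
            self.res_i = np.zeros(0, dtype=int)
            self.res_j = np.zeros(0, dtype=int)
            self.res_r0 = np.zeros(0)
            self.res_k = np.zeros(0)

        # excluded volume bookkeeping
        N = state.n_total
        self.active_beads = ~state.frozen
        radii = state.radii
        self.contact = radii[:, None] + radii[None, :]
        self.max_cut = float(self.contact[self.active_beads][:, self.active_beads].max()) \
            if self.active_beads.any() else 0.0

        allow = np.ones((N, N), dtype=bool)
        np.fill_diagonal(allow, False)
        allow[self.bond_i, self.bond_j] = False
        allow[self.bond_j, self.bond_i] = False
        # fibre-fibre pairs with a phantom member exert no excluded volume
        ph = np.zeros(N, dtype=bool)
        ph[:nf] = fib.phantom_beads
        ff = np.zeros(N, dtype=bool)
        ff[:nf] = True
        phantom_pair = (ph[:, None] | ph[None, :]) & ff[:, None] & ff[None, :]
        allow &= ~phantom_pair
        # intra-handcuff pairs: shape is held by the restraint network
        for h, off in zip(state.handcuffs, state.handcuff_offsets):
            sl = slice(off, off + h.n_beads)
            allow[sl, sl] = False
            if h.state == "dissociated":
                allow[sl, :] = False
                allow[:, sl] = False
        # CTCF obstacles sit concentric with their attachment bead: mask the
        # immediate fibre neighbourhood so the obstacle does not blast the
        # backbone apart (it still blocks cohesin rings).
        for k, site in enumerate(fib.ctcf_sites):
            gi = state.ctcf_offset + k
            for d in range(-2, 3):
                b = (site.fibre_bead + d) % n if fib.circular else site.fibre_bead + d
                if 0 <= b < nf:
                    allow[gi, b] = False
                    allow[b, gi] = False
        allow[state.frozen, :] = False
        allow[:, state.frozen] = False
        self.allow = allow
        self._nl_age = 0  # interaction topology changed: rebuild neighbours
        self._version = state.topology_version

    def sync(self, state) -> None:
        if state.topology_version != self._version:
            self._build(state)

    # -- per-term evaluations ------------------------------------------------

    def _fene(self, X, F, e, r):
        p = self.params
        delta = p.r_fene_max - p.l0
        x = (r - p.l0) / delta
        over = np.abs(x) >= 1.0
        if np.any(over):
            # a rare thermal kick past the extensibility limit is pulled back
            # by the (clipped) near-divergent force; only a gross excursion
            # signals a genuinely unstable timestep
            if np.any(np.abs(x) > 1.5):
                raise FloatingPointError(
                    "FENE bond far outside extensibility limit "
                    "(integration blow-up: reduce dt)"
                )
            self.n_overextended += int(np.count_nonzero(over))
        xc = np.clip(x, -0.98, 0.98)
        fmag = -p.k_fene * (xc * delta) / (1.0 - xc * xc)  # -dE/dr, clipped
        fv = (fmag / r)[:, None] * e
        ns = len(fv)
        if self.circular:
            F[:ns] -= fv
            F[:ns] += np.roll(fv, 1, axis=0)
        else:
            F[:ns] -= fv
            F[1:ns + 1] += fv
        return -0.5 * p.k_fene * delta**2 * float(np.sum(np.log(1.0 - xc * xc)))

    def _bend(self, X, F, le, t):
        # u, v: unit tangents entering/leaving each joint
        u = t[self.seg_in]
        v = t[self.seg_out]
        la = le[self.seg_in]
        lb = le[self.seg_out]
        c = np.clip(np.einsum("ij,ij->i", u, v), -1.0, 1.0)
        theta = np.arccos(c)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
        # d(theta)/d(cos theta) = -1/sin(theta); keep theta/sin stable near 0
        coef = self.k_bend_arr * np.where(theta > 1e-6, theta / s, 1.0)
        f_prev = coef[:, None] * (-(v - c[:, None] * u) / la[:, None])
        f_next = coef[:, None] * ((u - c[:, None] * v) / lb[:, None])
        self._scatter_joints(F, f_prev, f_next)
        return 0.5 * float(np.sum(self.k_bend_arr * theta * theta))

    def _twist(self, X, F, fiber, le, t):
        """Positional forces from torsional stress via the holonomy gradient."""
        dev = fiber.joint_twist - fiber.joint_twist0
        g = self.k_twist_arr * dev  # dE/dphi
        energy = 0.5 * float(np.sum(g * dev))
        if not np.any(g):
            return energy
        kb = curvature_binormals(t, fiber.circular)
        # dphi/dx_prev = -kb/(2 l_in); dphi/dx_next = kb/(2 l_out); middle = -(sum);
        # force = -g * dphi/dx
        gp = (g / (2.0 * le[self.seg_in]))[:, None] * kb
        gn = -(g / (2.0 * le[self.seg_out]))[:, None] * kb
        self._scatter_joints(F, gp, gn)
        return energy


    def _scatter_joints(self, F, f_prev, f_next):
        """Accumulate a (prev, this, next) joint-stencil force without scatter
        ops: joint arrays are index shifts on the chain."""
        mid = -(f_prev + f_next)
        if self.circular:
            n = len(f_prev)
            F[:n] += np.roll(f_prev, -1, axis=0)
            F[:n] += mid
            F[:n] += np.roll(f_next, 1, axis=0)
        else:
            nj = len(f_prev)
            F[0:nj] += f_prev
            F[1:nj + 1] += mid
            F[2:nj + 2] += f_next

    def twist_torques(self, fiber) -> np.ndarray:
        """Generalised torque on each segment's frame angle (twist transport).

        Rotating segment s about its tangent by +delta raises the twist of
        the joint it leaves from (s = outgoing segment) and lowers the twist
        of the joint it arrives at (s = incoming segment), so the torque
        -dE/dpsi_s is the difference of the two adjacent joint tensions.
        """
        g = self.k_twist_arr * (fiber.joint_twist - fiber.joint_twist0)  # dE/dphi
        tau = np.zeros(fiber.n_segments)
        np.add.at(tau, self.seg_in, g)
        np.subtract.at(tau, self.seg_out, g)
        return tau

    def _wca(self, X, F):
        # neighbour list with a 1-sigma skin, rebuilt every few evaluations
        # (bead motion per step is capped well below the skin)
        if self._nl_age % self._nl_rebuild_every == 0:
            act = np.flatnonzero(self.active_beads)
            tree = cKDTree(X[act])
            pairs = tree.query_pairs(self.max_cut + 1.0, output_type="ndarray")
            if len(pairs):
                gi = act[pairs[:, 0]]
                gj = act[pairs[:, 1]]
                ok = self.allow[gi, gj]
                self._nl = (gi[ok], gj[ok])
            else:
                self._nl = (np.zeros(0, dtype=int), np.zeros(0, dtype=int))
        self._nl_age += 1
        gi, gj = self._nl
        if len(gi) == 0:
            return 0.0
        d = X[gj] - X[gi]
        r = np.linalg.norm(d, axis=1)
        contact = self.contact[gi, gj]
        inside = r < contact
        if not np.any(inside):
            return 0.0
        gi, gj, d, r, contact = gi[inside], gj[inside], d[inside], r[inside], contact[inside]
        eps = self.params.eps_wca
        s6 = (contact / (2.0 ** (1.0 / 6.0) * r)) ** 6
        fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
        fv = (fmag / r)[:, None] * d
        np.add.at(F, gj, fv)
        np.add.at(F, gi, -fv)
        return float(np.sum(4.0 * eps * (s6 * s6 - s6) + eps))

    def _shape_restraints(self, X, F, state):
        """Handcuff rigidity: springs to the Kabsch-fitted reference shape.

        Fitting the reference (translation + rotation) to the current beads
        before applying the springs gives first-order stiffness to every
        internal mode -- including the out-of-plane bending of the planar
        figure-eight, which pure distance restraints resist only at second
        order. At the optimal fit the naive spring force is the exact energy
        gradient (envelope theorem) and the restraint field carries zero net
        force and torque.
        """
        e = 0.0
        k = self.params.k_restraint
        for h, off in zip(state.handcuffs, state.handcuff_offsets):
            if h.state == "dissociated" or h.reference_positions is None:
                continue
            x = X[off:off + h.n_beads]
            xc = x.mean(axis=0)
            y = h.reference_positions - h.reference_positions.mean(axis=0)
            hmat = y.T @ (x - xc)
            u, _, vt = np.linalg.svd(hmat)
            d = np.sign(np.linalg.det(u @ vt))
            rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
            fitted = xc + y @ rot.T
            dev = x - fitted
            F[off:off + h.n_beads] -= k * dev
            e += 0.5 * k * float(np.sum(dev * dev))
        return e

    def _restraints(self, X, F, state):
        e = 0.0
        if len(self.res_i):
            d = X[self.res_j] - X[self.res_i]
            r = np.linalg.norm(d, axis=1)
            r_safe = np.maximum(r, 1e-12)
            fmag = -self.res_k * (r - self.res_r0)
            fv = (fmag / r_safe)[:, None] * d
            np.add.at(F, self.res_j, fv)
            np.add.at(F, self.res_i, -fv)
            e += 0.5 * float(np.sum(self.res_k * (r - self.res_r0) ** 2))
        for (gi, gj, r0, k) in state.anchor_bonds:
            d = X[gj] - X[gi]
            r = max(float(np.linalg.norm(d)), 1e-12)
            fv = -k * (r - r0) / r * d
            F[gj] += fv
            F[gi] -= fv
            e += 0.5 * k * (r - r0) ** 2
        return e

    # -- public API ----------------------------------------------------------

    def forces(self, state) -> tuple[np.ndarray, np.ndarray, dict]:
        """Forces on all beads, torsional torques on fibre segments, energies."""
        self.sync(state)
        X = state.X
        fib = state.fiber
        F = np.zeros_like(X)
        ns = fib.n_segments
        e = (np.roll(X[:len(fib.positions)], -1, axis=0) - X[:len(fib.positions)]) \
            if fib.circular else X[1:len(fib.positions)] - X[:len(fib.positions) - 1]
        le = np.sqrt(np.einsum("ij,ij->i", e, e))
        if not np.all(le > 0):
            raise ValueError("degenerate (zero-length) segment")
        t = e / le[:, None]
        en = {}
        en["fene"] = self._fene(X, F, e, le)
        en["bend"] = self._bend(X, F, le, t)
        en["twist"] = self._twist(X, F, fib, le, t)
        en["wca"] = self._wca(X, F)
        en["restraint"] = self._restraints(X, F, state) + self._shape_restraints(X, F, state)
        tau = self.twist_torques(fib)
        return F, tau, en

    def energy(self, state) -> dict:
        F, _, en = self.forces(state)
        en["total"] = sum(en.values())
        return en
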