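"""Topological and geometric observables.

Twist, writhe, linking-number bookkeeping, supercoiling localisation,
plectoneme geometry, loop extent, contact maps and persistence-length
fitting. Writhe is the discrete Gauss double integral evaluated exactly for
straight segment pairs (solid-angle form), so White's theorem Lk = Tw + Wr
holds to integration accuracy and supercoil injection can be audited turn
by turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "writhe",
    "writhe_pair_matrix",
    "segment_writhe_density",
    "enclosed_writhe",
    "twist",
    "free_twist",
    "lk_deficit",
    "loop_extent",
    "contact_map",
    "detect_plectonemes",
    "Plectoneme",
    "fit_persistence_length",
    "PersistenceFit",
    "frame_observables",
    "detect_passages",
    "min_nonbonded_distance",
]


# -- writhe -----------------------------------------------------------------


def _segments(positions: np.ndarray, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(positions, dtype=float)
    if len(p) < 4:
        raise ValueError("writhe needs at least 4 beads")
    a, b = (p, np.roll(p, -1, axis=0)) if circular else (p[:-1], p[1:])
    if not np.all(np.linalg.norm(b - a, axis=1) > 1e-12):
        raise ValueError("degenerate (zero-length) segment")
    return a, b


def _gauss_pair(p1, p2, p3, p4):
    """Exact Gauss-integral solid angle Omega for straight segment pairs.

    Vectorised over leading axes. Coplanar/degenerate pairs contribute 0.
    """
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(v):
        nv = np.linalg.norm(v, axis=-1, keepdims=True)
        return np.divide(v, nv, out=np.zeros_like(v), where=nv > 1e-12), nv[..., 0]

    u1, l1 = _unit(n1)
    u2, l2 = _unit(n2)
    u3, l3 = _unit(n3)
    u4, l4 = _unit(n4)
    good = (l1 > 1e-12) & (l2 > 1e-12) & (l3 > 1e-12) & (l4 > 1e-12)

    def _asin_dot(a, b):
        return np.arcsin(np.clip(np.einsum("...i,...i->...", a, b), -1.0, 1.0))

    omega = _asin_dot(u1, u2) + _asin_dot(u2, u3) + _asin_dot(u3, u4) + _asin_dot(u4, u1)
    sign = np.sign(np.einsum("...i,...i->...", np.cross(p4 - p3, p2 - p1), r13))
    return np.where(good, omega * sign, 0.0)


def writhe(positions: np.ndarray, circular: bool = True) -> float:
    """Writhe of the bead polygon (exact discrete Gauss double sum).

    For an open chain the same sum without closure is reported (the standard
    open-chain extension); closed curves are the primary use. Antisymmetric
    under mirror reflection.
    """
    a, b = _segments(positions, circular)
    n = len(a)
    iu, ju = np.triu_indices(n, k=2)
    if circular:  # first and last segments share a bead: skip that pair too
        keep = ~((iu == 0) & (ju == n - 1))
        iu, ju = iu[keep], ju[keep]
    omega = _gauss_pair(a[iu], b[iu], a[ju], b[ju])
    return float(np.sum(omega) / (2.0 * np.pi))


def writhe_pair_matrix(positions: np.ndarray, circular: bool = True) -> np.ndarray:
    """Per-segment-pair writhe contributions (symmetric matrix summing to 2 Wr)."""
    a, b = _segments(positions, circular)
    n = len(a)
    iu, ju = np.triu_indices(n, k=2)
    if circular:
        keep = ~((iu == 0) & (ju == n - 1))
        iu, ju = iu[keep], ju[keep]
    omega = _gauss_pair(a[iu], b[iu], a[ju], b[ju]) / (2.0 * np.pi)
    m = np.zeros((n, n))
    m[iu, ju] = omega
    m[ju, iu] = omega
    return m


def segment_writhe_density(positions: np.ndarray, circular: bool = True) -> np.ndarray:
    """Writhe density per segment (half of each pair to each member; sums to Wr)."""
    return 0.5 * writhe_pair_matrix(positions, circular).sum(axis=1)


def enclosed_writhe(positions: np.ndarray, beads: np.ndarray, circular: bool = True) -> float:
    """Writhe carried by one contour interval: pair sum restricted to segment
    pairs that both lie inside ``beads`` (an index array of fibre beads)."""
    m = writhe_pair_matrix(positions, circular)
    n = len(m)
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(beads) % n] = True
    return float(0.5 * m[np.ix_(mask, mask)].sum())


# -- twist ------------------------------------------------------------------


def twist(fiber) -> float:
    """Elastic material twist Tw in turns, summed over transmitting joints.

    Passive joints (and the free face of barrier motors) are excluded; their
    accumulated free angle is reported by :func:`free_twist`. Active-swivel
    joints contribute their elastic deviation from the motor's rest angle --
    the rest angle itself is the motor's rotation, not fibre twist, which is
    what makes the Tw + Wr ledger count injected rotations exactly.
    """
    passive = fiber.passive_joint_mask()
    dev = fiber.joint_twist - fiber.joint_twist0
    return float(np.sum(dev[~passive]) / (2.0 * np.pi))


def free_twist(fiber) -> float:
    """Accumulated angle at passive (zero-stiffness) joints, in turns."""
    passive = fiber.passive_joint_mask()
    return float(np.sum(fiber.joint_twist[passive]) / (2.0 * np.pi))


def lk_deficit(state) -> float:
    """White's-theorem ledger: Tw + Wr - Lk0 - sum(sign * injected_R), turns.

    Approximately zero on a closed fibre in the absence of phantom strand
    passages and passive-swivel dissipation; jumps of ~+-2 flag a passage.
    For open fibres the value is a diagnostic only (no closed-curve Lk).
    """
    fib = state.fiber
    tw = twist(fib)
    wr = writhe(fib.positions, circular=fib.circular)
    injected = sum(sw.sign * sw.injected_R for sw in fib.active_swivels)
    return tw + wr - state.lk0 - injected


def detect_passages(observables, threshold: float = 1.0) -> list[int]:
    """Frame indices where the Lk ledger jumps by more than ``threshold``
    between consecutive observations (phantom strand-passage events)."""
    d = np.asarray(observables["lk_deficit"], dtype=float)
    jumps = np.abs(np.diff(d))
    return [int(i) + 1 for i in np.flatnonzero(jumps > threshold)]


# -- loop extent and contacts ----------------------------------------------


def loop_extent(state, handcuff) -> int | None:
    """Contour distance (bonds) between the two threaded beads, measured
    through the fibre arc that contains the active swivel."""
    a, b = handcuff.threaded_bead_a, handcuff.threaded_bead_b
    if a is None or b is None:
        state.log_event("loop extent undefined: ring unthreaded")
        return None
    fib = state.fiber
    through = fib.active_swivels[0].joint if fib.active_swivels else None
    return fib.contour_distance(a, b, through_joint=through)


def contact_map(trajectory, cutoff: float = 5.0) -> np.ndarray:
    """Fraction of frames in which fibre bead pairs are within ``cutoff``.

    Symmetric with unit diagonal; values in [0, 1], monotone in cutoff.
    """
    if trajectory.n_frames < 1:
        raise ValueError("contact map needs at least one frame")
    n = trajectory.n_fiber
    acc = np.zeros((n, n))
    for f in range(trajectory.n_frames):
        p = trajectory.fiber_positions(f)
        acc += cdist(p, p) < cutoff
    return acc / trajectory.n_frames


def min_nonbonded_distance(positions: np.ndarray, circular: bool, search_radius: float = 3.0) -> float:
    """Minimum distance between fibre beads more than 2 apart along the
    contour (self-approach diagnostic), or inf if none within the search radius."""
    n = len(positions)
    pairs = cKDTree(positions).query_pairs(search_radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.inf
    i, j = pairs[:, 0], pairs[:, 1]
    sep = np.abs(i - j)
    if circular:
        sep = np.minimum(sep, n - sep)
    keep = sep > 2
    if not np.any(keep):
        return np.inf
    d = np.linalg.norm(positions[i[keep]] - positions[j[keep]], axis=1)
    return float(d.min())


# -- plectoneme detection ---------------------------------------------------


@dataclass
class Plectoneme:
    """One interwound superhelical branch, in bead coordinates."""

    start: int
    end: int
    apex: int
    n_rungs: int
    mean_crossing_sign: float

    @property
    def handedness(self) -> str:
        # negative local crossing sign <=> right-handed interwound plectoneme
        # (the geometry adopted under negative supercoiling)
        return "right" if self.mean_crossing_sign < 0 else "left"


def detect_plectonemes(
    positions: np.ndarray,
    circular: bool = True,
    cutoff: float = 2.5,
    min_stem: int = 3,
    min_contour_sep: int = 4,
    merge_tol: int = 4,
) -> list[Plectoneme]:
    """Find maximal nested ladders of fibre self-contacts.

    Contact rungs are bead pairs (i, j) closer than ``cutoff`` in space and
    at least ``min_contour_sep`` apart along the contour; rungs whose
    midpoints coincide (within ``merge_tol``) form one plectoneme stem. The
    apex is the midpoint of the innermost rung; stem chirality is the mean
    sign of the local crossing ((t_i x t_j) . r_ij).
    """
    p = np.asarray(positions, dtype=float)
    n = len(p)
    pairs = cKDTree(p).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return []
    i, j = pairs[:, 0], pairs[:, 1]
    sep = j - i
    if circular:
        wrap = sep > n - sep
        # canonical arc: midpoint on the shorter arc between i and j
        sep = np.where(wrap, n - sep, sep)
        mid = np.where(wrap, ((j + (n - (j - i)) / 2.0) % n), (i + j) / 2.0)
    else:
        mid = (i + j) / 2.0
    keep = sep >= min_contour_sep
    i, j, sep, mid = i[keep], j[keep], sep[keep], mid[keep]
    if len(i) == 0:
        return []

    # crossing sign from the Gauss kernel of the segment pair (robust for
    # the near-antiparallel strands of an interwound stem)
    a, b = _segments(p, circular)
    ns = len(a)
    ii = np.minimum(i, ns - 1)
    jj = np.minimum(j, ns - 1)
    signs = np.sign(_gauss_pair(a[ii], b[ii], a[jj], b[jj]))

    order = np.argsort(mid)
    clusters: list[list[int]] = []
    for idx in order:
        placed = False
        for cl in clusters:
            ref = mid[cl[-1]]
            d = abs(mid[idx] - ref)
            if circular:
                d = min(d, n - d)
            if d <= merge_tol:
                cl.append(idx)
                placed = True
                break
        if not placed:
            clusters.append([idx])

    out = []
    for cl in clusters:
        if len(cl) < min_stem:
            continue
        ci = np.array(cl)
        outer = ci[np.argmax(sep[ci])]
        inner = ci[np.argmin(sep[ci])]
        out.append(
            Plectoneme(
                start=int(i[outer]),
                end=int(j[outer]),
                apex=int(round(mid[inner])) % n,
                n_rungs=len(cl),
                mean_crossing_sign=float(signs[ci].mean()),
            )
        )
    out.sort(key=lambda pl: pl.start)
    return out


# -- persistence-length fitting ---------------------------------------------


@dataclass
class PersistenceFit:
    """Tangent-correlation persistence length with a bootstrap CI."""

    lp_nm: float
    ci_nm: tuple[float, float]
    n_frames: int
    diverged: bool = False


def fit_persistence_length(
    frames: list[np.ndarray],
    units=None,
    s_max: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
    min_frames: int = 10,
) -> PersistenceFit:
    """Fit exp(-s l0 / Lp) to the tangent autocorrelation of a linear fibre.

    ``frames`` is a list of (n, 3) bead-position snapshots from an
    equilibrated trajectory. Returns Lp in nm with a bootstrap confidence
    interval over frames. A frozen straight rod has correlation 1 at all
    separations and is flagged as diverged.
    """
    from .units import UnitSystem

    units = units or UnitSystem()
    if len(frames) < min_frames:
        raise ValueError(
            f"persistence-length fit needs >= {min_frames} frames, got {len(frames)}"
        )
    n = len(frames[0])
    if s_max is None:
        s_max = min(12, n - 2)

    def corr_per_frame(p):
        t = p[1:] - p[:-1]
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        return np.array([
            np.mean(np.einsum("ij,ij->i", t[:-s], t[s:])) for s in range(1, s_max + 1)
        ])

    per_frame = np.array([corr_per_frame(np.asarray(p)) for p in frames])

    def lp_of(c):
        if np.any(c <= 0):
            return np.inf
        s = np.arange(1, s_max + 1)
        # weight by c: log-transformed noise grows as 1/c at small correlations
        slope = -np.polyfit(s, np.log(c), 1, w=c)[0]
        if slope <= 1e-9:
            return np.inf
        return units.to_nm(1.0 / slope)

    lp = lp_of(per_frame.mean(axis=0))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(frames), len(frames))
        boots.append(lp_of(per_frame[pick].mean(axis=0)))
    boots = np.array(boots)
    finite = boots[np.isfinite(boots)]
    if not np.isfinite(lp) or len(finite) < n_boot // 2:
        return PersistenceFit(lp_nm=float("inf"), ci_nm=(float("inf"), float("inf")),
                              n_frames=len(frames), diverged=True)
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return PersistenceFit(lp_nm=float(lp), ci_nm=(float(lo), float(hi)), n_frames=len(frames))


# -- per-frame observable row ----------------------------------------------


def frame_observables(state) -> dict:
    """One observables row: Tw, Wr, Lk ledger, threading, loop extent, contacts."""
    fib = state.fiber
    tw = twist(fib)
    wr = writhe(fib.positions, circular=fib.circular)
    injected = sum(sw.sign * sw.injected_R for sw in fib.active_swivels)
    row = {
        "time": state.time,
        "Tw": tw,
        "Wr": wr,
        "lk_deficit": tw + wr - state.lk0 - injected,
        "free_twist": free_twist(fib),
        "injected_R": sum(sw.injected_R for sw in fib.active_swivels),
        "min_nb_dist": min_nonbonded_distance(fib.positions, fib.circular),
    }
    for hi, h in enumerate(state.handcuffs):
        row[f"thread_a_{hi}"] = h.threaded_bead_a if h.threaded_bead_a is not None else -1
        row[f"thread_b_{hi}"] = h.threaded_bead_b if h.threaded_bead_b is not None else -1
        ext = loop_extent(state, h) if h.state != "dissociated" else None
        row[f"loop_extent_{hi}"] = ext if ext is not None else -1
        row[f"state_{hi}"] = h.state
    return row
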