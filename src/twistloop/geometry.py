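"""Discrete framed-curve geometry: tangents, parallel transport, twist angles.

The fibre is a twistable worm-like chain: every bond (segment) carries a
material frame vector m perpendicular to its tangent. The twist angle at a
joint between two consecutive segments is the rotation from the
parallel-transported frame of the incoming segment to the frame of the
outgoing segment, measured about the outgoing tangent. Tracking frames by
parallel transport makes Lk = Tw + Wr bookkeeping exact up to integration
error, which the conservation tests bound.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fast_cross",
    "segment_vectors",
    "unit_tangents",
    "parallel_transport",
    "initial_frames",
    "wrapped_joint_angles",
    "unwrap_angles",
    "curvature_binormals",
]


def fast_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (n, 3) arrays without np.cross overhead."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def segment_vectors(positions: np.ndarray, circular: bool) -> np.ndarray:
    """Bond vectors r[i+1] - r[i]; the last one wraps for circular chains."""
    if circular:
        return np.roll(positions, -1, axis=0) - positions
    return positions[1:] - positions[:-1]


def unit_tangents(positions: np.ndarray, circular: bool) -> np.ndarray:
    e = segment_vectors(positions, circular)
    ln = np.sqrt(np.einsum("ij,ij->i", e, e))
    if not np.all(ln > 0):
        raise ValueError("degenerate (zero-length) segment")
    return e / ln[:, None]


def parallel_transport(v: np.ndarray, t_old: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by the minimal rotation taking ``t_old`` to ``t_new``.

    All arguments are (n, 3) arrays of unit vectors; the rotation is applied
    row-wise (Rodrigues formula). Antiparallel tangent flips (c ~ -1) cannot
    occur on an intact chain at the bending stiffnesses used here; for safety
    they fall back to the identity.
    """
    axis = fast_cross(t_old, t_new)
    s2 = np.einsum("ij,ij->i", axis, axis)
    c = np.einsum("ij,ij->i", t_old, t_new)
    out = v.copy()
    ok = s2 > 1e-24
    if np.any(ok):
        k = axis[ok] / np.sqrt(s2[ok])[:, None]
        ck = c[ok][:, None]
        sk = np.sqrt(s2[ok])[:, None]
        vk = v[ok]
        kdotv = np.einsum("ij,ij->i", k, vk)[:, None]
        out[ok] = vk * ck + fast_cross(k, vk) * sk + k * kdotv * (1.0 - ck)
    return out


def initial_frames(positions: np.ndarray, circular: bool) -> np.ndarray:
    """Material frames with zero twist at every joint (Bishop frame).

    The first frame is an arbitrary unit vector perpendicular to the first
    tangent; the rest are obtained by parallel transport along the chain.
    """
    t = unit_tangents(positions, circular)
    n_seg = len(t)
    m = np.empty_like(t)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    m0 = ref - np.dot(ref, t[0]) * t[0]
    m[0] = m0 / np.linalg.norm(m0)
    for i in range(1, n_seg):
        m[i] = parallel_transport(m[i - 1][None, :], t[i - 1][None, :], t[i][None, :])[0]
        # re-orthonormalize against drift
        m[i] -= np.dot(m[i], t[i]) * t[i]
        m[i] /= np.linalg.norm(m[i])
    return m


def wrapped_joint_angles(m: np.ndarray, t: np.ndarray, circular: bool) -> np.ndarray:
    """Twist angle in (-pi, pi] at every joint between consecutive segments.

    For circular chains there are n_seg joints (joint j couples segments
    j-1 mod n and j); for linear chains there are n_seg - 1 interior joints
    (joint k couples segments k and k+1, sitting at bead k+1).
    """
    if circular:
        m_in, t_in = np.roll(m, 1, axis=0), np.roll(t, 1, axis=0)
        m_out, t_out = m, t
    else:
        m_in, t_in = m[:-1], t[:-1]
        m_out, t_out = m[1:], t[1:]
    mp = parallel_transport(m_in, t_in, t_out)
    x = np.einsum("ij,ij->i", mp, m_out)
    y = np.einsum("ij,ij->i", fast_cross(mp, m_out), t_out)
    return np.arctan2(y, x)


def unwrap_angles(wrapped: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """Lift wrapped angles to the branch nearest ``previous`` (continuity)."""
    return wrapped + 2.0 * np.pi * np.round((previous - wrapped) / (2.0 * np.pi))


def curvature_binormals(t: np.ndarray, circular: bool) -> np.ndarray:
    """Discrete curvature binormal (kappa b) at every joint.

    (kappa b)_j = 2 t_in x t_out / (1 + t_in . t_out); this is the kernel of
    the gradient of the parallel-transport holonomy with respect to bead
    positions, used to couple torsional stress to chain bending.
    """
    if circular:
        t_in = np.roll(t, 1, axis=0)
        t_out = t
    else:
        t_in, t_out = t[:-1], t[1:]
    denom = 1.0 + np.einsum("ij,ij->i", t_in, t_out)
    denom = np.maximum(denom, 1e-12)
    return 2.0 * fast_cross(t_in, t_out) / denom[:, None]
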