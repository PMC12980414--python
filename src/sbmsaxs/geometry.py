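"""Vectorized internal-coordinate measurements and their gradients.

Shared by the topology builder (native values r0, theta0, xi0, phi0 are
measured here) and by the potential (the same functions evaluate the
instantaneous internal coordinates, and the fused *_with_gradients
helpers implement the chain rule for the forces without recomputing
cross products).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product for (m, 3) arrays (faster than np.cross)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _row_norm(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def bond_lengths(coord: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Distances for index pairs ``idx`` of shape (m, 2)."""
    d = coord[idx[:, 1]] - coord[idx[:, 0]]
    return _row_norm(d)


def bond_angles(coord: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Angles (rad) at the middle atom for index triples (m, 3)."""
    u = coord[idx[:, 0]] - coord[idx[:, 1]]
    v = coord[idx[:, 2]] - coord[idx[:, 1]]
    sin = _row_norm(_cross(u, v))
    cos = np.einsum("ij,ij->i", u, v)
    return np.arctan2(sin, cos)


def dihedral_angles(coord: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed torsions (rad) for index quadruples (m, 4), in (-pi, pi]."""
    return dihedrals_with_gradients(coord, idx, want_gradients=False)[0]


def wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-pi, pi]."""
    return np.mod(np.asarray(delta) + np.pi, 2.0 * np.pi) - np.pi


# -- fused value + gradient helpers ------------------------------------

def bond_lengths_with_gradients(coord, idx):
    """(r, dr/dx_i, dr/dx_j) for index pairs."""
    d = coord[idx[:, 1]] - coord[idx[:, 0]]
    r = _row_norm(d)
    u = d / (r + _EPS)[:, None]
    return r, -u, u


def bond_angles_with_gradients(coord, idx):
    """(theta, dtheta/dx_i, dtheta/dx_j, dtheta/dx_k)."""
    u = coord[idx[:, 0]] - coord[idx[:, 1]]
    v = coord[idx[:, 2]] - coord[idx[:, 1]]
    nu = (_row_norm(u) + _EPS)[:, None]
    nv = (_row_norm(v) + _EPS)[:, None]
    uh = u / nu
    vh = v / nv
    cos = np.einsum("ij,ij->i", uh, vh)[:, None]
    sin = np.sqrt(np.clip(1.0 - cos * cos, _EPS, None))
    theta = np.arctan2(sin[:, 0], cos[:, 0])
    gi = (cos * uh - vh) / (nu * sin)
    gk = (cos * vh - uh) / (nv * sin)
    gj = -(gi + gk)
    return theta, gi, gj, gk


def dihedrals_with_gradients(coord, idx, want_gradients=True):
    """Torsion angles and (optionally) their Blondel–Karplus gradients.

    Returns ``(phi, (g1, g2, g3, g4))``; the gradient tuple is ``None``
    when ``want_gradients`` is false.
    """
    b1 = coord[idx[:, 1]] - coord[idx[:, 0]]
    b2 = coord[idx[:, 2]] - coord[idx[:, 1]]
    b3 = coord[idx[:, 3]] - coord[idx[:, 2]]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = (_row_norm(b2) + _EPS)[:, None]
    m1 = _cross(n1, b2 / nb2)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(-y, x)
    if not want_gradients:
        return phi, None
    n1sq = np.einsum("ij,ij->i", n1, n1)[:, None] + _EPS
    n2sq = np.einsum("ij,ij->i", n2, n2)[:, None] + _EPS
    g1 = -nb2 / n1sq * n1
    g4 = nb2 / n2sq * n2
    # projections of the *outward* end bonds (p1-p2, p4-p3) onto b2
    s = -np.einsum("ij,ij->i", b1, b2)[:, None] / (nb2 * nb2)
    t = -np.einsum("ij,ij->i", b3, b2)[:, None] / (nb2 * nb2)
    g2 = (s - 1.0) * g1 - t * g4
    g3 = (t - 1.0) * g4 - s * g1
    return phi, (g1, g2, g3, g4)


# backwards-compatible thin wrappers used by tests/oracles
def bond_length_gradients(coord, idx):
    _, gi, gj = bond_lengths_with_gradients(coord, idx)
    return gi, gj


def bond_angle_gradients(coord, idx):
    _, gi, gj, gk = bond_angles_with_gradients(coord, idx)
    return gi, gj, gk


def dihedral_gradients(coord, idx):
    return dihedrals_with_gradients(coord, idx)[1]
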