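"""Compiled force kernel for the structure-based potential.

The numpy implementation in :mod:`sbmsaxs.potential` is the reference;
this module provides a numerically identical scalar-loop kernel
(JIT-compiled with numba) that the integrator uses, since per-step
force evaluation dominates simulation cost.  Tests assert agreement
between the two paths.  When numba is unavailable the integrator
silently falls back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco


@njit(cache=True, fastmath=False)
def _forces_kernel(coord,
                   pairs, pair_kind, pair_ref,
                   eps_r, eps_contact, eps_nc, sigma_nc,
                   angles, theta0, eps_theta,
                   quads, quad_kind, quad_ref, quad_eps,
                   out):
    n = coord.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
        out[i, 2] = 0.0

    # pair terms: kind 0 harmonic bond, 1 native contact, 2 repulsion
    for m in range(pairs.shape[0]):
        i = pairs[m, 0]
        j = pairs[m, 1]
        dx = coord[j, 0] - coord[i, 0]
        dy = coord[j, 1] - coord[i, 1]
        dz = coord[j, 2] - coord[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if pair_kind[m] == 0:
            dvdr = 2.0 * eps_r * (r - pair_ref[m])
        elif pair_kind[m] == 1:
            x6 = (pair_ref[m] / r) ** 6
            dvdr = eps_contact * 12.0 * (x6 - x6 * x6) / r
        else:
            dvdr = -12.0 * eps_nc * (sigma_nc / r) ** 12 / r
        s = dvdr / r
        fx = s * dx
        fy = s * dy
        fz = s * dz
        out[i, 0] += fx
        out[i, 1] += fy
        out[i, 2] += fz
        out[j, 0] -= fx
        out[j, 1] -= fy
        out[j, 2] -= fz

    eps_g = 1e-12
    for m in range(angles.shape[0]):
        ia = angles[m, 0]
        ij = angles[m, 1]
        ik = angles[m, 2]
        ux = coord[ia, 0] - coord[ij, 0]
        uy = coord[ia, 1] - coord[ij, 1]
        uz = coord[ia, 2] - coord[ij, 2]
        vx = coord[ik, 0] - coord[ij, 0]
        vy = coord[ik, 1] - coord[ij, 1]
        vz = coord[ik, 2] - coord[ij, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz) + eps_g
        nv = np.sqrt(vx * vx + vy * vy + vz * vz) + eps_g
        ux /= nu; uy /= nu; uz /= nu
        vx /= nv; vy /= nv; vz /= nv
        cos = ux * vx + uy * vy + uz * vz
        s2 = 1.0 - cos * cos
        if s2 < eps_g:
            s2 = eps_g
        sin = np.sqrt(s2)
        th = np.arctan2(sin, cos)
        dv = 2.0 * eps_theta * (th - theta0[m])
        gix = (cos * ux - vx) / (nu * sin)
        giy = (cos * uy - vy) / (nu * sin)
        giz = (cos * uz - vz) / (nu * sin)
        gkx = (cos * vx - ux) / (nv * sin)
        gky = (cos * vy - uy) / (nv * sin)
        gkz = (cos * vz - uz) / (nv * sin)
        out[ia, 0] -= dv * gix
        out[ia, 1] -= dv * giy
        out[ia, 2] -= dv * giz
        out[ik, 0] -= dv * gkx
        out[ik, 1] -= dv * gky
        out[ik, 2] -= dv * gkz
        out[ij, 0] += dv * (gix + gkx)
        out[ij, 1] += dv * (giy + gky)
        out[ij, 2] += dv * (giz + gkz)

    # torsion terms: kind 0 planar quadratic, 1 periodic Fd restraint
    for m in range(quads.shape[0]):
        i1 = quads[m, 0]
        i2 = quads[m, 1]
        i3 = quads[m, 2]
        i4 = quads[m, 3]
        b1x = coord[i2, 0] - coord[i1, 0]
        b1y = coord[i2, 1] - coord[i1, 1]
        b1z = coord[i2, 2] - coord[i1, 2]
        b2x = coord[i3, 0] - coord[i2, 0]
        b2y = coord[i3, 1] - coord[i2, 1]
        b2z = coord[i3, 2] - coord[i2, 2]
        b3x = coord[i4, 0] - coord[i3, 0]
        b3y = coord[i4, 1] - coord[i3, 1]
        b3z = coord[i4, 2] - coord[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z) + eps_g
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        xdot = n1x * n2x + n1y * n2y + n1z * n2z
        ydot = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(-ydot, xdot)
        if quad_kind[m] == 0:
            dphi = np.mod(phi - quad_ref[m] + np.pi, 2.0 * np.pi) - np.pi
            dv = 2.0 * quad_eps[m] * dphi
        else:
            dphi = phi - quad_ref[m]
            dv = quad_eps[m] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z + eps_g
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z + eps_g
        g1x = -nb2 / n1sq * n1x
        g1y = -nb2 / n1sq * n1y
        g1z = -nb2 / n1sq * n1z
        g4x = nb2 / n2sq * n2x
        g4y = nb2 / n2sq * n2y
        g4z = nb2 / n2sq * n2z
        s = -(b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        t = -(b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = (s - 1.0) * g1x - t * g4x
        g2y = (s - 1.0) * g1y - t * g4y
        g2z = (s - 1.0) * g1z - t * g4z
        g3x = (t - 1.0) * g4x - s * g1x
        g3y = (t - 1.0) * g4y - s * g1y
        g3z = (t - 1.0) * g4z - s * g1z
        out[i1, 0] -= dv * g1x
        out[i1, 1] -= dv * g1y
        out[i1, 2] -= dv * g1z
        out[i2, 0] -= dv * g2x
        out[i2, 1] -= dv * g2y
        out[i2, 2] -= dv * g2z
        out[i3, 0] -= dv * g3x
        out[i3, 1] -= dv * g3y
        out[i3, 2] -= dv * g3z
        out[i4, 0] -= dv * g4x
        out[i4, 1] -= dv * g4y
        out[i4, 2] -= dv * g4z


class CompiledForceField:
    """Packed topology + parameters with a fast ``forces`` method."""

    def __init__(self, topo, p):
        nc = topo.noncontact_pairs()
        pair_sets = []
        if len(topo.bonds):
            pair_sets.append((topo.bonds, 0, topo.r0))
        if len(topo.contacts):
            pair_sets.append((topo.contacts, 1, topo.sigma))
        if len(nc):
            pair_sets.append((nc, 2, np.zeros(len(nc))))
        if pair_sets:
            self.pairs = np.concatenate([ps[0] for ps in pair_sets])
            self.pair_kind = np.concatenate(
                [np.full(len(ps[0]), ps[1], np.int64) for ps in pair_sets])
            self.pair_ref = np.concatenate([ps[2] for ps in pair_sets])
        else:
            self.pairs = np.zeros((0, 2), np.int64)
            self.pair_kind = np.zeros(0, np.int64)
            self.pair_ref = np.zeros(0)
        self.angles = topo.angles
        self.theta0 = topo.theta0
        con = topo.dihedral_constrained
        quad_sets = []
        if len(topo.planar_dihedrals):
            quad_sets.append((topo.planar_dihedrals, 0, topo.xi0,
                              np.full(len(topo.planar_dihedrals), p.eps_xi)))
        if np.any(con):
            eps = np.where(topo.dihedral_is_backbone[con],
                           p.eps_phi_bb, p.eps_phi_sc)
            quad_sets.append((topo.proper_dihedrals[con], 1,
                              topo.phi0[con], eps))
        if quad_sets:
            self.quads = np.concatenate([qs[0] for qs in quad_sets])
            self.quad_kind = np.concatenate(
                [np.full(len(qs[0]), qs[1], np.int64) for qs in quad_sets])
            self.quad_ref = np.concatenate([qs[2] for qs in quad_sets])
            self.quad_eps = np.concatenate([qs[3] for qs in quad_sets])
        else:
            self.quads = np.zeros((0, 4), np.int64)
            self.quad_kind = np.zeros(0, np.int64)
            self.quad_ref = np.zeros(0)
            self.quad_eps = np.zeros(0)
        self.p = p
        self._buf = np.zeros((topo.n_atoms, 3))

    def forces(self, coord: np.ndarray) -> np.ndarray:
        _forces_kernel(coord,
                       self.pairs, self.pair_kind, self.pair_ref,
                       self.p.eps_r, self.p.eps_contact, self.p.eps_nc,
                       self.p.sigma_nc,
                       self.angles, self.theta0, self.p.eps_theta,
                       self.quads, self.quad_kind, self.quad_ref,
                       self.quad_eps, self._buf)
        return self._buf
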