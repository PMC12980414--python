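"""The structure-based potential and its analytic gradient.

The potential is a sum over the native topology:

* bonds            eps_r   * (r - r0)^2
* angles           eps_th  * (theta - theta0)^2
* planar dihedrals eps_xi  * (xi - xi0)^2
* proper dihedrals eps_phi * Fd(phi),
  Fd(phi) = [1 - cos(phi - phi0)] + 1/2 [1 - cos 3(phi - phi0)]
  (backbone and side-chain weights differ; released linker dihedrals
  contribute nothing)
* native contacts  eps_C  * [(sigma_ij/r)^12 - 2 (sigma_ij/r)^6]
  (minimum of exactly -eps_C at the native distance sigma_ij)
* all other pairs  eps_NC * (sigma_NC/r)^12   (pure repulsion)

Energies are in reduced units; lengths in Å, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .topology import SBMTopology, ForceFieldParameters


@dataclass
class EnergyBreakdown:
    """Per-term energies (reduced units); ``total`` is their sum."""

    bond: float = 0.0
    angle: float = 0.0
    planar: float = 0.0
    dihedral_bb: float = 0.0
    dihedral_sc: float = 0.0
    contact: float = 0.0
    noncontact: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.planar + self.dihedral_bb
                + self.dihedral_sc + self.contact + self.noncontact)

    def as_dict(self) -> dict[str, float]:
        d = {k: float(getattr(self, k)) for k in (
            "bond", "angle", "planar", "dihedral_bb", "dihedral_sc",
            "contact", "noncontact")}
        d["total"] = self.total
        return d


def dihedral_restraint(phi, phi0):
    """Periodic torsional restraint Fd; zero and minimal at phi = phi0."""
    d = np.asarray(phi, dtype=np.float64) - phi0
    return (1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d))


def dihedral_restraint_derivative(phi, phi0):
    d = np.asarray(phi, dtype=np.float64) - phi0
    return np.sin(d) + 1.5 * np.sin(3.0 * d)


def _check_conf(conf: np.ndarray, topo: SBMTopology) -> np.ndarray:
    conf = np.asarray(conf, dtype=np.float64)
    if conf.shape != (topo.n_atoms, 3):
        raise ValueError(
            f"conformation has shape {conf.shape}, topology expects "
            f"({topo.n_atoms}, 3)")
    return conf


def energy(conf: np.ndarray, topo: SBMTopology,
           p: ForceFieldParameters) -> EnergyBreakdown:
    """Evaluate every term of the potential at one conformation."""
    conf = _check_conf(conf, topo)
    out = EnergyBreakdown()

    if len(topo.bonds):
        r = geometry.bond_lengths(conf, topo.bonds)
        out.bond = float(p.eps_r * np.sum((r - topo.r0) ** 2))
    if len(topo.angles):
        th = geometry.bond_angles(conf, topo.angles)
        out.angle = float(p.eps_theta * np.sum((th - topo.theta0) ** 2))
    if len(topo.planar_dihedrals):
        xi = geometry.dihedral_angles(conf, topo.planar_dihedrals)
        dxi = geometry.wrap_angle(xi - topo.xi0)
        out.planar = float(p.eps_xi * np.sum(dxi ** 2))
    con = topo.dihedral_constrained
    if np.any(con):
        phi = geometry.dihedral_angles(conf, topo.proper_dihedrals[con])
        fd = dihedral_restraint(phi, topo.phi0[con])
        bb = topo.dihedral_is_backbone[con]
        out.dihedral_bb = float(p.eps_phi_bb * np.sum(fd[bb]))
        out.dihedral_sc = float(p.eps_phi_sc * np.sum(fd[~bb]))
    if len(topo.contacts):
        r = geometry.bond_lengths(conf, topo.contacts)
        x6 = (topo.sigma / r) ** 6
        out.contact = float(p.eps_contact * np.sum(x6 * x6 - 2.0 * x6))
    nc = topo.noncontact_pairs()
    if len(nc):
        r = geometry.bond_lengths(conf, nc)
        out.noncontact = float(p.eps_nc * np.sum((p.sigma_nc / r) ** 12))
    return out


def forces(conf: np.ndarray, topo: SBMTopology,
           p: ForceFieldParameters) -> np.ndarray:
    """Analytic forces F = -grad V, shape (n_atoms, 3)."""
    conf = _check_conf(conf, topo)
    idx_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []

    def _scatter_add(idx, vals):
        idx_parts.append(idx)
        val_parts.append(vals)

    # all pure pair terms (bonds, contacts, noncontact repulsion) share
    # one distance/gradient pass
    nc = topo.noncontact_pairs()
    pair_idx = [a for a in (topo.bonds, topo.contacts, nc) if len(a)]
    if pair_idx:
        pairs = np.concatenate(pair_idx, axis=0)
        d = conf[pairs[:, 1]] - conf[pairs[:, 0]]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dvdr = np.empty_like(r)
        lo = 0
        if len(topo.bonds):
            hi = lo + len(topo.bonds)
            dvdr[lo:hi] = 2.0 * p.eps_r * (r[lo:hi] - topo.r0)
            lo = hi
        if len(topo.contacts):
            hi = lo + len(topo.contacts)
            x6 = (topo.sigma / r[lo:hi]) ** 6
            dvdr[lo:hi] = p.eps_contact * 12.0 * (x6 - x6 * x6) / r[lo:hi]
            lo = hi
        if len(nc):
            rr = r[lo:]
            dvdr[lo:] = -12.0 * p.eps_nc * (p.sigma_nc / rr) ** 12 / rr
        scale = (dvdr / (r + 1e-300))[:, None] * d    # dV/dr * dr/dx_j
        _scatter_add(pairs[:, 0], scale)
        _scatter_add(pairs[:, 1], -scale)

    if len(topo.angles):
        th, gi, gj, gk = geometry.bond_angles_with_gradients(conf, topo.angles)
        dv = (2.0 * p.eps_theta * (th - topo.theta0))[:, None]
        _scatter_add(topo.angles[:, 0], -dv * gi)
        _scatter_add(topo.angles[:, 1], -dv * gj)
        _scatter_add(topo.angles[:, 2], -dv * gk)

    # planar and constrained proper dihedrals share one torsion pass
    con = topo.dihedral_constrained
    quad_sets = []
    if len(topo.planar_dihedrals):
        quad_sets.append(("planar", topo.planar_dihedrals))
    if np.any(con):
        quad_sets.append(("proper", topo.proper_dihedrals[con]))
    if quad_sets:
        quads = np.concatenate([q for _, q in quad_sets], axis=0)
        phi, grads = geometry.dihedrals_with_gradients(conf, quads)
        dv = np.empty(len(quads))
        lo = 0
        for kind, q in quad_sets:
            hi = lo + len(q)
            if kind == "planar":
                dv[lo:hi] = 2.0 * p.eps_xi * geometry.wrap_angle(
                    phi[lo:hi] - topo.xi0)
            else:
                eps = np.where(topo.dihedral_is_backbone[con],
                               p.eps_phi_bb, p.eps_phi_sc)
                dv[lo:hi] = eps * dihedral_restraint_derivative(
                    phi[lo:hi], topo.phi0[con])
            lo = hi
        dv = dv[:, None]
        for col, g in enumerate(grads):
            _scatter_add(quads[:, col], -dv * g)

    f = np.zeros_like(conf)
    if idx_parts:
        idx = np.concatenate(idx_parts)
        vals = np.concatenate(val_parts, axis=0)
        n = conf.shape[0]
        for k in range(3):
            f[:, k] = np.bincount(idx, weights=vals[:, k], minlength=n)
    return f
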