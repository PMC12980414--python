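"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its parameters and a seed and
emulates one of the pipeline's experimental inputs: toy multidomain
chains (a rigid two-domain core plus a flexible domain on a linker, and
a compact dimer of the same chain), Poisson-count SAXS curves, mono-
and bi-level relaxation decays, overlapping amide-I Voigt bands, and a
second-order-cumulant DLS autocorrelation.  The planted parameters are
returned alongside the data so recovery tests can score themselves.

The toy chains use three pseudo-atoms per residue (N, CA backbone plus
a CB side-chain atom, 1.5 Å bonds) so every term of the structure-based
potential — including side-chain dihedrals and planar centers — is
exercised without full residue templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .saxs import ScatteringCurve, debye_profile
from .spectro import _g2_model, _voigt_sum, hydrodynamic_diameter
from .structure import MolecularStructure, extract_chain, merge_structures

BOND_LENGTH = 1.5          # Å, pseudo-bond
MIN_NONBONDED = 2.5        # Å, self-avoidance acceptance threshold


# -- toy structures ----------------------------------------------------

def _grow_walk(rng, n_steps, start, direction_fn, existing, min_dist,
               max_tries=120, max_backtracks=2000):
    """Self-avoiding 1.5 Å-step walk; backtracks on dead ends and
    restarts from scratch (fresh random stream) if a fold jams.

    The full ``min_dist`` clearance applies to atoms at least three
    bonds away.  The 1-3 distance is kept in [2.0, 2.9] Å, i.e. bend
    angles in roughly [84°, 150°]: never so sharp that atoms clash and
    never near-linear, where angle and torsion gradients degenerate.
    """
    start = np.asarray(start, dtype=np.float64)
    angle_lo, angle_hi = 2.0, 2.9   # 1-3 distance window (Å)
    while True:
        pts = [start]
        backtracks = 0
        jammed = False
        while len(pts) < n_steps and not jammed:
            placed = False
            for _ in range(max_tries):
                u = direction_fn(len(pts), pts[-1], rng)
                cand = pts[-1] + BOND_LENGTH * u
                if len(pts) >= 2:
                    d13 = np.linalg.norm(cand - pts[-2])
                    if d13 < angle_lo or d13 > angle_hi:
                        continue
                cloud = pts[:-2] + existing
                if cloud and np.min(np.linalg.norm(
                        np.asarray(cloud) - cand, axis=1)) < min_dist:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                backtracks += 1
                if backtracks > max_backtracks:
                    jammed = True
                elif len(pts) > 1:
                    pts.pop()
                else:
                    jammed = True
        if not jammed:
            return pts


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chain_from_backbone(backbone, cb, title):
    n_res = len(backbone) // 2
    serial, name, element, res_index, coords = [], [], [], [], []
    cb_iter = iter(cb)
    k = 0
    for res in range(1, n_res + 1):
        for atom_name, elem, pos in (
                ("N", "N", backbone[2 * (res - 1)]),
                ("CA", "C", backbone[2 * (res - 1) + 1]),
                ("CB", "C", next(cb_iter))):
            k += 1
            serial.append(k)
            name.append(atom_name)
            element.append(elem)
            res_index.append(res)
            coords.append(pos)
    n = len(serial)
    return MolecularStructure(
        serial=np.array(serial), name=np.array(name),
        element=np.array(element), res_index=np.array(res_index),
        res_name=np.array(["GLY"] * n), chain_id=np.array(["A"] * n),
        coord=np.array(coords), title=title)


def _place_sidechains(rng, backbone, n_res_total):
    """One CB per residue hanging off each CA; prefers full 2.5 Å
    clearance, accepts >= 2.05 Å (safely above the 1.9 Å bond-detection
    cutoff, so no spurious bonds), gives up otherwise."""
    cb = []
    for res in range(n_res_total):
        ca = backbone[2 * res + 1]
        cloud = np.asarray(backbone + cb)
        mask = np.ones(len(cloud), dtype=bool)
        mask[2 * res + 1] = False      # its own CA is bonded, not a clash
        best, best_gap = None, -np.inf
        for _ in range(300):
            cand = ca + BOND_LENGTH * _random_unit(rng)
            gap = float(np.min(np.linalg.norm(cloud[mask] - cand, axis=1)))
            if gap >= MIN_NONBONDED:
                best, best_gap = cand, gap
                break
            if gap > best_gap:
                best, best_gap = cand, gap
        if best_gap < 2.05:
            return None
        cb.append(best)
    return cb


def make_toy_chain(n_res: int, seed: int = 0,
                   compact: bool = True) -> MolecularStructure:
    """Single-domain toy chain (3 pseudo-atoms/residue)."""
    s, _, _ = make_two_domain(n_res, 0, seed=seed, n_res_second=0,
                              compact=compact)
    return s


def make_two_domain(n_res_per_domain: int, linker_len: int, seed: int = 0,
                    n_res_second: int | None = None, compact: bool = True
                    ) -> tuple[MolecularStructure, dict, list]:
    """Two compact self-avoiding globules joined by an extended linker.

    Returns ``(structure, domain_map, linker_residues)`` where the map
    and linker ranges are in the 1-based inclusive form the topology
    builder consumes.  Deterministic for a fixed seed.
    """
    if n_res_per_domain < 3 and n_res_per_domain != 0:
        raise ValueError("domains need >= 3 residues")
    n2 = n_res_per_domain if n_res_second is None else n_res_second
    rng = np.random.default_rng(seed)
    n_res_total = n_res_per_domain + linker_len + n2

    # confinement radius from the self-avoidance volume per atom
    def radius(n_res):
        n_atoms = 2 * n_res
        return (n_atoms * MIN_NONBONDED ** 3 * 1.8 * 3 / (4 * np.pi)) ** (1 / 3)

    c1 = np.zeros(3)
    r1 = radius(max(n_res_per_domain, 1))
    lx = linker_len * 2 * BOND_LENGTH * 0.95
    c2 = np.array([r1 + lx + radius(max(n2, 1)), 0.0, 0.0])

    def direction(k, last, rng):
        res = k // 2 + 1
        if res <= n_res_per_domain and compact:
            u = _random_unit(rng)
            pull = c1 - last
            npull = np.linalg.norm(pull)
            if npull > r1:          # steer back into the globule
                u = 0.2 * u + 0.8 * pull / npull
        elif res <= n_res_per_domain + linker_len:
            u = np.array([1.0, 0.0, 0.0]) + 0.15 * rng.normal(size=3)
        else:
            u = _random_unit(rng)
            pull = c2 - last
            npull = np.linalg.norm(pull)
            if compact and npull > radius(max(n2, 1)):
                u = 0.2 * u + 0.8 * pull / npull
        return u / np.linalg.norm(u)

    # the side-chain pass occasionally finds no clash-free direction in
    # a dense fold; retry the whole build (rng stream continues, so the
    # result is still a pure function of the seed)
    for _attempt in range(50):
        backbone = _grow_walk(rng, 2 * n_res_total, c1, direction, [],
                              MIN_NONBONDED)
        cb = _place_sidechains(rng, backbone, n_res_total)
        if cb is not None:
            break
    else:
        raise RuntimeError("could not build a clash-free toy chain")

    s = _chain_from_backbone(backbone, cb, title=f"toy two-domain seed={seed}")
    domain_map, linker = {}, []
    if n_res_per_domain:
        domain_map["D1"] = [(1, n_res_per_domain)]
    if linker_len:
        linker = [(n_res_per_domain + 1, n_res_per_domain + linker_len)]
    if n2:
        domain_map["D2"] = [(n_res_per_domain + linker_len + 1, n_res_total)]
    return s, domain_map, linker


def make_dimer(monomer: MolecularStructure, contact_offset: float = 3.5,
               seed: int = 0) -> MolecularStructure:
    """Two copies of a chain related by a rigid transform with a small
    interface gap; chains labelled A (the input, untouched) and B."""
    rng = np.random.default_rng(seed)
    axis = _random_unit(rng)
    # 180° rotation about a random axis (Rodrigues with theta = pi)
    R = 2.0 * np.outer(axis, axis) - np.eye(3)
    com = monomer.coord.mean(axis=0)
    rotated = (monomer.coord - com) @ R.T + com
    u = _random_unit(rng)

    def min_gap(t):
        from scipy.spatial.distance import cdist
        return float(np.min(cdist(monomer.coord, rotated + t * u)))

    t_lo, t_hi = 0.0, 10.0
    while min_gap(t_hi) < contact_offset:
        t_hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (t_lo + t_hi)
        if min_gap(mid) < contact_offset:
            t_lo = mid
        else:
            t_hi = mid
    b = monomer.copy()
    b.coord = rotated + t_hi * u
    b.chain_id = np.full(b.n_atoms, "B", dtype="U4")
    a = monomer.copy()
    a.chain_id = np.full(a.n_atoms, "A", dtype="U4")
    dimer = merge_structures([a, b], title=monomer.title + " dimer")
    return dimer


# -- SAXS --------------------------------------------------------------

def default_q_grid(n: int = 1001, q_min: float = 0.013,
                   q_max: float = 0.26) -> np.ndarray:
    """The emulated instrument q grid (Å⁻¹): the 0.013–0.26 range at a
    typical azimuthal-integration binning of ~10³ radial bins, which
    keeps the sampling spread of chi^2 (sqrt(2/n) ≈ 0.045) well inside
    the selection band."""
    return np.linspace(q_min, q_max, n)


def synth_saxs(s: MolecularStructure, q_grid=None, mean_counts: float = 1e4,
               seed: int = 0, form_factor_model: str = "constant"
               ) -> ScatteringCurve:
    """Poisson-count noisy curve from a structure's Debye profile.

    The profile is scaled so its maximum is ``mean_counts`` detector
    counts and each point is sampled as a Poisson count.  The reported
    sigma is the counting-statistics noise level sqrt(lambda) of the
    underlying rate (what a real reduction pipeline approaches by
    averaging repeated exposures), mapped back to the intensity scale.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    rng = np.random.default_rng(seed)
    th = debye_profile(s, q, form_factor_model=form_factor_model)
    scale = mean_counts / float(np.max(th.I))
    lam = th.I * scale
    counts = rng.poisson(lam).astype(np.float64)
    return ScatteringCurve(q, counts / scale, np.sqrt(lam) / scale)


# -- planted ensembles -------------------------------------------------

@dataclass
class PlantedEnsemble:
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    labels: np.ndarray          # mode index per frame
    modes: list[np.ndarray]     # mode center conformations
    elements: np.ndarray


def swell(coord: np.ndarray, factor: float) -> np.ndarray:
    """Isotropic expansion about the centroid (a cheap 'unfolded' decoy)."""
    com = coord.mean(axis=0)
    return com + factor * (coord - com)


def planted_ensemble(base: MolecularStructure, n_frames: int = 1000,
                     mixture_weights=(0.7, 0.3),
                     perturbation_scales=(0.1, 0.25),
                     decoy_swell: float = 1.35,
                     seed: int = 0) -> PlantedEnsemble:
    """Frames drawn from labelled perturbation modes around the native
    conformation (mode 0) and a swollen decoy (mode 1, and further
    swelling for any extra modes)."""
    weights = np.asarray(mixture_weights, dtype=np.float64)
    weights = weights / weights.sum()
    scales = np.asarray(perturbation_scales, dtype=np.float64)
    if len(weights) != len(scales):
        raise ValueError("weights and scales must align")
    rng = np.random.default_rng(seed)
    modes = [base.coord.copy()]
    for m in range(1, len(weights)):
        modes.append(swell(base.coord, decoy_swell ** m))
    labels = rng.choice(len(weights), size=n_frames, p=weights)
    frames = np.empty((n_frames, base.n_atoms, 3))
    for k, lab in enumerate(labels):
        frames[k] = modes[lab] + rng.normal(
            0.0, scales[lab], size=(base.n_atoms, 3))
    return PlantedEnsemble(frames=frames, labels=labels, modes=modes,
                           elements=base.element.copy())


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no superposition)."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# -- spectroscopy series -----------------------------------------------

def synth_relaxation(kind: str, i0: float, rate: float, n_points: int = 12,
                     snr: float | None = 50.0, seed: int = 0,
                     t_max: float | None = None):
    """Noisy decay series from the exact relaxation forward model.

    Returns ``(t, I, truth)`` with the planted parameters in ``truth``.
    """
    rng = np.random.default_rng(seed)
    t_max = t_max if t_max is not None else 4.0 / rate
    t = np.linspace(t_max / n_points, t_max, n_points)
    if kind == "inversion_recovery":
        I = i0 * (1.0 - 2.0 * np.exp(-rate * t))
    elif kind == "cpmg_decay":
        I = i0 * np.exp(-rate * t)
    else:
        raise ValueError(f"unknown relaxation kind {kind!r}")
    # SNR is peak intensity over noise, matching the fitters' convention
    sigma = 0.0 if snr is None else float(np.max(np.abs(I))) / snr
    I = I + rng.normal(0.0, sigma, size=n_points) if sigma else I
    return t, I, {"i0": i0, "rate": rate, "snr": snr, "sigma": sigma}


def synth_ir(centers, areas, gaussian_width: float = 6.0,
             lorentzian_width: float = 4.0, noise: float = 0.0,
             seed: int = 0, step: float = 0.5):
    """Amide-I absorbance spectrum as a sum of planted Voigt bands."""
    rng = np.random.default_rng(seed)
    x = np.arange(1600.0, 1700.0 + step / 2, step)
    params = []
    for c, a in zip(centers, areas):
        params += [c, gaussian_width, lorentzian_width, a]
    y = _voigt_sum(x, *params)
    if noise:
        y = y + rng.normal(0.0, noise, size=len(x))
    return x, y, {"centers": list(centers), "areas": list(areas),
                  "gaussian_width": gaussian_width,
                  "lorentzian_width": lorentzian_width, "noise": noise}


def synth_dls(dh: float = 72.3, pdi: float = 0.05, baseline: float = 1.0,
              intercept: float = 0.8, mean_counts: float = 1e5,
              seed: int = 0, n_points: int = 80,
              **instrument):
    """Intensity autocorrelation with count-statistics noise.

    The decay rate is the one a particle of hydrodynamic diameter
    ``dh`` (Å) would show on a 90° 633 nm instrument (overridable via
    ``instrument`` keywords); per-point noise follows the Poisson-count
    model, sigma ∝ sqrt((g2 - B + 1/M)) with M = ``mean_counts``.
    """
    rng = np.random.default_rng(seed)
    gamma = hydrodynamic_diameter(dh, **instrument)  # involutive relation
    mu2 = pdi * gamma ** 2
    tau = np.logspace(-7, np.log10(50.0 / gamma), n_points)
    g2 = _g2_model(tau, baseline, intercept, gamma, mu2)
    sigma = np.sqrt((g2 - baseline) + 1.0) / np.sqrt(mean_counts)
    g2_noisy = g2 + rng.normal(0.0, sigma)
    return tau, g2_noisy, sigma, {
        "dh": dh, "gamma": gamma, "mu2": mu2, "pdi": pdi,
        "baseline": baseline, "intercept": intercept}
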