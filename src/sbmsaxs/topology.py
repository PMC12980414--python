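"""Structure-based-model topology construction.

From a native structure the builder enumerates bonds, bond angles,
planar (improper) dihedrals and proper dihedrals directly from covalent
connectivity, measures their native values, and records the exclusion
set (bonded, 1-3 and 1-4 pairs).  Native contacts are found with a
shadow criterion: an atom pair within a cutoff counts as a contact only
if no third atom, modelled as a sphere, occludes the line of sight
between the two.  Contacts bridging different rigid domains can be
excluded so that inter-domain arrangements are sampled freely, and
proper dihedrals inside flexible linkers can be released (restraint
weight zero).

Residue intervals for domains and linkers are 1-based and inclusive,
e.g. ``{"core": [(1, 10)], "flex": [(16, 25)]}`` with linker
``[(11, 15)]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import geometry
from .structure import MolecularStructure, StructureError

#: atom names treated as backbone for dihedral classification
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: defaults of the shadow-map contact search
DEFAULT_CONTACT_CUTOFF = 6.0    # Å
DEFAULT_SHADOW_RADIUS = 1.0     # Å
DEFAULT_MIN_SEQ_SEP = 3         # residues

ResidueRanges = list[tuple[int, int]]


class TopologyError(ValueError):
    """Raised when a topology cannot be built from the given structure."""


@dataclass
class ForceFieldParameters:
    """Energy prefactors of the structure-based potential (reduced units).

    ``eps_r`` (energy/Å²), ``eps_theta`` and ``eps_xi`` (energy/rad²)
    restrain bonds, angles and planar dihedrals to their native values;
    ``eps_phi_bb``/``eps_phi_sc`` weight the periodic proper-dihedral
    restraint; each native contact contributes a well of depth
    ``eps_contact``; all remaining pairs repel with the ``sigma_nc``
    excluded-volume radius scaled by ``eps_nc``.
    """

    eps_r: float = 100.0
    eps_theta: float = 20.0
    eps_xi: float = 10.0
    eps_phi_bb: float = 1.0
    eps_phi_sc: float = 0.5
    eps_contact: float = 1.0
    eps_nc: float = 0.01
    sigma_nc: float = 2.5

    def __post_init__(self) -> None:
        for name in ("eps_r", "eps_theta", "eps_xi", "eps_phi_bb",
                     "eps_phi_sc", "eps_contact", "eps_nc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_nc <= 0:
            raise ValueError("sigma_nc must be > 0")


@dataclass
class SBMTopology:
    """Bonded terms with native values, contacts and the exclusion set."""

    n_atoms: int
    bonds: np.ndarray            # (nb, 2) int
    r0: np.ndarray               # (nb,) Å
    angles: np.ndarray           # (na, 3) int
    theta0: np.ndarray           # (na,) rad
    planar_dihedrals: np.ndarray  # (nx, 4) int
    xi0: np.ndarray              # (nx,) rad
    proper_dihedrals: np.ndarray  # (nd, 4) int
    phi0: np.ndarray             # (nd,) rad
    dihedral_is_backbone: np.ndarray  # (nd,) bool
    dihedral_constrained: np.ndarray  # (nd,) bool
    contacts: np.ndarray         # (nc, 2) int, i < j
    sigma: np.ndarray            # (nc,) Å
    exclusions: np.ndarray       # (ne, 2) int, i < j  (bonded/1-3/1-4)
    _noncontact_cache: np.ndarray | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("bonds", "angles", "planar_dihedrals",
                     "proper_dihedrals", "contacts", "exclusions"):
            setattr(self, name, np.asarray(getattr(self, name),
                                           dtype=np.int64).reshape(-1, {
                "bonds": 2, "angles": 3, "planar_dihedrals": 4,
                "proper_dihedrals": 4, "contacts": 2, "exclusions": 2,
            }[name]))
        for name in ("r0", "theta0", "xi0", "phi0", "sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.dihedral_is_backbone = np.asarray(self.dihedral_is_backbone, bool)
        self.dihedral_constrained = np.asarray(self.dihedral_constrained, bool)

    # -- pair bookkeeping ---------------------------------------------

    def noncontact_pairs(self) -> np.ndarray:
        """All i<j pairs that are neither excluded nor native contacts."""
        if self._noncontact_cache is None:
            n = self.n_atoms
            iu, ju = np.triu_indices(n, k=1)
            keys = iu * n + ju
            drop = set()
            for arr in (self.exclusions, self.contacts):
                if len(arr):
                    lo = np.minimum(arr[:, 0], arr[:, 1])
                    hi = np.maximum(arr[:, 0], arr[:, 1])
                    drop.update((lo * n + hi).tolist())
            mask = ~np.isin(keys, np.fromiter(drop, dtype=np.int64,
                                              count=len(drop)))
            self._noncontact_cache = np.stack([iu[mask], ju[mask]], axis=1)
        return self._noncontact_cache

    # -- serialization -------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "units": {"length": "angstrom", "angle": "radian"},
            "n_atoms": self.n_atoms,
            "bonds": self.bonds.tolist(), "r0": self.r0.tolist(),
            "angles": self.angles.tolist(), "theta0": self.theta0.tolist(),
            "planar_dihedrals": self.planar_dihedrals.tolist(),
            "xi0": self.xi0.tolist(),
            "proper_dihedrals": self.proper_dihedrals.tolist(),
            "phi0": self.phi0.tolist(),
            "dihedral_is_backbone": self.dihedral_is_backbone.tolist(),
            "dihedral_constrained": self.dihedral_constrained.tolist(),
            "contacts": self.contacts.tolist(), "sigma": self.sigma.tolist(),
            "exclusions": self.exclusions.tolist(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SBMTopology":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload.pop("units", None)
        return cls(**payload)


# -- helpers -----------------------------------------------------------

def expand_ranges(ranges: ResidueRanges | set[int] | None) -> set[int]:
    """1-based inclusive residue intervals -> set of residue numbers."""
    if ranges is None:
        return set()
    if isinstance(ranges, (set, frozenset)):
        return set(int(r) for r in ranges)
    out: set[int] = set()
    for lo, hi in ranges:
        if hi < lo:
            raise ValueError(f"invalid residue interval ({lo}, {hi})")
        out.update(range(int(lo), int(hi) + 1))
    return out


def residue_domain_lookup(domain_map: dict[str, ResidueRanges] | None
                          ) -> dict[int, str]:
    """Flatten a domain map to residue-number -> domain-id."""
    lookup: dict[int, str] = {}
    if domain_map:
        for dom, ranges in domain_map.items():
            for res in expand_ranges(ranges):
                if res in lookup and lookup[res] != dom:
                    raise ValueError(f"residue {res} assigned to two domains")
                lookup[res] = dom
    return lookup


def _pair_key(n: int, pairs: np.ndarray) -> np.ndarray:
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    return lo * n + hi


# -- topology construction --------------------------------------------

def _covalent_bonds(s: MolecularStructure, bond_cutoff: float) -> np.ndarray:
    d = cdist(s.coord, s.coord)
    iu, ju = np.triu_indices(s.n_atoms, k=1)
    mask = d[iu, ju] < bond_cutoff
    return np.stack([iu[mask], ju[mask]], axis=1)


def build_topology(s: MolecularStructure,
                   linker_residues: ResidueRanges | set[int] | None = None,
                   domain_map: dict[str, ResidueRanges] | None = None,
                   bond_cutoff: float = 1.9,
                   chain_break_threshold: float = 2.0,
                   contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   shadow_radius: float = DEFAULT_SHADOW_RADIUS,
                   min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
                   with_contacts: bool = True) -> SBMTopology:
    """Build the full SBM topology from a single-chain native structure.

    Connectivity comes from a heavy-atom distance rule (``bond_cutoff``);
    native values of every internal coordinate are measured from ``s``.
    Proper dihedrals whose atoms touch a linker residue are released
    (``constrained = False``).  With ``with_contacts`` the shadow contact
    search is run and its pairs stored with their native distances.
    """
    s.validate()
    if len(s.chains()) != 1:
        raise TopologyError(
            f"topology requires a single chain, got {s.chains()}; "
            "use extract_chain first")

    bonds = _covalent_bonds(s, bond_cutoff)
    _check_chain_breaks(s, bonds, chain_break_threshold)

    n = s.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(int(j))
        adj[j].append(int(i))
    for nb in adj:
        nb.sort()

    angles = []
    for j in range(n):
        nb = adj[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)

    propers = []
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                propers.append((i, j, k, l))
    propers = np.asarray(propers, dtype=np.int64).reshape(-1, 4)

    # planar (improper) dihedrals: one per atom with exactly 3 neighbours,
    # keeping that atom's local frame near its native pyramid/plane; of
    # the equivalent neighbour orderings keep the best-conditioned one
    # (largest plane normals) so forces stay numerically clean
    impropers = []
    for j in range(n):
        if len(adj[j]) == 3:
            a, b, c = adj[j]
            options = ((a, j, b, c), (b, j, a, c), (a, j, c, b))
            impropers.append(max(options, key=lambda q: _improper_conditioning(
                s.coord, q)))
    impropers = np.asarray(impropers, dtype=np.int64).reshape(-1, 4)

    linker = expand_ranges(linker_residues)
    is_backbone_atom = np.isin(s.name, sorted(BACKBONE_ATOMS))
    res_of = s.res_index

    if len(propers):
        bb = np.all(is_backbone_atom[propers], axis=1)
        in_linker = np.array(
            [any(int(res_of[a]) in linker for a in quad) for quad in propers],
            dtype=bool)
        constrained = ~in_linker
    else:
        bb = np.zeros(0, bool)
        constrained = np.zeros(0, bool)

    exclusions = _exclusion_pairs(n, bonds, angles, propers)

    topo = SBMTopology(
        n_atoms=n,
        bonds=bonds, r0=geometry.bond_lengths(s.coord, bonds)
        if len(bonds) else np.zeros(0),
        angles=angles, theta0=geometry.bond_angles(s.coord, angles)
        if len(angles) else np.zeros(0),
        planar_dihedrals=impropers,
        xi0=geometry.dihedral_angles(s.coord, impropers)
        if len(impropers) else np.zeros(0),
        proper_dihedrals=propers,
        phi0=geometry.dihedral_angles(s.coord, propers)
        if len(propers) else np.zeros(0),
        dihedral_is_backbone=bb,
        dihedral_constrained=constrained,
        contacts=np.zeros((0, 2), np.int64), sigma=np.zeros(0),
        exclusions=exclusions,
    )
    if with_contacts:
        pairs, sigma = shadow_contacts(
            s, cutoff=contact_cutoff, shadow_radius=shadow_radius,
            domain_map=domain_map, min_seq_sep=min_seq_sep,
            exclusions=exclusions)
        topo.contacts = pairs
        topo.sigma = sigma
        topo._noncontact_cache = None
    return topo


def _improper_conditioning(coord: np.ndarray, quad) -> float:
    p1, p2, p3, p4 = (coord[i] for i in quad)
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    return min(float(n1 @ n1), float(n2 @ n2))


def _check_chain_breaks(s, bonds, threshold):
    res_ids = np.unique(s.res_index)
    linked: set[tuple[int, int]] = set()
    if len(bonds):
        res_pairs = np.sort(s.res_index[bonds], axis=1)
        inter = res_pairs[:, 0] != res_pairs[:, 1]
        linked = {(int(a), int(b)) for a, b in res_pairs[inter]}
    for a, b in zip(res_ids[:-1], res_ids[1:]):
        if b == a + 1 and (int(a), int(b)) not in linked:
            raise TopologyError(
                f"chain break between residues {int(a)} and {int(b)}: "
                f"no inter-residue bond within {threshold} Å")


def _exclusion_pairs(n, bonds, angles, propers) -> np.ndarray:
    keys: set[int] = set()
    def add(i, j):
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        keys.add(i * n + j)
    for i, j in bonds:
        add(i, j)
    for i, _, k in angles:
        add(i, k)
    for i, _, _, l in propers:
        add(i, l)
    out = np.array(sorted(keys), dtype=np.int64)
    return np.stack([out // n, out % n], axis=1) if len(out) else \
        np.zeros((0, 2), np.int64)


# -- shadow contacts ---------------------------------------------------

def _segment_point_distances(a: np.ndarray, b: np.ndarray,
                             points: np.ndarray) -> np.ndarray:
    """Distances from ``points`` (m,3) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / (denom + 1e-300), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def shadow_contacts(s: MolecularStructure,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    shadow_radius: float = DEFAULT_SHADOW_RADIUS,
                    domain_map: dict[str, ResidueRanges] | None = None,
                    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
                    exclusions: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Shadow-map native contacts.

    Returns ``(pairs, sigma)``: canonical i<j atom pairs within
    ``cutoff`` that are separated by at least ``min_seq_sep`` residues,
    not in ``exclusions``, not bridging two different domains of
    ``domain_map``, and whose connecting segment is not intersected by
    any third atom modelled as a sphere of ``shadow_radius``; ``sigma``
    holds the native distances.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = s.n_atoms
    coord = s.coord
    d = cdist(coord, coord)
    iu, ju = np.triu_indices(n, k=1)
    mask = d[iu, ju] <= cutoff
    mask &= np.abs(s.res_index[iu] - s.res_index[ju]) >= min_seq_sep
    if exclusions is not None and len(exclusions):
        keys = iu * n + ju
        mask &= ~np.isin(keys, _pair_key(n, exclusions))
    if domain_map:
        lookup = residue_domain_lookup(domain_map)
        dom = np.array([lookup.get(int(r), "") for r in s.res_index])
        mask &= (dom[iu] == dom[ju]) & (dom[iu] != "")
    cand = np.stack([iu[mask], ju[mask]], axis=1)

    keep = np.ones(len(cand), dtype=bool)
    idx_all = np.arange(n)
    for m, (i, j) in enumerate(cand):
        others = idx_all[(idx_all != i) & (idx_all != j)]
        dist = _segment_point_distances(coord[i], coord[j], coord[others])
        if np.any(dist < shadow_radius):
            keep[m] = False
    pairs = cand[keep]
    return pairs, d[pairs[:, 0], pairs[:, 1]] if len(pairs) else np.zeros(0)
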