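"""Synthetic structure generation: nanotubes, functional groups, water boxes.

Everything the simulation stage consumes is generated here from first
principles (tube lattice geometry, tabulated functional-group bond lengths,
TIP3P water geometry), so the pipeline needs no external coordinate files.
All coordinates are Cartesian angstroms; the tube axis is z; periodic boxes
are origin-centered with coordinates wrapped to [-L/2, L/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import align_rotation, random_rotation, rotation_about_axis

__all__ = [
    "AtomSite",
    "RigidMolecule",
    "SimulationBox",
    "SolvatedSystem",
    "TIP3P_OH",
    "TIP3P_HOH_DEG",
    "WATER_MOLAR_MASS",
    "AVOGADRO",
    "default_lj_parameters",
    "zigzag_radius",
    "build_zigzag_cnt",
    "functionalize",
    "build_drug_surrogate",
    "assign_charges",
    "make_complex",
    "make_tip3p_water",
    "water_count_for_density",
    "build_water_box",
    "solvate",
]

TIP3P_OH = 0.9572  # O-H bond, angstrom
TIP3P_HOH_DEG = 104.52  # H-O-H angle, degrees
WATER_MOLAR_MASS = 18.015  # g/mol
AVOGADRO = 6.02214076e23

_KNOWN_ELEMENTS = {
    "H", "He", "B", "C", "N", "O", "F", "Na", "Mg", "P", "S", "Cl", "K", "Ca",
    "Fe", "Zn", "Br", "I",
}


class AtomSite(NamedTuple):
    """One interaction site: element, position, charge and LJ parameters."""

    element: str
    position: np.ndarray
    partial_charge: float
    lj_sigma: float
    lj_epsilon: float


@dataclass
class RigidMolecule:
    """A molecule moved only as a rigid unit (internal geometry frozen).

    Sites are stored as parallel arrays; ``labels`` maps chemically meaningful
    site names (``O4``, ``N_py``, ``H3`` ...) to atom indices so charge maps
    and binding-site placement can address them.
    """

    molecule_id: str
    elements: list[str]
    positions: np.ndarray  # (n, 3) angstrom
    charges: np.ndarray  # elementary charges
    lj_sigma: np.ndarray  # angstrom
    lj_epsilon: np.ndarray  # kcal/mol
    labels: dict[str, int] = field(default_factory=dict)
    role: str = "solute"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("molecule needs at least one site")
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float).reshape(n)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float).reshape(n)
        if np.any(self.lj_sigma < 0) or np.any(self.lj_epsilon < 0):
            raise ValueError("LJ parameters must be non-negative")
        for el in self.elements:
            if el not in _KNOWN_ELEMENTS:
                raise ValueError(f"unknown element symbol {el!r}")
        for name, idx in self.labels.items():
            if not 0 <= idx < n:
                raise ValueError(f"label {name!r} points outside molecule")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def site(self, i: int) -> AtomSite:
        return AtomSite(self.elements[i], self.positions[i].copy(),
                        float(self.charges[i]), float(self.lj_sigma[i]),
                        float(self.lj_epsilon[i]))

    def labeled_position(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise KeyError(f"{self.molecule_id}: no site labeled {name!r}")
        return self.positions[self.labels[name]].copy()

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, vec: np.ndarray) -> "RigidMolecule":
        return replace(self, positions=self.positions + np.asarray(vec, float))

    def rotated(self, matrix: np.ndarray, center: np.ndarray | None = None) -> "RigidMolecule":
        c = self.centroid() if center is None else np.asarray(center, float)
        return replace(self, positions=(self.positions - c) @ np.asarray(matrix).T + c)

    def copy(self) -> "RigidMolecule":
        return replace(self, positions=self.positions.copy(),
                       charges=self.charges.copy(), lj_sigma=self.lj_sigma.copy(),
                       lj_epsilon=self.lj_epsilon.copy(), elements=list(self.elements),
                       labels=dict(self.labels))


@dataclass(frozen=True)
class SimulationBox:
    """Rectangular (usually cubic) periodic cell, origin-centered."""

    edge_lengths: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edge_lengths):
            raise ValueError("box edges must be positive")

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "SimulationBox":
        return cls((float(edge),) * 3, periodic)

    @property
    def volume(self) -> float:
        lx, ly, lz = self.edge_lengths
        return lx * ly * lz

    def edges_array(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Map positions into [-L/2, L/2) componentwise."""
        if not self.periodic:
            return np.asarray(positions, float)
        box = self.edges_array()
        return (np.asarray(positions, float) + box / 2) % box - box / 2


@dataclass
class SolvatedSystem:
    """One (optional) rigid solute plus rigid waters in a periodic box."""

    box: SimulationBox
    waters: list[RigidMolecule]
    solute: RigidMolecule | None = None
    temperature: float = 298.0

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    def water_array(self) -> np.ndarray:
        """(N, 3, 3) array of water site positions, O first."""
        if not self.waters:
            return np.zeros((0, 3, 3))
        return np.stack([w.positions for w in self.waters])

    def with_water_array(self, coords: np.ndarray) -> "SolvatedSystem":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.waters), 3, 3):
            raise ValueError("water coordinate array has wrong shape")
        waters = [replace(w, positions=coords[i].copy())
                  for i, w in enumerate(self.waters)]
        return SolvatedSystem(self.box, waters, self.solute, self.temperature)


def default_lj_parameters() -> pd.DataFrame:
    """Bundled generic solute Lennard-Jones set (element -> sigma, epsilon)."""
    with resources.files("nanosolv.data").joinpath("lj_solute_params.csv").open() as fh:
        return pd.read_csv(fh).set_index("element")


def _lj_for_elements(elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
    table = default_lj_parameters()
    sig = np.array([table.loc[el, "sigma"] if el in table.index else 0.0
                    for el in elements])
    eps = np.array([table.loc[el, "epsilon"] if el in table.index else 0.0
                    for el in elements])
    return sig, eps


# ---------------------------------------------------------------------------
# carbon nanotube
# ---------------------------------------------------------------------------

def zigzag_radius(n: int, cc_bond: float) -> float:
    """Radius of a zigzag (n,0) tube: sqrt(3) * n * a_cc / (2 pi)."""
    return math.sqrt(3.0) * n * cc_bond / (2.0 * math.pi)


def build_zigzag_cnt(n: int = 9, n_cells: int = 5, cc_bond: float = 1.455) -> RigidMolecule:
    """Generate a zigzag (n,0) carbon nanotube of ``n_cells`` unit cells.

    The translational unit cell holds 4n atoms in four rings of n; the tube
    axis is z and the tube is centered at the origin.  Every atom lies exactly
    on the cylinder of radius sqrt(3)*n*a_cc/(2 pi).  Defaults give the
    180-atom (9,0) tube of radius 3.61 angstrom used throughout the study.
    Tube ends are left open (no hydrogen caps); carbons carry zero charge.
    """
    if n < 3:
        raise ValueError("chiral index n must be >= 3")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 1.2 < cc_bond < 1.7:
        raise ValueError("cc_bond outside plausible carbon-carbon range")

    radius = zigzag_radius(n, cc_bond)
    a = cc_bond
    period = 3.0 * a
    # axial offsets and angular phase (in units of pi/n) of the four rings
    ring_geometry = [(0.0, 0.0), (0.5 * a, 1.0), (1.5 * a, 1.0), (2.0 * a, 0.0)]
    positions = []
    for cell in range(n_cells):
        z0 = cell * period
        for dz, phase in ring_geometry:
            for i in range(n):
                theta = (2.0 * i + phase) * math.pi / n
                positions.append(
                    (radius * math.cos(theta), radius * math.sin(theta), z0 + dz)
                )
    pos = np.array(positions)
    pos[:, 2] -= pos[:, 2].mean()  # center on origin
    n_atoms = pos.shape[0]
    sig, eps = _lj_for_elements(["C"] * n_atoms)
    return RigidMolecule(
        molecule_id=f"CNT({n},0)x{n_cells}",
        elements=["C"] * n_atoms,
        positions=pos,
        charges=np.zeros(n_atoms),
        lj_sigma=sig,
        lj_epsilon=eps,
    )


def _neighbor_counts(positions: np.ndarray, cutoff: float) -> np.ndarray:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return (d < cutoff).sum(axis=1)


def functionalize(cnt: RigidMolecule, group: str, site_index: int) -> RigidMolecule:
    """Attach an OH or COOH group to a sidewall carbon, radially outward.

    Bond lengths follow the tabulated optimized geometries: OH uses
    C-O 1.476 / O-H 0.999; COOH uses C1-O2 1.377, C1-O6 1.219, O2-H3 0.997.
    The new sites are labeled C1/O2/H3/O6 so Mulliken charge maps can be
    applied, matching the naming of the charge table.
    """
    group = group.upper()
    if group not in {"OH", "COOH"}:
        raise ValueError("group must be 'OH' or 'COOH'")
    if not 0 <= site_index < cnt.n_atoms:
        raise IndexError("site_index out of range")
    if cnt.elements[site_index] != "C":
        raise ValueError("functionalization site must be a carbon")

    # sidewall interior carbons have exactly three ring neighbours; a fourth
    # neighbour means an edge mismatch or a previously attached group
    dists = np.linalg.norm(cnt.positions - cnt.positions[site_index], axis=1)
    dists[site_index] = np.inf
    cc = dists.min()
    n_nb = int((dists < 1.25 * cc).sum())
    if n_nb != 3:
        raise ValueError(
            f"site {site_index} is not a pristine sidewall carbon "
            f"({n_nb} neighbours within {1.25 * cc:.2f} angstrom)"
        )

    site = cnt.positions[site_index]
    u = np.array([site[0], site[1], 0.0])
    nu = np.linalg.norm(u)
    if nu < 1e-6:
        raise ValueError("site lies on the tube axis; not a sidewall atom")
    u /= nu
    zhat = np.array([0.0, 0.0, 1.0])

    new_elements: list[str] = []
    new_pos: list[np.ndarray] = []
    labels = dict(cnt.labels)
    base = cnt.n_atoms

    if group == "OH":
        o2 = site + 1.476 * u
        # tetrahedral C-O-H angle, hydrogen tilted along the tube axis
        ang = math.radians(180.0 - 109.47)
        h3 = o2 + 0.999 * (math.cos(ang) * u + math.sin(ang) * zhat)
        new_elements += ["O", "H"]
        new_pos += [o2, h3]
        labels.update({"C1": site_index, "O2": base, "H3": base + 1})
    else:
        c1 = site + 1.52 * u
        d_o6 = 0.5 * u + math.sin(math.radians(120.0)) * zhat
        d_o2 = 0.5 * u - math.sin(math.radians(120.0)) * zhat
        o6 = c1 + 1.219 * d_o6 / np.linalg.norm(d_o6)
        o2 = c1 + 1.377 * d_o2 / np.linalg.norm(d_o2)
        v = (o2 - c1) / np.linalg.norm(o2 - c1)
        m = u - np.dot(u, v) * v
        m /= np.linalg.norm(m)
        ang = math.radians(180.0 - 106.0)
        h3 = o2 + 0.997 * (math.cos(ang) * v + math.sin(ang) * m)
        new_elements += ["C", "O", "O", "H"]
        new_pos += [c1, o6, o2, h3]
        labels.update({"C1": base, "O6": base + 1, "O2": base + 2, "H3": base + 3})

    elements = list(cnt.elements) + new_elements
    positions = np.vstack([cnt.positions, np.array(new_pos)])
    sig_new, eps_new = _lj_for_elements(new_elements)
    return RigidMolecule(
        molecule_id=f"{cnt.molecule_id}-{group}",
        elements=elements,
        positions=positions,
        charges=np.concatenate([cnt.charges, np.zeros(len(new_elements))]),
        lj_sigma=np.concatenate([cnt.lj_sigma, sig_new]),
        lj_epsilon=np.concatenate([cnt.lj_epsilon, eps_new]),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# drug surrogate
# ---------------------------------------------------------------------------

def _hexagon(center: np.ndarray, bond: float, phase_deg: float = 0.0) -> np.ndarray:
    ang = np.radians(phase_deg + 60.0 * np.arange(6))
    return center + bond * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)


def build_drug_surrogate() -> RigidMolecule:
    """Deterministic rigid stand-in for the optimized imatinib geometry.

    Synthetic surrogate: a planar two-ring scaffold (pyridine + benzene)
    bearing an amide group, reproducing the two binding motifs the analysis
    needs -- a carbonyl oxygen tagged ``O4`` (C=O bond fixed at the tabulated
    1.228 angstrom) and a pyridine nitrogen tagged ``N_py``.  It is a pure
    function of standard bond geometry, not a quantum-chemistry output, and is
    bitwise identical across calls.  Charges default to zero until
    :func:`assign_charges` applies a Mulliken charge map.
    """
    rb = 1.39  # aromatic ring bond
    elements: list[str] = []
    pos: list[np.ndarray] = []
    labels: dict[str, int] = {}

    def add(el: str, p: np.ndarray, label: str | None = None) -> int:
        idx = len(elements)
        elements.append(el)
        pos.append(np.asarray(p, float))
        if label:
            labels[label] = idx
        return idx

    # benzene centered at origin, vertices at 0, 60, ... degrees
    benz = _hexagon(np.zeros(3), rb)
    benz_ids = [add("C", p) for p in benz]

    # pyridine fused-free, attached at the -x benzene vertex through a 1.48 bond
    py_attach = benz[3]  # (-1.39, 0, 0)
    py_first = py_attach + np.array([-1.48, 0.0, 0.0])
    py_center = py_first + np.array([-rb, 0.0, 0.0])
    py = _hexagon(py_center, rb)
    for k, p in enumerate(py):
        # vertex opposite the attachment point becomes the pyridine nitrogen
        if k == 3:
            add("N", p, "N_py")
        else:
            add("C", p)

    # amide arm on the +x benzene vertex: C(=O4)-N(H)-CH3
    c_am = benz[0] + np.array([1.48, 0.0, 0.0])
    add("C", c_am, "C_carbonyl")
    add("O", c_am + 1.228 * np.array([0.5, math.sin(math.radians(60)), 0.0]), "O4")
    n_am = add("N", c_am + 1.35 * np.array([0.5, -math.sin(math.radians(60)), 0.0]))
    add("H", pos[n_am] + 1.01 * np.array([1.0, 0.0, 0.0]))
    add("C", pos[n_am] + 1.45 * np.array([0.0, -1.0, 0.0]), "C_methyl")

    # ring hydrogens on unsubstituted carbons, radially outward in-plane
    for ring_center, ring, skip in (
        (np.zeros(3), benz, {0, 3}),
        (py_center, py, {0, 3}),
    ):
        for k, p in enumerate(ring):
            if k in skip:
                continue
            out = (p - ring_center) / np.linalg.norm(p - ring_center)
            add("H", p + 1.08 * out)

    positions = np.array(pos)
    positions -= positions.mean(axis=0)
    sig, eps = _lj_for_elements(elements)
    return RigidMolecule(
        molecule_id="IMA-surrogate",
        elements=elements,
        positions=positions,
        charges=np.zeros(len(elements)),
        lj_sigma=sig,
        lj_epsilon=eps,
        labels=labels,
    )


def assign_charges(
    mol: RigidMolecule,
    charge_map: dict[str, float],
    neutralize: bool = True,
    formal_charge: float = 0.0,
) -> RigidMolecule:
    """Set partial charges on labeled sites; optionally rebalance the rest.

    With ``neutralize`` the residual (formal charge minus the mapped charges)
    is spread uniformly over the unmapped sites so the molecular total equals
    ``formal_charge`` exactly.
    """
    out = mol.copy()
    charges = np.zeros(mol.n_atoms) if neutralize else out.charges.copy()
    if not neutralize:
        charges = np.where(np.isfinite(charges), charges, 0.0)
    if neutralize:
        charges[:] = 0.0
    mapped = np.zeros(mol.n_atoms, dtype=bool)
    for label, q in charge_map.items():
        if label not in mol.labels:
            raise KeyError(f"{mol.molecule_id}: unknown site label {label!r}")
        charges[mol.labels[label]] = q
        mapped[mol.labels[label]] = True
    if neutralize:
        n_free = int((~mapped).sum())
        if n_free:
            charges[~mapped] = (formal_charge - charges[mapped].sum()) / n_free
    out.charges = charges
    return out


# ---------------------------------------------------------------------------
# complex posing
# ---------------------------------------------------------------------------

def _min_intermolecular_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def make_complex(
    drug: RigidMolecule,
    carrier: RigidMolecule,
    site: str = "CO",
    contact_distance: float = 1.8,
) -> RigidMolecule:
    """Rigidly pose the drug on the carrier at the chosen binding motif.

    ``site='CO'`` anchors the drug's carbonyl oxygen (O4); ``site='PY'`` the
    pyridine nitrogen.  For a functionalized carrier the tagged site is placed
    ``contact_distance`` from the acidic hydrogen H3 along the O-H direction
    (a hydrogen-bond pose); for a pristine tube the drug ring plane is laid
    parallel to the tube surface at ``contact_distance`` (a pi-stacking pose).
    The result is a single rigid unit with all site labels preserved.
    """
    site = site.upper()
    if site not in {"CO", "PY"}:
        raise ValueError("site must be 'CO' or 'PY'")
    tag = "O4" if site == "CO" else "N_py"
    if tag not in drug.labels:
        raise ValueError(f"drug has no {tag} site")

    posed = drug.copy()
    if "H3" in carrier.labels:
        anchor = carrier.labeled_position("H3")
        direction = anchor - carrier.labeled_position("O2")
        direction /= np.linalg.norm(direction)
        target = anchor + contact_distance * direction
        # orient the drug so its bulk points away from the tube
        rot = align_rotation(posed.centroid() - posed.labeled_position(tag), direction)
        posed = posed.rotated(rot, center=posed.labeled_position(tag))
        posed = posed.translated(target - posed.labeled_position(tag))
        spin_axis = direction
    else:
        # pristine tube: stack above the sidewall along +x
        radial = np.array([1.0, 0.0, 0.0])
        radii = np.linalg.norm(carrier.positions[:, :2], axis=1)
        r_wall = float(radii.max())
        normal = _plane_normal(posed)
        rot = align_rotation(normal, radial)
        posed = posed.rotated(rot, center=posed.centroid())
        target_center = (r_wall + contact_distance) * radial
        posed = posed.translated(target_center - posed.centroid())
        spin_axis = radial

    chosen = None
    for spin_deg in range(0, 360, 30):
        trial = posed.rotated(
            rotation_about_axis(spin_axis, math.radians(spin_deg)),
            center=posed.labeled_position(tag) if "H3" in carrier.labels
            else posed.centroid(),
        )
        if _min_intermolecular_distance(trial.positions, carrier.positions) >= 1.0:
            chosen = trial
            break
    if chosen is None:
        raise ValueError("could not pose drug without steric clash")

    elements = list(carrier.elements) + list(chosen.elements)
    positions = np.vstack([carrier.positions, chosen.positions])
    labels = dict(carrier.labels)
    offset = carrier.n_atoms
    for name, idx in chosen.labels.items():
        labels[name] = idx + offset
    return RigidMolecule(
        molecule_id=f"{carrier.molecule_id}-D({site})",
        elements=elements,
        positions=positions,
        charges=np.concatenate([carrier.charges, chosen.charges]),
        lj_sigma=np.concatenate([carrier.lj_sigma, chosen.lj_sigma]),
        lj_epsilon=np.concatenate([carrier.lj_epsilon, chosen.lj_epsilon]),
        labels=labels,
    )


def _plane_normal(mol: RigidMolecule) -> np.ndarray:
    centered = mol.positions - mol.centroid()
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[2]


# ---------------------------------------------------------------------------
# water
# ---------------------------------------------------------------------------

def make_tip3p_water(index: int = 0) -> RigidMolecule:
    """One TIP3P water at the origin in its canonical orientation."""
    half = math.radians(TIP3P_HOH_DEG / 2.0)
    hx, hy = TIP3P_OH * math.sin(half), TIP3P_OH * math.cos(half)
    positions = np.array([[0.0, 0.0, 0.0], [hx, hy, 0.0], [-hx, hy, 0.0]])
    return RigidMolecule(
        molecule_id=f"HOH{index}",
        elements=["O", "H", "H"],
        positions=positions,
        charges=np.array([-0.834, 0.417, 0.417]),
        lj_sigma=np.array([3.15061, 0.0, 0.0]),
        lj_epsilon=np.array([0.1521, 0.0, 0.0]),
        role="water",
    )


def water_count_for_density(box: SimulationBox, density: float) -> int:
    """Closed-form molecule count: N = round(rho * V * N_A / M)."""
    volume_cm3 = box.volume * 1e-24
    return int(round(density * volume_cm3 * AVOGADRO / WATER_MOLAR_MASS))


def build_water_box(
    box: SimulationBox,
    density: float = 0.993,
    temperature: float = 298.0,
    seed: int | np.random.Generator = 0,
) -> SolvatedSystem:
    """Fill a periodic box with rigid TIP3P waters at the requested density.

    Oxygens go on a jittered cubic lattice with random molecular orientations;
    the jitter amplitude is capped so that no two molecules can come closer
    than 0.5 angstrom site-to-site, keeping the initial configuration finite
    in energy.  Deterministic for a given seed.
    """
    if not 0.5 < density < 1.5:
        raise ValueError("density outside liquid-water range")
    n = water_count_for_density(box, density)
    if n < 1:
        raise ValueError("box too small to hold one water at this density")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lx, ly, lz = box.edge_lengths
    m = max(1, math.ceil(n ** (1.0 / 3.0)))
    while m ** 3 < n:
        m += 1
    spacing = min(lx, ly, lz) / m
    # guarantee O-O >= 2.42 so site-site >= 0.5 even for unlucky orientations
    jitter = max(0.0, min(0.2, (spacing - 2.42) / (2.0 * math.sqrt(3.0))))

    cells = np.stack(np.meshgrid(range(m), range(m), range(m), indexing="ij"),
                     axis=-1).reshape(-1, 3)
    chosen = cells[rng.permutation(m ** 3)[:n]]
    origins = (chosen + 0.5) * np.array([lx, ly, lz]) / m - np.array([lx, ly, lz]) / 2
    origins = origins + rng.uniform(-jitter, jitter, size=origins.shape)

    template = make_tip3p_water()
    waters = []
    for i in range(n):
        rot = random_rotation(rng)
        pos = template.positions @ rot.T + origins[i]
        waters.append(replace(template, molecule_id=f"HOH{i}", positions=pos))
    system = SolvatedSystem(box=box, waters=waters, solute=None,
                            temperature=temperature)
    return system


def solvate(
    solute: RigidMolecule | None,
    waterbox: SolvatedSystem,
    clash_cutoff: float = 2.6,
) -> SolvatedSystem:
    """Immerse a solute in a pre-built water box, deleting clashing waters.

    The solute is centered at the origin; every water having any site within
    ``clash_cutoff`` of any solute site (minimum image) is removed.
    Idempotent, and monotone in the cutoff.
    """
    if solute is None:
        return SolvatedSystem(waterbox.box, [w.copy() for w in waterbox.waters],
                              None, waterbox.temperature)
    box = waterbox.box
    centered = solute.translated(-solute.centroid())
    half = box.edges_array() / 2
    if np.any(np.abs(centered.positions) > half):
        raise ValueError("solute does not fit in the box")
    kept = []
    edges = box.edges_array()
    for w in waterbox.waters:
        delta = w.positions[:, None, :] - centered.positions[None, :, :]
        if box.periodic:
            delta -= edges * np.round(delta / edges)
        if np.min(np.einsum("ijk,ijk->ij", delta, delta)) >= clash_cutoff ** 2:
            kept.append(w.copy())
    return SolvatedSystem(box, kept, centered, waterbox.temperature)
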