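"""Post-simulation structure analysis: cylindrical water distribution.

The solvent structure around a nanotube is summarized by the cylindrical
radial distribution function g(r) = rho(r) / rho_bulk, where r is the
perpendicular distance of a water oxygen from the tube axis and rho(r) the
per-shell number density within a slab spanning the tube; rho_bulk is the
overall water density of the same trajectory, so g approaches 1 far from
the tube by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_structure, write_xyz_frames
from .structures import RigidMolecule, SimulationBox, SolvatedSystem

__all__ = [
    "RDFProfile",
    "cylindrical_rdf",
    "first_exterior_peak",
    "bulk_convergence",
    "export_snapshot",
]


@dataclass(frozen=True)
class RDFProfile:
    """Cylindrical RDF on uniform bins [k*w, (k+1)*w)."""

    bin_centers: np.ndarray  # angstrom from the axis
    g_values: np.ndarray  # dimensionless
    counts: np.ndarray  # raw oxygen counts per bin, summed over frames
    bulk_density: float  # molecules / angstrom^3
    slab_height: float  # angstrom
    n_frames: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.bin_centers, "g": self.g_values})


def _oxygen_frames(trajectory) -> list[np.ndarray]:
    frames = []
    for f in trajectory:
        arr = np.asarray(f, float)
        if arr.ndim == 3:  # (Nw, sites, 3): oxygens first
            arr = arr[:, 0, :]
        frames.append(arr)
    return frames


def cylindrical_rdf(
    trajectory,
    box: SimulationBox,
    axis_point=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
    r_max: float | None = None,
    bin_width: float = 0.1,
    slab_height: float | None = None,
    bulk_region: tuple[float, float] | None = None,
) -> RDFProfile:
    """Water-oxygen density around an axis, normalized to the bulk density.

    ``trajectory`` is a sequence of per-frame water coordinates, either
    (N, 3, 3) site arrays (oxygen first) or (N, 3) oxygen positions.  Only
    oxygens whose axial coordinate lies within ``slab_height`` (centered on
    ``axis_point``) are counted; shell volumes are exact cylindrical shells.

    By default the bulk density is the frame-average water count over the
    box volume (N/V).  In a reduced box a bulky solute makes N/V an
    underestimate of the true far-field density (the solute excludes volume),
    inflating g everywhere; passing ``bulk_region=(r_lo, r_hi)`` instead
    estimates the bulk density from the trajectory's own far cylindrical
    region, which removes that finite-size bias.
    """
    frames = _oxygen_frames(trajectory)
    if len(frames) == 0:
        raise ValueError("trajectory has no frames")
    origin = np.asarray(axis_point, float)
    axis = np.asarray(axis_direction, float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis direction must be non-zero")
    axis = axis / norm

    if r_max is None:
        # largest radius with complete cylindrical shells perpendicular to z
        r_max = min(box.edge_lengths[0], box.edge_lengths[1]) / 2.0
    if slab_height is None:
        slab_height = min(box.edge_lengths)
    if bin_width <= 0 or r_max <= bin_width:
        raise ValueError("need bin_width > 0 and r_max > bin_width")

    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    n_total = 0
    for pts in frames:
        rel = pts - origin
        t = rel @ axis
        perp = rel - np.outer(t, axis)
        r = np.linalg.norm(perp, axis=1)
        sel = np.abs(t) <= slab_height / 2.0
        hist, _ = np.histogram(r[sel], bins=edges)
        counts += hist
        n_total += pts.shape[0]
    shell_volumes = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * slab_height
    rho = counts / (len(frames) * shell_volumes)
    if bulk_region is not None:
        r_lo, r_hi = bulk_region
        centers = 0.5 * (edges[1:] + edges[:-1])
        far = (centers >= r_lo) & (centers <= r_hi)
        if not np.any(far):
            raise ValueError("bulk_region contains no bins")
        bulk = counts[far].sum() / (len(frames) * shell_volumes[far].sum())
    else:
        bulk = (n_total / len(frames)) / box.volume
    return RDFProfile(
        bin_centers=0.5 * (edges[1:] + edges[:-1]),
        g_values=rho / bulk,
        counts=counts,
        bulk_density=bulk,
        slab_height=float(slab_height),
        n_frames=len(frames),
    )


def first_exterior_peak(profile: RDFProfile, tube_radius: float) -> tuple[float, float]:
    """Bin center and height of the largest g(r) outside the tube wall."""
    mask = profile.bin_centers > tube_radius
    if not np.any(mask):
        raise ValueError("no bins beyond the tube radius")
    g_ext = np.where(mask, profile.g_values, -np.inf)
    k = int(np.argmax(g_ext))
    return float(profile.bin_centers[k]), float(profile.g_values[k])


def bulk_convergence(profile: RDFProfile, r_from: float, tolerance: float = 0.1) -> bool:
    """True if mean |g - 1| beyond ``r_from`` is below the tolerance."""
    mask = profile.bin_centers > r_from
    if not np.any(mask):
        raise ValueError("no bins beyond r_from")
    return bool(np.mean(np.abs(profile.g_values[mask] - 1.0)) < tolerance)


def export_snapshot(frame, path: str | Path, format: str | None = None) -> None:
    """Write a system, molecule, or trajectory to XYZ/PDB.

    ``frame`` may be a SolvatedSystem, a RigidMolecule, or a list of water
    coordinate arrays (multi-frame XYZ, oxygens and hydrogens).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"xyz", "pdb"}:
        raise ValueError(f"unknown snapshot format {fmt!r}")
    if isinstance(frame, (SolvatedSystem, RigidMolecule)):
        write_structure(frame, path.with_suffix(f".{fmt}"))
        return
    frames = [np.asarray(f, float).reshape(-1, 3) for f in frame]
    if fmt != "xyz":
        raise ValueError("multi-frame export supports XYZ only")
    n_sites = frames[0].shape[0]
    elements = (["O", "H", "H"] * ((n_sites + 2) // 3))[:n_sites]
    write_xyz_frames(path, frames, elements)
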