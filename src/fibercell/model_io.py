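"""Readers converting atomic models and density maps into scatterer sets.

Atomic coordinate files (PDB format) and CCP4/MRC density maps are both
reduced to weighted point scatterers.  At the ≥60 Å resolution of
low-angle fiber patterns atomic form factors are flat, so atoms are
weighted simply by atomic number (hydrogens omitted); map voxels become
point scatterers at their centres weighted by the voxel value, negatives
included, since fitting rescales total intensity anyway.

File parsing is delegated to gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from fibercell.lattice import FilamentModel, Scatterer

__all__ = [
    "DensityGrid", "read_atomic_model", "read_density_map",
    "write_density_map", "grid_to_scatterers",
]


@dataclass
class DensityGrid:
    """A scalar density sampled on a regular 3D grid.

    ``voxel_size`` is Å per voxel along each axis and ``origin`` the
    Cartesian position (Å) of the corner of voxel (0,0,0).  Values are on
    an arbitrary scale.
    """

    dims: tuple[int, int, int]
    voxel_size: np.ndarray
    origin: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"grid dims must be positive, got {self.dims}")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        if self.values.shape != self.dims:
            raise ValueError(
                f"values shape {self.values.shape} != dims {self.dims}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def read_atomic_model(
    path, symmetry_order: int = 1, axial_repeat: float | None = None,
    label: str | None = None,
) -> FilamentModel:
    """Read a PDB-format coordinate file into a FilamentModel.

    One scatterer per non-hydrogen atom, weighted by atomic number,
    positions in Å.  Raises ValueError on malformed records (gemmi reports
    the offending line) or on atoms with an unidentifiable element.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    positions, weights = [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.is_hydrogen():
                        continue
                    z = atom.element.atomic_number
                    if z == 0:
                        raise ValueError(
                            f"unknown element for atom {atom.name!r} in "
                            f"residue {res.name} {res.seqid.num} of {path}")
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(float(z))
        break  # first model only
    if not positions:
        raise ValueError(f"no atoms parsed from {path}")
    return FilamentModel(
        np.array(positions), np.array(weights),
        symmetry_order=symmetry_order,
        axial_repeat=axial_repeat if axial_repeat is not None else 1.0,
        label=label if label is not None else str(path),
    )


def read_density_map(path) -> DensityGrid:
    """Read a CCP4/MRC-format density map into a DensityGrid."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"not a readable CCP4/MRC map: {path}: {exc}") from exc
    grid = ccp4.grid
    dims = (grid.nu, grid.nv, grid.nw)
    cell = grid.unit_cell
    voxel = np.array([cell.a / dims[0], cell.b / dims[1], cell.c / dims[2]])
    try:
        origin = np.array([ccp4.header_float(50), ccp4.header_float(51),
                           ccp4.header_float(52)])
    except Exception:
        origin = np.zeros(3)
    values = np.array(grid, copy=True).astype(float)
    return DensityGrid(dims=dims, voxel_size=voxel, origin=origin,
                       values=values)


def write_density_map(grid: DensityGrid, path) -> None:
    """Write a DensityGrid as a mode-2 (float) CCP4 map."""
    g = gemmi.FloatGrid(*grid.dims)
    g.spacegroup = gemmi.SpaceGroup("P1")
    g.unit_cell = gemmi.UnitCell(
        grid.voxel_size[0] * grid.dims[0],
        grid.voxel_size[1] * grid.dims[1],
        grid.voxel_size[2] * grid.dims[2], 90, 90, 90)
    np.array(g, copy=False)[:] = grid.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.set_header_float(50, float(grid.origin[0]))
    ccp4.set_header_float(51, float(grid.origin[1]))
    ccp4.set_header_float(52, float(grid.origin[2]))
    ccp4.write_ccp4_map(str(path))


def grid_to_scatterers(grid: DensityGrid, threshold: float = 0.0) -> list[Scatterer]:
    """One point scatterer per voxel above threshold, at the voxel centre.

    Weights are the raw voxel values, so the summed weight equals the sum
    of above-threshold values and F(0,0,0) of the resulting scatterer set
    conserves the map's total density.
    """
    mask = grid.values > threshold
    if not mask.any():
        raise ValueError(
            f"threshold {threshold} is above the grid maximum "
            f"({grid.values.max():g}); no scatterers")
    idx = np.argwhere(mask)
    centres = grid.origin + (idx + 0.5) * grid.voxel_size
    vals = grid.values[mask]
    return [Scatterer(tuple(c), float(v)) for c, v in zip(centres, vals)]
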