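"""Hexagonal A-band unit cells and placement of filament models.

The muscle A-band lattices handled here are hexagonal with one myosin
filament per cell corner: the vertebrate (bony fish) simple lattice,
a = b = 470 Å, c = 429.6 Å, and the insect flight-muscle lattice,
a = b = 510 Å, c = 1160 Å, both with α = β = 90°, γ = 120°.  The filament
axis runs along c.  Actin filaments are never placed: their layer lines are
unsampled and are stripped from observed patterns as background, so the
model is myosin-only.

Conventions
-----------
* The filament axis is z and coincides with the c axis.
* Azimuthal rotation is counterclockwise looking down +z, in degrees;
  rotation 0 aligns the model frame's x-axis with the cell a edge.
* Fractional coordinates are wrapped into the half-open interval [0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "UnitCell", "Scatterer", "FilamentModel", "PlacedCell",
    "make_unit_cell", "reciprocal_radius", "d_spacing", "place_filament",
    "check_rotational_symmetry",
]


@dataclass(frozen=True)
class UnitCell:
    """Hexagonal unit cell with the filament axis along c.

    Only the a = b, α = β = 90°, γ = 120° setting used by muscle A-band
    lattices is supported; any other setting is rejected at construction.
    Lengths in Å, angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 120.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"cell length {name} must be positive, got {v!r}")
        if self.a != self.b:
            raise ValueError(
                f"unsupported setting: a must equal b (got a={self.a}, b={self.b})"
            )
        if (self.alpha, self.beta, self.gamma) != (90.0, 90.0, 120.0):
            raise ValueError(
                "unsupported setting: require alpha = beta = 90, gamma = 120 "
                f"(got {self.alpha}, {self.beta}, {self.gamma})"
            )

    @property
    def volume(self) -> float:
        """Cell volume a²·c·sin(120°) in Å³."""
        return self.a * self.b * self.c * np.sin(np.radians(self.gamma))

    @property
    def direct_basis(self) -> np.ndarray:
        """3×3 matrix whose *columns* are the cell edge vectors in Å.

        a1 = (a, 0, 0); a2 = (−a/2, a·√3/2, 0); a3 = (0, 0, c).
        """
        g = np.radians(self.gamma)
        return np.array(
            [
                [self.a, self.b * np.cos(g), 0.0],
                [0.0, self.b * np.sin(g), 0.0],
                [0.0, 0.0, self.c],
            ]
        )

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian (Å) → fractional coordinates (no wrapping)."""
        return np.asarray(xyz, dtype=float) @ np.linalg.inv(self.direct_basis).T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional → Cartesian coordinates (Å)."""
        return np.asarray(frac, dtype=float) @ self.direct_basis.T


@dataclass(frozen=True)
class Scatterer:
    """A weighted point scatterer in the filament frame (axis along z).

    The weight is in electrons for atoms, map value for voxels, and
    arbitrary units for synthetic blobs; only relative weights matter
    because fitting rescales total intensity.
    """

    position: tuple[float, float, float]
    weight: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite scatterer position {self.position!r}")
        if not np.isfinite(self.weight):
            raise ValueError(f"non-finite scatterer weight {self.weight!r}")


@dataclass
class FilamentModel:
    """Weighted point-scatterer model of a filament in its own axis frame.

    Positions are (N, 3) Cartesian Å with the filament axis along z;
    ``symmetry_order`` declares C_n rotational symmetry about z (checked,
    with a warning on failure) and ``axial_repeat`` the true axial repeat
    in Å (429.6 Å for the vertebrate filament, 1160 Å for insect).
    """

    positions: np.ndarray
    weights: np.ndarray
    symmetry_order: int = 1
    axial_repeat: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.positions.shape[0] == 0:
            raise ValueError("filament model must contain at least one scatterer")
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.positions.shape[0] != self.weights.shape[0]:
            raise ValueError("positions and weights length mismatch")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.weights))):
            raise ValueError("positions and weights must be finite")
        if self.axial_repeat <= 0:
            raise ValueError("axial_repeat must be positive")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        if self.symmetry_order > 1:
            mismatch = check_rotational_symmetry(self, self.symmetry_order)
            if mismatch > 1e-6 * max(1.0, float(np.abs(self.positions).max())):
                warnings.warn(
                    f"model {self.label!r} declared C{self.symmetry_order} but "
                    f"rotated copy mismatches by up to {mismatch:.3g} Å",
                    stacklevel=2,
                )

    @classmethod
    def from_scatterers(
        cls,
        scatterers: list[Scatterer],
        symmetry_order: int = 1,
        axial_repeat: float = 1.0,
        label: str = "",
    ) -> "FilamentModel":
        pos = np.array([s.position for s in scatterers], dtype=float)
        w = np.array([s.weight for s in scatterers], dtype=float)
        return cls(pos, w, symmetry_order, axial_repeat, label)

    @property
    def scatterers(self) -> list[Scatterer]:
        return [
            Scatterer(tuple(p), float(w))
            for p, w in zip(self.positions, self.weights)
        ]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class PlacedCell:
    """A filament model placed at the cell corner with an azimuthal rotation.

    ``frac`` holds fractional coordinates wrapped into [0, 1); the total
    scatterer weight equals that of the source model.
    """

    cell: UnitCell
    frac: np.ndarray
    weights: np.ndarray
    rotation: float = 0.0

    @property
    def fractional_scatterers(self) -> list[tuple[float, float, float, float]]:
        return [
            (float(x), float(y), float(z), float(w))
            for (x, y, z), w in zip(self.frac, self.weights)
        ]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def make_unit_cell(a: float, b: float, c: float, gamma: float = 120.0) -> UnitCell:
    """Build and validate a hexagonal unit cell (lengths Å, gamma degrees)."""
    return UnitCell(a=float(a), b=float(b), c=float(c), gamma=float(gamma))


def reciprocal_radius(cell: UnitCell, h: int, k: int) -> float:
    """Equatorial reciprocal radius |h·a* + k·b*| in Å⁻¹.

    For the a = b hexagonal setting this is sqrt(4(h² + hk + k²) / (3a²)),
    so indices with equal s = h² + hk + k² (e.g. 5,3 and 7,0 with s = 49)
    fall at the same radius and belong to the same fiber multiplet.
    """
    s = h * h + h * k + k * k
    return float(np.sqrt(4.0 * s / (3.0 * cell.a ** 2)))


def d_spacing(cell: UnitCell, h: int, k: int, l: int) -> float:
    """Bragg spacing d(h,k,l) in Å: 1/d² = r_perp² + (l/c)².

    Meridional reflections (0,0,l) give exactly c/l.
    """
    if h == 0 and k == 0 and l == 0:
        raise ValueError("d-spacing undefined for (0,0,0)")
    inv_d2 = reciprocal_radius(cell, h, k) ** 2 + (l / cell.c) ** 2
    return float(1.0 / np.sqrt(inv_d2))


def _rotation_z(angle_deg: float) -> np.ndarray:
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def check_rotational_symmetry(model: FilamentModel, order: int) -> float:
    """Largest distance (Å) by which the model rotated by 360/order fails
    to map onto itself (nearest-neighbour matching, weights compared too)."""
    rot = model.positions @ _rotation_z(360.0 / order).T
    tree = cKDTree(model.positions)
    dist, idx = tree.query(rot, k=1)
    scale = max(1.0, float(np.abs(model.weights).max()))
    wmis = np.abs(model.weights[idx] - model.weights) / scale
    return float(max(dist.max(), wmis.max()))


def place_filament(
    cell: UnitCell,
    model: FilamentModel,
    rotation: float,
    repeat_tolerance: float = 0.01,
) -> PlacedCell:
    """Rotate a filament model about the c axis and place it at the cell corner.

    Scatterers are rotated by ``rotation`` degrees about z, converted to
    fractional coordinates through the cell basis and wrapped into [0, 1).
    If the model's axial repeat differs from c by more than
    ``repeat_tolerance`` (relative), a warning is issued — EM-derived
    repeats routinely differ slightly from the X-ray cell.
    """
    if len(model) == 0:  # pragma: no cover - FilamentModel forbids this
        raise ValueError("cannot place an empty model")
    if abs(model.axial_repeat - cell.c) / cell.c > repeat_tolerance:
        warnings.warn(
            f"model axial repeat {model.axial_repeat:g} Å differs from cell "
            f"c = {cell.c:g} Å by more than {repeat_tolerance:.1%}",
            stacklevel=2,
        )
    cart = model.positions @ _rotation_z(rotation).T
    frac = cell.fractionalize(cart) % 1.0
    frac[frac >= 1.0] = 0.0  # guard: x % 1.0 can return 1.0 for tiny negatives
    return PlacedCell(cell=cell, frac=frac, weights=model.weights.copy(),
                      rotation=float(rotation))
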