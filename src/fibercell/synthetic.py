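"""Parametric toy filaments and synthetic observed-intensity tables.

Two families of toy thick filaments are generated, mirroring the
symmetries of the muscles the pipeline targets:

* a vertebrate-like filament — myosin head pairs on a 3-start helix with
  9 head pairs per turn (40° azimuthal step per 143.2 Å crown), C3
  rotational symmetry, true repeat 429.6 Å, and a periodic perturbation
  of the three crowns in the repeat so the structure is not perfectly
  helical (this populates the otherwise forbidden l = 1, 2 layer lines);
* an insect-like filament — C4, 8 crowns per 1160 Å repeat at 145 Å
  spacing with a 33.75° twist per crown, giving 32 equally spaced head
  azimuths in axial projection.

Each myosin molecule carries a pair of heads modelled as isotropic
Gaussian blobs of point scatterers, in one of two configurations:
``compact_pair`` (both heads packed tangentially against the backbone,
an interacting-head-motif-like arrangement) or ``radial_extended`` (one
head near the backbone, the other projecting radially outward).  The
backbone is a uniform cylinder of point scatterers giving a strong
equator.  All randomness flows from the single seed in the spec.

Synthetic observed tables are pipeline-computed multiplet intensities
with optional multiplicative Gaussian noise and matching standard
deviations, standing in for background-stripped fiber-pattern intensity
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from fibercell.diffraction import (
    DisorderModel,
    apply_lateral_disorder,
    collapse_multiplets,
    enumerate_reflections,
    structure_factors,
)
from fibercell.fitting import ObservedPeak
from fibercell.lattice import FilamentModel, UnitCell, place_filament

__all__ = [
    "HelixSpec", "NoiseSpec", "vertebrate_spec", "insect_spec",
    "build_toy_filament", "head_anchor_azimuths", "make_synthetic_observed",
]


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of a toy thick filament.

    rise is the axial crown spacing (Å); the azimuthal twist per crown
    along one strand is 360/units_per_turn degrees.  crown_perturbations
    lists one (Δz Å, Δφ degrees) pair per crown in the repeat.
    head_radius is the blob-centre radius of the outward head in
    ``radial_extended`` mode.
    """

    n_start: int
    units_per_turn: float
    rise: float
    rot_symmetry: int
    repeat: float
    crown_perturbations: tuple[tuple[float, float], ...]
    head_mode: str = "compact_pair"
    head_radius: float = 160.0
    blob_n: int = 40
    blob_sigma: float = 20.0
    seed: int = 0
    backbone_radius: float = 65.0
    backbone_n: int = 200  # points per C_n wedge
    label: str = "toy"

    def __post_init__(self) -> None:
        if self.n_start < 1:
            raise ValueError("n_start must be >= 1")
        if self.rise <= 0 or self.repeat <= 0:
            raise ValueError("rise and repeat must be positive")
        if self.head_mode not in ("compact_pair", "radial_extended"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if len(self.crown_perturbations) != self.crowns_per_repeat:
            raise ValueError(
                f"{len(self.crown_perturbations)} crown perturbations given "
                f"but the repeat holds {self.crowns_per_repeat} crowns")

    @property
    def crowns_per_repeat(self) -> int:
        n = self.repeat / self.rise
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"repeat {self.repeat} is not an integer number of crowns "
                f"at rise {self.rise}")
        return int(round(n))

    @property
    def twist(self) -> float:
        """Azimuthal step per crown along one strand, degrees."""
        return 360.0 / self.units_per_turn


def vertebrate_spec(head_mode: str = "compact_pair", seed: int = 0,
                    **overrides) -> HelixSpec:
    """Default vertebrate-like toy: 3-start, 9 per turn, C3, 429.6 Å repeat.

    The three crowns carry a periodic perturbation — defaults
    (0, 0), (+8 Å, −5°), (−8 Å, +5°) — so l = 1, 2 layer lines are
    visibly populated, as in real vertebrate filaments.
    """
    spec = HelixSpec(
        n_start=3, units_per_turn=9.0, rise=143.2, rot_symmetry=3,
        repeat=429.6,
        crown_perturbations=((0.0, 0.0), (8.0, -5.0), (-8.0, 5.0)),
        head_mode=head_mode, head_radius=160.0, seed=seed,
        backbone_radius=65.0, label=f"vertebrate-{head_mode}",
    )
    return replace(spec, **overrides) if overrides else spec


def insect_spec(head_mode: str = "compact_pair", seed: int = 0,
                **overrides) -> HelixSpec:
    """Default insect-like toy: C4, 8 crowns per 1160 Å repeat, 33.75°/crown.

    The twist makes the 8 crowns × 4 molecules project onto 32 equally
    spaced azimuths (11.25° apart) down the filament axis.
    """
    spec = HelixSpec(
        n_start=4, units_per_turn=360.0 / 33.75, rise=145.0, rot_symmetry=4,
        repeat=1160.0,
        crown_perturbations=tuple((0.0, 0.0) for _ in range(8)),
        head_mode=head_mode, head_radius=170.0, seed=seed,
        backbone_radius=80.0, label=f"insect-{head_mode}",
    )
    return replace(spec, **overrides) if overrides else spec


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def head_anchor_azimuths(spec: HelixSpec) -> np.ndarray:
    """Distinct projected head-pair azimuths (degrees, sorted, mod 360).

    The vertebrate default gives 9 (approximate 9-fold projection), the
    insect default 32.
    """
    az = []
    for j in range(spec.crowns_per_repeat):
        phi = j * spec.twist + spec.crown_perturbations[j][1]
        for m in range(spec.rot_symmetry):
            az.append((phi + m * 360.0 / spec.rot_symmetry) % 360.0)
    return np.unique(np.round(az, 6))


def build_toy_filament(spec: HelixSpec) -> FilamentModel:
    """Build the point-scatterer toy filament described by ``spec``.

    One strand of crowns is generated (head-pair blobs plus a backbone
    wedge) and replicated exactly by the C_n rotations, so the declared
    rotational symmetry holds by construction.  Head blobs have unit
    point weights; total head weight is identical between the two head
    modes, making model discrimination purely a matter of shape.
    """
    rng = np.random.default_rng(spec.seed)
    anchor_r = spec.backbone_radius + 25.0
    pair_half_angle = np.degrees(22.0 / anchor_r)  # ~22 Å tangential offset

    wedge_pos = []
    for j in range(spec.crowns_per_repeat):
        dz, dphi = spec.crown_perturbations[j]
        z = (j * spec.rise + dz) % spec.repeat
        phi = j * spec.twist + dphi
        if spec.head_mode == "compact_pair":
            centres = [
                (anchor_r, phi - pair_half_angle, z),
                (anchor_r, phi + pair_half_angle, z),
            ]
        else:  # radial_extended
            centres = [
                (anchor_r, phi, z),
                (spec.head_radius, phi, z),
            ]
        for r, ang, zc in centres:
            c = np.array([r * np.cos(np.radians(ang)),
                          r * np.sin(np.radians(ang)), zc])
            wedge_pos.append(c + rng.normal(0.0, spec.blob_sigma,
                                            size=(spec.blob_n, 3)))
    # backbone: uniform cylinder sampled in one C_n wedge
    nb = spec.backbone_n
    bb_r = spec.backbone_radius * np.sqrt(rng.uniform(size=nb))
    bb_t = np.radians(rng.uniform(0.0, 360.0 / spec.rot_symmetry, size=nb))
    bb_z = rng.uniform(0.0, spec.repeat, size=nb)
    wedge_pos.append(np.column_stack(
        [bb_r * np.cos(bb_t), bb_r * np.sin(bb_t), bb_z]))
    wedge = np.concatenate(wedge_pos, axis=0)

    parts = [wedge @ _rot_z(m * 360.0 / spec.rot_symmetry).T
             for m in range(spec.rot_symmetry)]
    positions = np.concatenate(parts, axis=0)
    weights = np.ones(positions.shape[0])
    return FilamentModel(positions, weights,
                         symmetry_order=spec.rot_symmetry,
                         axial_repeat=spec.repeat, label=spec.label)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative intensity noise for synthetic observed tables.

    I_obs = max(I·(1+ε), 0) + floor with ε ~ N(0, rel_sigma), and
    Φ = rel_sigma·I + floor.
    """

    rel_sigma: float = 0.0
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sigma < 0:
            raise ValueError("rel_sigma must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")


def make_synthetic_observed(
    cell: UnitCell,
    model: FilamentModel,
    rotation: float,
    disorder: DisorderModel | None,
    noise: NoiseSpec,
    l_set,
    d_min: float = 60.0,
) -> list[ObservedPeak]:
    """Pipeline-computed multiplet intensities perturbed into an
    observed-peak table.

    Keys are the exact integer multiplet classes s, so fitting the
    generating model at the generating rotation with zero noise returns
    R = 0 identically.  Tables are reproducible from ``noise.seed``.
    """
    hkl = enumerate_reflections(cell, d_min, l_set)
    placed = place_filament(cell, model, rotation)
    table = collapse_multiplets(structure_factors(placed, hkl))
    if disorder is not None:
        table = apply_lateral_disorder(table, disorder)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.rel_sigma, size=len(table)) \
        if noise.rel_sigma > 0 else np.zeros(len(table))
    I_obs = np.clip(table.intensity * (1.0 + eps), 0.0, None) + noise.floor
    phi = noise.rel_sigma * table.intensity + noise.floor
    peaks = []
    for i in range(len(table)):
        peaks.append(ObservedPeak(
            l=int(table.l[i]), key=int(table.s[i]), I_obs=float(I_obs[i]),
            phi=float(phi[i]) if phi[i] > 0 else None))
    return peaks
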