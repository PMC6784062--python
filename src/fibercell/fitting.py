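"""Intensity scaling, R-factors, and rotation/disorder searches.

Calculated multiplet intensities are scaled to the observed total
intensity, k = ΣI_obs / ΣI_calc, and scored with either the unweighted
R-factor

    R = Σ(I_obs − I_calc)² / Σ I_obs²

or its sigma-weighted form

    R = Σ[(I_obs − I_calc)²/Φ²] / Σ[I_obs²/Φ²]

where Φ is the standard deviation of each observed intensity.  With
constant Φ the two are identical.  The azimuthal orientation of the
filament in the lattice is unknown a priori, so the model is rotated
systematically about the c axis and R evaluated at each step; the trace is
periodic (60° for a 3-fold filament in the hexagonal lattice, 30° for a
4-fold one).  An optional lateral-disorder parameter sigma can be searched
on a grid at fixed rotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from fibercell.diffraction import (
    DisorderModel,
    MultipletTable,
    apply_lateral_disorder,
    collapse_multiplets,
    enumerate_reflections,
    structure_factors,
)
from fibercell.lattice import FilamentModel, UnitCell, place_filament

logger = logging.getLogger(__name__)

__all__ = [
    "ObservedPeak", "MatchedPeaks", "FitResult", "match_peaks", "scale_calc",
    "r_factor", "r_factor_weighted", "rotation_search", "disorder_search",
    "read_observed_table", "write_observed_table",
]


@dataclass(frozen=True)
class ObservedPeak:
    """One observed fiber-pattern spot.

    ``key`` identifies the multiplet radius class: either the exact
    integer s = h²+hk+k², or a float equatorial radius in Å⁻¹ matched to
    the nearest calculated multiplet.  ``phi`` is the standard deviation
    of the observed intensity (same arbitrary units), optional.
    """

    l: int
    key: int | float
    I_obs: float
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.I_obs < 0:
            raise ValueError(f"I_obs must be >= 0, got {self.I_obs}")
        if self.phi is not None and self.phi <= 0:
            raise ValueError(f"phi must be > 0 when given, got {self.phi}")


@dataclass
class MatchedPeaks:
    """Observed/calculated intensity pairs after multiplet matching."""

    l: np.ndarray
    s: np.ndarray
    I_obs: np.ndarray
    I_calc: np.ndarray
    phi: np.ndarray | None
    unmatched: list[ObservedPeak]

    def __len__(self) -> int:
        return len(self.I_obs)


@dataclass
class FitResult:
    """Outcome of a rotation search: R-factor trace and best fit."""

    angles: np.ndarray
    r_trace: np.ndarray
    best_angle: float
    best_r: float
    scale: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.r_trace = np.asarray(self.r_trace, dtype=float)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# best_angle_deg\t{self.best_angle:.6g}\n")
            fh.write(f"# best_R\t{self.best_r:.10g}\n")
            fh.write(f"# scale\t{self.scale:.10g}\n")
            if self.sigma is not None:
                fh.write(f"# sigma_A\t{self.sigma:.6g}\n")
            fh.write("angle_deg\tR\n")
            for a, r in zip(self.angles, self.r_trace):
                fh.write(f"{a:.6g}\t{r:.10g}\n")


def match_peaks(
    observed: list[ObservedPeak],
    table: MultipletTable,
    r_tolerance: float = 1e-4,
) -> MatchedPeaks:
    """Pair observed peaks with calculated multiplet rows.

    Integer keys join exactly on (l, s); float keys match the nearest
    calculated r_perp on the same layer line within ``r_tolerance`` Å⁻¹.
    Two calculated rows inside the tolerance make the match ambiguous and
    raise.  Observed peaks with no counterpart are reported, not scored.
    """
    by_ls = {(int(l), int(s)): i for i, (l, s) in enumerate(zip(table.l, table.s))}
    r_calc = table.r_perp
    ls, ss, io, ic, ph = [], [], [], [], []
    unmatched: list[ObservedPeak] = []
    any_phi = False
    for pk in observed:
        idx = None
        if isinstance(pk.key, (int, np.integer)):
            idx = by_ls.get((pk.l, int(pk.key)))
        else:
            on_l = np.flatnonzero(table.l == pk.l)
            if on_l.size:
                dr = np.abs(r_calc[on_l] - float(pk.key))
                near = on_l[dr <= r_tolerance]
                if near.size > 1:
                    cands = [(int(table.l[i]), int(table.s[i])) for i in near]
                    raise ValueError(
                        f"ambiguous radius match for observed peak l={pk.l}, "
                        f"r={pk.key}: candidates {cands}")
                if near.size == 1:
                    idx = int(near[0])
        if idx is None:
            unmatched.append(pk)
            logger.info("observed peak l=%s key=%s has no calculated "
                        "multiplet; dropped", pk.l, pk.key)
            continue
        ls.append(table.l[idx]); ss.append(table.s[idx])
        io.append(pk.I_obs); ic.append(table.intensity[idx])
        ph.append(pk.phi if pk.phi is not None else np.nan)
        any_phi = any_phi or pk.phi is not None
    if len(io) == 1:
        warnings.warn("only one observed peak matched: R is 0 after "
                      "scaling and non-informative", stacklevel=2)
    phi = np.array(ph) if any_phi else None
    return MatchedPeaks(np.array(ls, dtype=int), np.array(ss, dtype=int),
                        np.array(io), np.array(ic), phi, unmatched)


def scale_calc(matched: MatchedPeaks, method: str = "total") -> tuple[float, MatchedPeaks]:
    """Scale calculated intensities onto the observed scale.

    ``total`` (default) matches total intensity, k = ΣI_obs/ΣI_calc, as a
    fiber pattern is normally put on scale; ``lsq`` minimizes the squared
    residual, k = ΣI_obs·I_calc / ΣI_calc².  Returns the scale and a
    rescaled copy of the pairing.
    """
    if len(matched) == 0:
        raise ValueError("no matched peaks to scale")
    tot_calc = matched.I_calc.sum()
    if tot_calc <= 0:
        raise ValueError("calculated intensities sum to zero; cannot scale")
    if method == "total":
        k = matched.I_obs.sum() / tot_calc
    elif method == "lsq":
        denom = (matched.I_calc ** 2).sum()
        if denom <= 0:
            raise ValueError("calculated intensities are all zero")
        k = (matched.I_obs * matched.I_calc).sum() / denom
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    scaled = MatchedPeaks(matched.l, matched.s, matched.I_obs,
                          k * matched.I_calc, matched.phi, matched.unmatched)
    return float(k), scaled


def r_factor(matched: MatchedPeaks) -> float:
    """Unweighted intensity R-factor Σ(I_obs − I_calc)²/ΣI_obs²."""
    if len(matched) == 0:
        raise ValueError("empty pairing")
    denom = (matched.I_obs ** 2).sum()
    if denom <= 0:
        raise ValueError("observed intensities are all zero")
    return float(((matched.I_obs - matched.I_calc) ** 2).sum() / denom)


def r_factor_weighted(matched: MatchedPeaks) -> float:
    """Sigma-weighted R-factor Σ[(I_obs−I_calc)²/Φ²]/Σ[I_obs²/Φ²]."""
    if len(matched) == 0:
        raise ValueError("empty pairing")
    if matched.phi is None or np.any(~np.isfinite(matched.phi)):
        raise ValueError(
            "observed standard deviations Φ are missing for some peaks; "
            "use the unweighted r_factor instead")
    w = 1.0 / matched.phi ** 2
    denom = (w * matched.I_obs ** 2).sum()
    if denom <= 0:
        raise ValueError("observed intensities are all zero")
    return float((w * (matched.I_obs - matched.I_calc) ** 2).sum() / denom)


def _score(matched: MatchedPeaks, weighted: bool, scale_method: str) -> tuple[float, float]:
    k, scaled = scale_calc(matched, scale_method)
    r = r_factor_weighted(scaled) if weighted else r_factor(scaled)
    return r, k


def rotation_search(
    cell: UnitCell,
    model: FilamentModel,
    observed: list[ObservedPeak],
    start: float = 0.0,
    stop: float = 60.0,
    step: float = 1.0,
    weighted: bool = False,
    disorder: DisorderModel | None = None,
    l_set=None,
    d_min: float = 60.0,
    r_max: float | None = None,
    scale_method: str = "total",
) -> FitResult:
    """Grid search of the filament azimuth against observed intensities.

    At each rotation the model is placed in the cell, reflections on the
    configured layer lines are computed to d ≥ ``d_min``, collapsed into
    multiplets, optionally disorder-attenuated, scaled to the observed
    total, and scored.  Ties in R go to the smallest angle.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if stop <= start:
        raise ValueError("stop must exceed start")
    if l_set is None:
        l_set = sorted({pk.l for pk in observed})
    hkl = enumerate_reflections(cell, d_min, l_set, r_max=r_max)
    angles = np.arange(start, stop + 0.5 * step, step)
    r_trace = np.empty_like(angles)
    scales = np.empty_like(angles)
    for i, ang in enumerate(angles):
        placed = place_filament(cell, model, float(ang))
        table = collapse_multiplets(structure_factors(placed, hkl))
        if disorder is not None:
            table = apply_lateral_disorder(table, disorder)
        matched = match_peaks(observed, table)
        r_trace[i], scales[i] = _score(matched, weighted, scale_method)
    best = int(np.argmin(r_trace))  # argmin takes the first, smallest angle
    return FitResult(angles=angles, r_trace=r_trace,
                     best_angle=float(angles[best]),
                     best_r=float(r_trace[best]), scale=float(scales[best]),
                     sigma=disorder.sigma if disorder is not None else None)


def disorder_search(
    cell: UnitCell,
    model: FilamentModel,
    observed: list[ObservedPeak],
    rotation: float,
    sigma_grid,
    weighted: bool = False,
    l_set=None,
    d_min: float = 60.0,
    scale_method: str = "total",
) -> tuple[float, float]:
    """Grid search of the lateral-disorder sigma at a fixed rotation.

    Intensities are recomputed once; each sigma attenuates and rescales
    them before scoring.  Returns (best sigma in Å, best R); ties go to
    the smallest sigma.
    """
    sigma_grid = np.asarray(list(sigma_grid), dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma_grid is empty")
    if np.any(sigma_grid < 0):
        raise ValueError("sigma values must be >= 0")
    if l_set is None:
        l_set = sorted({pk.l for pk in observed})
    hkl = enumerate_reflections(cell, d_min, l_set)
    placed = place_filament(cell, model, rotation)
    table = collapse_multiplets(structure_factors(placed, hkl))
    best_sigma, best_r = None, np.inf
    for sigma in np.sort(sigma_grid):
        att = apply_lateral_disorder(table, DisorderModel(float(sigma)))
        matched = match_peaks(observed, att)
        r, _ = _score(matched, weighted, scale_method)
        if r < best_r:
            best_sigma, best_r = float(sigma), float(r)
    return best_sigma, best_r


def write_observed_table(observed: list[ObservedPeak], path) -> None:
    """Write observed peaks as tab-separated text (l, s_or_radius, I, phi)."""
    with open(path, "w") as fh:
        fh.write("# observed fiber peaks: l\ts_or_radius\tI_obs\tphi\n")
        for pk in observed:
            phi = f"{pk.phi:.10g}" if pk.phi is not None else "NA"
            fh.write(f"{pk.l}\t{pk.key}\t{pk.I_obs:.10g}\t{phi}\n")


def read_observed_table(path) -> list[ObservedPeak]:
    """Read an observed-peak table written by :func:`write_observed_table`.

    The key column is taken as an integer multiplet class s when it parses
    as an integer, otherwise as an equatorial radius in Å⁻¹.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            l = int(parts[0])
            key_txt = parts[1]
            try:
                key: int | float = int(key_txt)
            except ValueError:
                key = float(key_txt)
            I_obs = float(parts[2])
            phi = None
            if len(parts) > 3 and parts[3] not in ("", "NA", "nan"):
                phi = float(parts[3])
            peaks.append(ObservedPeak(l=l, key=key, I_obs=I_obs, phi=phi))
    if not peaks:
        raise ValueError(f"no observed peaks in {path}")
    return peaks
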