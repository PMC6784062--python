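"""Rendering of simulated 2D fiber-pattern images.

Each multiplet (or observed peak) is drawn as a Gaussian spot at
(±R⊥, ±l/c) in reciprocal space and the four quadrants are mirrored, as
in a real fiber pattern.  Images are a reporting convenience only —
fitting consumes intensity tables, never pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from fibercell.diffraction import MultipletTable
from fibercell.fitting import ObservedPeak
from fibercell.lattice import UnitCell

__all__ = ["PatternImage", "render_pattern", "save_png"]


@dataclass
class PatternImage:
    """A rendered fiber pattern: non-negative pixels with four-quadrant
    mirror symmetry, calibrated in Å⁻¹ per pixel, normalized to total 1."""

    pixels: np.ndarray
    calibration: tuple[float, float]
    spread: float

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("pattern intensities must be >= 0")


def _peaks_from(table, cell: UnitCell | None):
    if isinstance(table, MultipletTable):
        return table.r_perp, table.l / table.cell.c, table.intensity
    peaks: list[ObservedPeak] = list(table)
    if not peaks:
        raise ValueError("empty table")
    if cell is None:
        raise ValueError("rendering observed peaks requires the unit cell")
    r = np.array([
        float(pk.key) if not isinstance(pk.key, (int, np.integer))
        else np.sqrt(4.0 * int(pk.key) / (3.0 * cell.a ** 2))
        for pk in peaks])
    zeta = np.array([pk.l / cell.c for pk in peaks])
    I = np.array([pk.I_obs for pk in peaks])
    return r, zeta, I


def render_pattern(
    table,
    size: int = 256,
    r_max: float | None = None,
    spread: float = 2.0,
    cell: UnitCell | None = None,
) -> PatternImage:
    """Render a multiplet table (or observed peaks) into a PatternImage.

    ``size`` is the full image edge in pixels, ``r_max`` the reciprocal
    extent of a half-axis (defaults to 1.1× the largest peak coordinate)
    and ``spread`` the Gaussian spot sigma in pixels.
    """
    r, zeta, I = _peaks_from(table, cell)
    if len(I) == 0:
        raise ValueError("empty table")
    if r_max is None:
        r_max = 1.1 * max(float(np.max(r)), float(np.max(np.abs(zeta))), 1e-6)
    half = size // 2
    calib = (r_max / half, r_max / half)
    # build the upper-right quadrant, then mirror
    quad = np.zeros((half, half))
    yy, xx = np.mgrid[0:half, 0:half]
    for ri, zi, Ii in zip(r, zeta, I):
        if Ii <= 0:
            continue
        px = ri / calib[0]
        py = zi / calib[1]
        quad += Ii * np.exp(-((xx - px) ** 2 + (yy - py) ** 2)
                            / (2.0 * spread ** 2))
    top = np.concatenate([quad[:, ::-1], quad], axis=1)
    img = np.concatenate([top[::-1, :], top], axis=0)
    total = img.sum()
    if total > 0:
        img = img / total
    return PatternImage(pixels=img, calibration=calib, spread=spread)


def save_png(image: PatternImage, path, gamma: float = 0.4) -> None:
    """Save a pattern image as 8-bit PNG with a display gamma."""
    px = image.pixels
    peak = px.max() if px.max() > 0 else 1.0
    scaled = (255.0 * (px / peak) ** gamma).astype(np.uint8)
    Image.fromarray(scaled[::-1, :], mode="L").save(str(path))
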