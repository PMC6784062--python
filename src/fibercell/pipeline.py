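"""End-to-end pipeline driver: config in, report bundle out.

A single declarative YAML config names the unit cell, the filament model
source (toy spec, PDB coordinates, or CCP4 map), the observed-intensity
table, and the search settings.  ``run_pipeline`` executes place →
diffract → collapse → (disorder) → scale → score over the rotation grid
and writes the R-factor trace, the best-fit multiplet table, rendered
pattern images, a plain-text run log, and a machine-readable manifest.

Tabular outputs are deterministic: re-running the same config with the
same seeds is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

import fibercell
from fibercell.diffraction import (
    DisorderModel, apply_lateral_disorder, collapse_multiplets,
    enumerate_reflections, structure_factors,
)
from fibercell.fitting import read_observed_table, rotation_search
from fibercell.lattice import make_unit_cell, place_filament
from fibercell.model_io import grid_to_scatterers, read_atomic_model, read_density_map
from fibercell.lattice import FilamentModel
from fibercell.render import render_pattern, save_png
from fibercell.synthetic import build_toy_filament, insect_spec, vertebrate_spec

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "model_from_config"]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def model_from_config(mcfg: dict) -> FilamentModel:
    kind = mcfg.get("kind", "toy_vertebrate")
    if kind in ("toy_vertebrate", "toy_insect"):
        factory = vertebrate_spec if kind == "toy_vertebrate" else insect_spec
        spec = factory(head_mode=mcfg.get("head_mode", "compact_pair"),
                       seed=int(mcfg.get("seed", 0)))
        return build_toy_filament(spec)
    if kind == "pdb":
        return read_atomic_model(
            mcfg["path"], symmetry_order=int(mcfg.get("symmetry_order", 1)),
            axial_repeat=mcfg.get("axial_repeat"))
    if kind == "map":
        grid = read_density_map(mcfg["path"])
        scat = grid_to_scatterers(grid, threshold=float(mcfg.get("threshold", 0.0)))
        return FilamentModel.from_scatterers(
            scat, symmetry_order=int(mcfg.get("symmetry_order", 1)),
            axial_repeat=float(mcfg.get("axial_repeat", 1.0)),
            label=str(mcfg["path"]))
    raise ValueError(f"unknown model kind {kind!r}")


def run_pipeline(config, outdir) -> dict:
    """Run the full fit described by ``config`` (path or dict) into ``outdir``.

    Returns the manifest dictionary.  Any stage failure aborts with a
    stage-named diagnostic.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fibercell")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _run(cfg: dict, outdir: Path) -> dict:
    ccfg = cfg["cell"]
    cell = _stage("cell")(make_unit_cell)(
        float(ccfg["a"]), float(ccfg.get("b", ccfg["a"])),
        float(ccfg["c"]), float(ccfg.get("gamma", 120.0)))
    logger.info("unit cell a=b=%g A, c=%g A", cell.a, cell.c)

    model = _stage("model")(model_from_config)(cfg.get("model", {}))
    logger.info("model %r: %d scatterers, C%d", model.label, len(model),
                model.symmetry_order)

    obs_path = cfg["observed"]
    if not Path(obs_path).exists():
        raise FileNotFoundError(f"observed intensity table not found: {obs_path}")
    observed = _stage("observed")(read_observed_table)(obs_path)

    scfg = cfg.get("search", {})
    d_min = float(scfg.get("d_min", 60.0))
    exclude_l = set(int(x) for x in scfg.get("exclude_l", []))
    l_set = sorted({pk.l for pk in observed} - exclude_l)
    for l in sorted(exclude_l):
        logger.info("layer line l=%d excluded from the R-factor calculation", l)
    observed = [pk for pk in observed if pk.l in l_set]

    disorder = None
    if "sigma" in scfg:
        disorder = DisorderModel(float(scfg["sigma"]))
    fit = _stage("fit")(rotation_search)(
        cell, model, observed,
        start=float(scfg.get("start", 0.0)), stop=float(scfg.get("stop", 60.0)),
        step=float(scfg.get("step", 1.0)),
        weighted=bool(scfg.get("weighted", False)),
        disorder=disorder, l_set=l_set, d_min=d_min)
    logger.info("best rotation %.4g deg, R = %.6g, scale = %.6g",
                fit.best_angle, fit.best_r, fit.scale)

    trace_path = outdir / "trace.tsv"
    fit.to_tsv(trace_path)

    placed = place_filament(cell, model, fit.best_angle)
    hkl = enumerate_reflections(cell, d_min, l_set)
    table = collapse_multiplets(structure_factors(placed, hkl))
    if disorder is not None:
        table = apply_lateral_disorder(table, disorder)
    table = table.with_intensity(table.intensity * fit.scale)
    table_path = outdir / "best_multiplets.tsv"
    table.to_tsv(table_path)

    calc_png = outdir / "pattern_calc.png"
    obs_png = outdir / "pattern_obs.png"
    r_extent = 1.1 * max(float(np.max(table.r_perp)),
                         float(np.max(table.l)) / cell.c, 1e-6)
    save_png(render_pattern(table, r_max=r_extent), calc_png)
    save_png(render_pattern(observed, r_max=r_extent, cell=cell), obs_png)

    manifest = {
        "fibercell_version": fibercell.__version__,
        "cell": {"a": cell.a, "b": cell.b, "c": cell.c, "gamma": cell.gamma},
        "model": cfg.get("model", {}),
        "observed": str(obs_path),
        "search": {"start": float(scfg.get("start", 0.0)),
                   "stop": float(scfg.get("stop", 60.0)),
                   "step": float(scfg.get("step", 1.0)),
                   "weighted": bool(scfg.get("weighted", False)),
                   "d_min": d_min,
                   "exclude_l": sorted(exclude_l),
                   "sigma": scfg.get("sigma")},
        "layer_lines": l_set,
        "best_angle_deg": fit.best_angle,
        "best_R": fit.best_r,
        "scale": fit.scale,
        "outputs": {"trace": trace_path.name, "multiplets": table_path.name,
                    "pattern_calc": calc_png.name, "pattern_obs": obs_png.name,
                    "log": "run.log"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
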