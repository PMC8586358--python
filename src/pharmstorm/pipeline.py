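"""Config-driven end-to-end runs: simulate -> quantify -> spatial stats -> report.

A run is described by a plain-text YAML config::

    seed: 1
    outdir: runs/demo
    stages:
      - stage: simulate
        field_um: 5.0
        mask_kind: disks
        n_structures: 4
        radius_nm: 300
        density_on: 150
        density_off: 30
      - stage: density
      - stage: nnd
      - stage: structure_ratio
      - stage: hull_distance
      - stage: stoichiometry
      - stage: fit_binding
        kd: 123
        bmax: 100

Each stage's random stream is derived from the global seed by hashing the
stage name, so adding or removing a stage never perturbs another stage's
stream.  Every output file is listed in ``manifest.json`` with a sha256
checksum; re-running an identical config and seed reproduces the
checksums.  A stage failure aborts the run with the stage name, keeping
partial outputs flagged in the manifest.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import io as locio
from . import simulate as sim
from . import spatial, stoichiometry
from ._rng import as_generator, stage_seed
from .binding import BindingSeries, fit_one_site, fit_sigmoid
from .core import PolygonROI, ValidationError, union_masks
from .density import background_correct, density as compute_density


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list[dict]
    log_level: str = "info"

    @classmethod
    def from_dict(cls, cfg: dict, base_dir: "Path | None" = None) -> "RunConfig":
        if "stages" not in cfg or not isinstance(cfg["stages"], list):
            raise ValidationError("config must contain a 'stages' list")
        outdir = Path(cfg.get("outdir", "pharmstorm_run"))
        if base_dir is not None and not outdir.is_absolute():
            outdir = Path(base_dir) / outdir
        return cls(
            seed=int(cfg.get("seed", 0)),
            outdir=outdir,
            stages=[dict(s) for s in cfg["stages"]],
            log_level=str(cfg.get("log_level", "info")),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _Context:
    """Artifacts shared across stages within one run."""

    outdir: Path
    scene: "sim.Scene | None" = None
    pharmaco: Any = None
    immuno: Any = None
    summaries: dict = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def _write_json(ctx: _Context, name: str, payload: dict) -> None:
    path = ctx.outdir / name
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonable))
    ctx.files.append(path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


def _stage_simulate(ctx: _Context, params: dict, rng) -> dict:
    field_nm = float(params.get("field_um", 5.0)) * 1000.0
    pixel = float(params.get("pixel_nm", 10.0))
    npx = int(round(field_nm / pixel))
    roi = PolygonROI.rectangle(0, 0, field_nm, field_nm)
    masks = sim.generate_structure_masks(
        params.get("mask_kind", "disks"),
        int(params.get("n_structures", 4)),
        {
            "radius_nm": params.get("radius_nm", 300.0),
            "r_inner_nm": params.get("r_inner_nm", 200.0),
            "r_outer_nm": params.get("r_outer_nm", 400.0),
            "length_nm": params.get("length_nm", 3000.0),
            "width_nm": params.get("width_nm", 200.0),
        },
        shape=(npx, npx),
        pixel_size=pixel,
        seed=rng,
    )
    scene = sim.place_molecules(
        masks, roi, float(params.get("density_on", 100.0)), float(params.get("density_off", 100.0)), seed=rng
    )
    model_name = params.get("blink_model", "pharmacoprobe")
    factory = sim.antibody_blink_model if model_name == "antibody" else sim.pharmacoprobe_blink_model
    model = factory(sigma_xy=float(params.get("sigma_xy", 9.42)))
    table = sim.render_blinks(
        scene, model, background_rate=float(params.get("background_rate", 0.0)), seed=rng
    )
    ctx.scene = scene
    ctx.pharmaco = table
    ctx.files.append(locio.write_molecule_list(table, ctx.outdir / "pharmaco.csv"))
    truth_path = ctx.outdir / "ground_truth.csv"
    scene.molecules.to_csv(truth_path, index=False)
    ctx.files.append(truth_path)
    for i, m in enumerate(masks):
        p = locio.write_mask(m, ctx.outdir / f"mask_{i}.tif")
        ctx.files.extend([p, p.with_suffix(".json")])
    ctx.files.append(locio.write_roi(roi, ctx.outdir / "roi.txt"))
    if params.get("immuno", True):
        immuno_scene = sim.place_molecules(
            masks, roi, float(params.get("immuno_density_on", 300.0)), 0.0, seed=rng
        )
        immuno = sim.render_blinks(immuno_scene, sim.antibody_blink_model(), seed=rng, channel="immuno")
        ctx.immuno = immuno
        ctx.files.append(locio.write_molecule_list(immuno, ctx.outdir / "immuno.csv"))
    return {"n_molecules": len(scene), "n_lps": len(table), "enrichment": scene.enrichment}


def _require_table(ctx: _Context, params: dict):
    if "input" in params:
        return locio.read_molecule_list(params["input"])
    if ctx.pharmaco is None:
        raise ValidationError("no molecule list available; run simulate first or give 'input'")
    return ctx.pharmaco


def _stage_density(ctx: _Context, params: dict, rng) -> dict:
    table = _require_table(ctx, params)
    roi = ctx.scene.roi if ctx.scene is not None else locio.read_roi(params["roi"])
    res = compute_density(table, roi)
    out = {
        "count": res.count,
        "area_um2": res.area_um2,
        "density_per_um2": res.density_per_um2,
    }
    if "background_input" in params:
        bg = compute_density(locio.read_molecule_list(params["background_input"]), roi)
        res = background_correct(res, bg)
        out.update(
            background_density_per_um2=res.background_density_per_um2,
            corrected_density_per_um2=res.corrected_density_per_um2,
            clamped=res.clamped,
        )
    _write_json(ctx, "density.json", out)
    return out


def _stage_nnd(ctx: _Context, params: dict, rng) -> dict:
    table = _require_table(ctx, params)
    roi = ctx.scene.roi if ctx.scene is not None else locio.read_roi(params["roi"])
    res = spatial.nnd_vs_csr(table, roi, seed=rng)
    cdf = pd.DataFrame(
        {
            "distance_nm": np.sort(res.distances),
            "ecdf_observed": np.arange(1, len(res.distances) + 1) / len(res.distances),
        }
    )
    path = ctx.outdir / "nnd_cdf.csv"
    cdf.to_csv(path, index=False)
    ctx.files.append(path)
    out = {
        "n": len(res.distances),
        "median_nnd_nm": float(np.median(res.distances)),
        "ks_statistic": res.ks_statistic,
        "p_value": res.p_value,
    }
    _write_json(ctx, "nnd.json", out)
    return out


def _stage_structure_ratio(ctx: _Context, params: dict, rng) -> dict:
    table = _require_table(ctx, params)
    if ctx.scene is None:
        raise ValidationError("structure_ratio requires a simulated scene in this pipeline")
    mask = union_masks(ctx.scene.masks)
    cfg = spatial.StructureAssocConfig(n_dilations=int(params.get("n_dilations", 50)))
    res = spatial.structure_density_ratio(table, mask, cfg, seed=rng)
    out = {
        "ratio": res.ratio,
        "randomized_ratio": res.randomized_ratio,
        "on_structure_density": res.on_structure_density,
        "neighborhood_density": res.neighborhood_density,
    }
    _write_json(ctx, "structure_ratio.json", out)
    return out


def _stage_hull_distance(ctx: _Context, params: dict, rng) -> dict:
    table = _require_table(ctx, params)
    if ctx.immuno is None or ctx.scene is None:
        raise ValidationError("hull_distance requires simulated immuno channel")
    rois = []
    for m in ctx.scene.masks:
        rows, cols = np.nonzero(m.pixels)
        x0, y0 = m.origin
        pad = 2 * m.pixel_size
        rois.append(
            PolygonROI.rectangle(
                x0 + cols.min() * m.pixel_size - pad,
                y0 + rows.min() * m.pixel_size - pad,
                x0 + (cols.max() + 1) * m.pixel_size + pad,
                y0 + (rows.max() + 1) * m.pixel_size + pad,
            )
        )
    fit = spatial.fit_convex_hulls(ctx.immuno, rois)
    res = spatial.hull_surface_distances(
        table, fit.hulls, cutoff=float(params.get("cutoff_nm", 1000.0)),
        null_region=ctx.scene.roi, seed=rng,
    )
    cdf = pd.DataFrame({"distance_nm": np.sort(res.distances)})
    path = ctx.outdir / "hull_distances.csv"
    cdf.to_csv(path, index=False)
    ctx.files.append(path)
    out = {
        "n_hulls": len(fit.hulls),
        "n_excluded_boutons": len(fit.excluded),
        "n_within_cutoff": len(res.distances),
        "ks_statistic": res.ks_statistic,
        "p_value": res.p_value,
    }
    _write_json(ctx, "hull_distance.json", out)
    return out


def _stage_stoichiometry(ctx: _Context, params: dict, rng) -> dict:
    table = _require_table(ctx, params)
    cfg = stoichiometry.ClusteringConfig(radius=float(params.get("radius_nm", 30.0)))
    clusters = stoichiometry.cluster_blinks(table, cfg)
    rows = pd.DataFrame(
        {
            "centroid_x_nm": [c.centroid[0] for c in clusters],
            "centroid_y_nm": [c.centroid[1] for c in clusters],
            "lp_count": [c.lp_count for c in clusters],
            "precision_lateral_nm": [c.precision_lateral for c in clusters],
        }
    )
    path = ctx.outdir / "clusters.csv"
    rows.to_csv(path, index=False)
    ctx.files.append(path)
    out: dict = {"n_clusters": len(clusters), "single_fraction": stoichiometry.single_fraction(clusters)}
    multi = [c for c in clusters if c.lp_count >= 2]
    if multi:
        _, med = stoichiometry.localization_precision(clusters)
        out["median_lateral_precision_nm"] = med
    _write_json(ctx, "stoichiometry.json", out)
    return out


def _stage_fit_binding(ctx: _Context, params: dict, rng) -> dict:
    if "input" in params:
        series = BindingSeries.from_dataframe(pd.read_csv(params["input"]))
    else:
        series = sim.generate_binding_series(
            kd=float(params.get("kd", 123.0)),
            bmax=float(params.get("bmax", 100.0)),
            concentrations=params.get(
                "concentrations", [1, 3, 10, 30, 100, 300, 1000, 3000]
            ),
            noise_sd=float(params.get("noise_sd", 0.0)),
            replicates=int(params.get("replicates", 3)),
            seed=rng,
        )
    model = params.get("model", "one_site")
    fit = fit_one_site(series) if model == "one_site" else fit_sigmoid(series)
    out = {
        "model": fit.model,
        "kd_or_ec50_nm": fit.kd_or_ec50,
        "bmax_or_emax": fit.bmax_or_emax,
        "converged": fit.converged,
        "sse": fit.sse,
    }
    _write_json(ctx, "binding_fit.json", out)
    return out


_STAGES: dict[str, Callable] = {
    "simulate": _stage_simulate,
    "density": _stage_density,
    "nnd": _stage_nnd,
    "structure_ratio": _stage_structure_ratio,
    "hull_distance": _stage_hull_distance,
    "stoichiometry": _stage_stoichiometry,
    "fit_binding": _stage_fit_binding,
}


def run_pipeline(config: "RunConfig | dict", base_dir: "Path | None" = None) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config, base_dir=base_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(outdir=outdir)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "files": {},
        "config": {"stages": config.stages, "seed": config.seed},
        "complete": False,
    }
    for stage_cfg in config.stages:
        name = stage_cfg.get("stage")
        if name not in _STAGES:
            raise PipelineError(f"unknown stage {name!r}")
        rng = as_generator(stage_seed(config.seed, name))
        try:
            summary = _STAGES[name](ctx, stage_cfg, rng)
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            manifest["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in ctx.files}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        ctx.summaries[name] = summary
        manifest["stages"].append({"stage": name, "summary": summary})
    manifest["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(ctx.files))}
    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
    return manifest


_REPORT_SECTIONS = [
    ("simulate", "Simulation", ["n_molecules", "n_lps", "enrichment"]),
    ("density", "LP density", ["count", "area_um2", "density_per_um2", "corrected_density_per_um2"]),
    ("nnd", "Nearest-neighbor distances vs CSR", ["n", "median_nnd_nm", "ks_statistic", "p_value"]),
    ("structure_ratio", "Structure-association (dilation) ratio", ["ratio", "randomized_ratio"]),
    ("hull_distance", "Convex-hull surface distances", ["n_hulls", "n_within_cutoff", "ks_statistic", "p_value"]),
    ("stoichiometry", "Blink stoichiometry", ["n_clusters", "single_fraction", "median_lateral_precision_nm"]),
    ("fit_binding", "Binding-curve fit", ["model", "kd_or_ec50_nm", "bmax_or_emax", "converged"]),
]


def make_report(manifest: "dict | Path") -> str:
    """Human-readable summary of a completed run (idempotent)."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    summaries = {s["stage"]: s["summary"] for s in manifest.get("stages", [])}
    lines = ["# Run report", "", f"Global seed: {manifest.get('seed')}", ""]
    if not manifest.get("complete", False):
        lines.append(f"**Run incomplete** — failed at stage {manifest.get('failed_stage')!r}.")
        lines.append("")
    for key, title, fields_ in _REPORT_SECTIONS:
        if key not in summaries:
            continue
        lines.append(f"## {title}")
        for f in fields_:
            if f in summaries[key] and summaries[key][f] is not None:
                v = summaries[key][f]
                lines.append(f"- {f}: {v:.6g}" if isinstance(v, float) else f"- {f}: {v}")
        lines.append("")
    missing = [s.get("stage") for s in manifest.get("config", {}).get("stages", []) if s.get("stage") not in summaries]
    if missing:
        lines.append(f"Stages without outputs: {', '.join(map(str, missing))}")
        lines.append("")
    lines.append("## Settings")
    lines.append("```json")
    lines.append(json.dumps(manifest.get("config", {}), indent=1, sort_keys=True))
    lines.append("```")
    return "\n".join(lines) + "\n"
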