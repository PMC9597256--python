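"""End-to-end orchestration: synth -> fields -> fibers -> simulate.

A single YAML config drives the four stages; every stage writes its VTU
output plus a JSON run manifest recording configuration and mesh checksums,
solver counts, region element counts, frame-fallback counts and per-stage
wall times.  All stages are deterministic for a fixed config, so reruns
produce byte-identical field and fiber files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ep import (EPParameters, compute_cv, conductivity_tensor,
                 find_bb_stimulus_site, simulate_monodomain)
from .fibers import (assign_frames, assign_regions, default_threshold_table,
                     load_threshold_table)
from .fields import build_bc_tables, compute_fields
from .io import read_mesh, write_fields, write_landmarks, write_mesh
from .ionic import TwoCurrentModel
from .mesh import AnatomyMesh
from .synth import AnatomyConfig, extract_layer_surfaces, generate_idealized_la


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _mesh_checksum(mesh: AnatomyMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    return h.hexdigest()[:16]


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as f:
        return yaml.safe_load(f)


def _build_anatomy(config: dict, seed=None) -> AnatomyMesh:
    if "mesh" in config:
        return read_mesh(config["mesh"], landmarks=config.get("landmarks"))
    anat = dict(config.get("anatomy") or {})
    if seed is not None:
        anat.setdefault("seed", int(seed))
    return generate_idealized_la(AnatomyConfig(**anat))


def _threshold_table(config: dict, variant: str):
    spec = config.get("regions", "default")
    if spec in (None, "default"):
        return default_threshold_table(variant)
    return load_threshold_table(spec)


def _stage(manifest, name, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err
    manifest["stage_seconds"][name] = round(time.perf_counter() - t0, 3)
    return out


def run_pipeline(config, outdir, seed=None) -> dict:
    """Run all configured stages; return (and write) the run manifest."""
    config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "atriafiber", "version": __version__},
        "config_hash": _config_hash(config),
        "seed": seed,
        "stage_seconds": {},
    }

    mesh = _stage(manifest, "anatomy", lambda: _build_anatomy(config, seed))
    manifest["mesh_checksum"] = _mesh_checksum(mesh)
    manifest["n_nodes"] = mesh.n_nodes
    manifest["n_elements"] = mesh.n_elements
    if "anatomy" in config or "mesh" not in config:
        write_mesh(mesh, outdir / "la.msh")
        write_landmarks(mesh, outdir / "la_landmarks.json")

    surface_mode = config.get("mode", "volume") == "surface"
    fcfg = dict(config.get("fields") or {})
    tol = float(fcfg.pop("tol", 1e-10))

    if surface_mode:
        endo, epi = _stage(manifest, "surfaces",
                           lambda: extract_layer_surfaces(mesh))
        manifest["layers"] = {}
        for surf in (endo, epi):
            tag = surf.layer
            tables = build_bc_tables(surf, **fcfg)
            fs = _stage(manifest, f"fields_{tag}",
                        lambda: compute_fields(surf, tables, tol=tol))
            table = _threshold_table(config, tables.anatomy_variant)
            lab = assign_regions(fs, table)
            fr = _stage(manifest, f"fibers_{tag}",
                        lambda: assign_frames(fs, lab, table))
            write_fields(surf, {k: v.values for k, v in fs.fields.items()},
                         {"f": fr.f, "s": fr.s, "n": fr.n},
                         outdir / f"fibers_{tag}.vtu",
                         cell_scalars={"region": lab.region})
            manifest["layers"][tag] = {
                "laplace_solves": fs.solve_count,
                "region_counts": lab.counts(),
                "fallback_frames": fr.fallback_count,
            }
        _write_manifest(manifest, outdir)
        return manifest

    tables = build_bc_tables(mesh, **fcfg)
    fs = _stage(manifest, "fields", lambda: compute_fields(mesh, tables, tol=tol))
    manifest["laplace_solves"] = fs.solve_count
    manifest["anatomy_variant"] = tables.anatomy_variant
    write_fields(mesh, {k: v.values for k, v in fs.fields.items()}, {},
                 outdir / "fields.vtu")

    table = _threshold_table(config, tables.anatomy_variant)
    lab = _stage(manifest, "regions", lambda: assign_regions(fs, table))
    fr = _stage(manifest, "fibers", lambda: assign_frames(fs, lab, table))
    manifest["region_counts"] = lab.counts()
    manifest["nonempty_regions"] = len(lab.nonempty())
    manifest["fallback_frames"] = fr.fallback_count
    write_fields(mesh, {}, {"f": fr.f, "s": fr.s, "n": fr.n},
                 outdir / "fibers.vtu",
                 cell_scalars={"region": lab.region,
                               "endo_layer": lab.endo.astype(np.int64)})

    ep_cfg = dict(config.get("ep") or {})
    if ep_cfg.pop("enabled", bool(ep_cfg)):
        stim = dict(ep_cfg.pop("stim", {}))
        params = EPParameters(**ep_cfg)
        if "amplitude" in stim:
            params.stim_amplitude = float(stim["amplitude"])
        if "duration_ms" in stim:
            params.stim_duration = float(stim["duration_ms"])
        if stim.get("center") is not None:
            params.stim_center = tuple(stim["center"])
            params.stim_radius = float(stim.get("radius", 2.0))
        else:
            params.stim_nodes = find_bb_stimulus_site(
                mesh, fs, radius=float(stim.get("radius", 2.5)))
        tensors = conductivity_tensor(fr, params)
        res = _stage(manifest, "simulate",
                     lambda: simulate_monodomain(mesh, tensors,
                                                 TwoCurrentModel(), params))
        cv = compute_cv(mesh, res.lat)
        write_fields(mesh, {"LAT": np.where(np.isnan(res.lat), -1.0, res.lat)},
                     {}, outdir / "lat.vtu", cell_scalars={"CV": cv})
        tip = mesh.landmarks.get("laa_tip")
        lab_c = lab.region == lab.labels.index("C") if "C" in lab.labels else None
        laa_max = None
        if lab_c is not None and lab_c.any():
            laa_nodes = np.unique(mesh.elements[lab_c])
            laa_max = float(np.nanmax(res.lat[laa_nodes]))
        manifest["ep"] = {
            "stim_nodes": int(len(_as_array(params, mesh))),
            "activated_fraction": float(np.isfinite(res.lat).mean()),
            "max_lat_ms": float(np.nanmax(res.lat)),
            "laa_tip_lat_ms": (float(res.lat[tip]) if tip is not None else None),
            "laa_region_max_lat_ms": laa_max,
            "median_cv_mm_per_ms": float(np.nanmedian(cv)),
        }

    _write_manifest(manifest, outdir)
    return manifest


def _as_array(params: EPParameters, mesh: AnatomyMesh):
    from .ep import _stimulus_nodes
    return _stimulus_nodes(mesh, params)


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
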