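"""Shared fixtures: expensive meshes, field solves and simulations are
computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from atriafiber import (AnatomyConfig, EPParameters, FiberFrame, TwoCurrentModel,
                        assign_frames, assign_regions, box_mesh,
                        build_bc_tables, compute_fields, conductivity_tensor,
                        default_threshold_table, generate_idealized_la,
                        simulate_monodomain)


@pytest.fixture(scope="session")
def la_default():
    """Default four-PV synthetic LA with fields, regions and frames."""
    mesh = generate_idealized_la(AnatomyConfig())
    tables = build_bc_tables(mesh)
    fields = compute_fields(mesh, tables)
    table = default_threshold_table()
    labeling = assign_regions(fields, table)
    frame = assign_frames(fields, labeling, table)
    return {"mesh": mesh, "tables": tables, "fields": fields,
            "table": table, "labeling": labeling, "frame": frame}


@pytest.fixture(scope="session")
def la_coarse():
    """Coarser LA for simulation-heavy tests."""
    mesh = generate_idealized_la(AnatomyConfig(refine_levels=3))
    tables = build_bc_tables(mesh)
    fields = compute_fields(mesh, tables)
    table = default_threshold_table()
    labeling = assign_regions(fields, table)
    frame = assign_frames(fields, labeling, table)
    return {"mesh": mesh, "tables": tables, "fields": fields,
            "table": table, "labeling": labeling, "frame": frame}


def axis_frame(n_elements: int, fiber_axis=(1.0, 0.0, 0.0),
               sheet_axis=(0.0, 1.0, 0.0)) -> FiberFrame:
    f = np.tile(np.asarray(fiber_axis, float), (n_elements, 1))
    s = np.tile(np.asarray(sheet_axis, float), (n_elements, 1))
    return FiberFrame(f=f, s=s, n=np.cross(f, s),
                      fallback=np.zeros(n_elements, bool))


def run_bar(sigma_f: float, dt: float = 0.02, t_end: float = 40.0,
            fiber_axis=(1.0, 0.0, 0.0), sheet_axis=(0.0, 1.0, 0.0),
            h: float = 0.2):
    """Planar-wave run along a thin bar; returns (mesh, result)."""
    n = int(round(12.0 / h))
    mesh = box_mesh((12.0, 0.8, 0.8), (n, 4, 4))
    frame = axis_frame(mesh.n_elements, fiber_axis, sheet_axis)
    params = EPParameters(sigma_f=sigma_f, dt=dt, t_end=t_end, stim_tag="x0")
    tensors = conductivity_tensor(frame, params)
    res = simulate_monodomain(mesh, tensors, TwoCurrentModel(), params)
    return mesh, res


def bar_cv(mesh, lat, x_a: float = 3.0, x_b: float = 9.0) -> float:
    """Two-probe conduction speed between cross-sections of the bar."""
    x = mesh.nodes[:, 0]
    t_a = np.nanmean(lat[np.abs(x - x_a) < 1e-9])
    t_b = np.nanmean(lat[np.abs(x - x_b) < 1e-9])
    return (x_b - x_a) / (t_b - t_a)


@pytest.fixture(scope="session")
def cable_runs():
    """Bar simulations at sigma_f and 4 sigma_f (CV ~ sqrt(sigma) check)."""
    out = {}
    for key, sig in (("base", 1.3342), ("quad", 4 * 1.3342)):
        mesh, res = run_bar(sig)
        out[key] = {"mesh": mesh, "lat": res.lat, "cv": bar_cv(mesh, res.lat)}
    return out


@pytest.fixture(scope="session")
def slab_aniso():
    """Longitudinal vs transverse propagation with the default conductivities."""
    mesh_f, res_f = run_bar(1.3342, t_end=45.0)
    mesh_s, res_s = run_bar(1.3342, t_end=80.0,
                            fiber_axis=(0, 1, 0), sheet_axis=(1, 0, 0))
    return {"cv_f": bar_cv(mesh_f, res_f.lat),
            "cv_s": bar_cv(mesh_s, res_s.lat),
            "lat_f": res_f.lat, "mesh_f": mesh_f}
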