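"""Anisotropic monodomain electrophysiology on a fibered mesh.

Solves

    chi C_m dV/dt + I_ion(y, V) + I_stim(t) = div(sigma grad V)
    dy/dt = g(y, V)

with the conductivity tensor built from the local frame,
``sigma = sigma_f f (x) f + sigma_s s (x) s + sigma_n n (x) n``,
P1 finite elements in space, and first-order IMEX (SBDF1) stepping: the
gating states advance first, the updated states feed an explicit evaluation
of the ionic current, and the diffusion term is treated implicitly.
Natural (no-flux) boundary conditions apply on the whole boundary.

Units: conductivities mS/cm, chi 1/cm, C_m uF/cm^2, time ms, mesh
coordinates mm (converted to cm internally), stimulus uA/cm^3.  The solver
integrates the ionic model's normalized potential; activation times are
detected on the millivolt scale via the model's affine map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fibers import FiberFrame
from .ionic import IonicModel, TwoCurrentModel
from .laplace import SpecificationError, element_gradient, ScalarField
from .mesh import AnatomyMesh

#: Nodes that never cross the activation threshold keep this sentinel.
LAT_SENTINEL = np.nan

MM_PER_CM = 10.0


class FrameError(ValueError):
    """Fiber frame is not orthonormal within tolerance."""


class StabilityError(RuntimeError):
    """Time integration produced non-finite or out-of-range potentials."""


@dataclass
class EPParameters:
    """Monodomain and stimulus parameters.

    Defaults are the standard atrial-tissue set: chi = 1000 /cm, C_m = 1
    uF/cm^2, conductivities (1.3342, 0.36, 0.36) mS/cm along {f, s, n}, and
    a 1000 uA/cm^3 stimulus applied for the first 2 ms (positive amplitude
    depolarizes).
    """

    chi: float = 1000.0
    Cm: float = 1.0
    sigma_f: float = 1.3342
    sigma_s: float = 0.36
    sigma_n: float = 0.36
    stim_amplitude: float = 1000.0   # uA/cm^3
    stim_duration: float = 2.0       # ms
    stim_start: float = 0.0          # ms
    stim_nodes: np.ndarray | None = None
    stim_center: tuple | None = None   # mm; used with stim_radius
    stim_radius: float = 2.0           # mm
    stim_tag: str | None = None
    dt: float = 0.05                 # ms
    t_end: float = 60.0              # ms
    lat_threshold_mV: float = -40.0
    lump_mass: bool = False

    def validate(self):
        if min(self.sigma_f, self.sigma_s, self.sigma_n) <= 0:
            raise SpecificationError("conductivities must be positive")
        if self.dt <= 0:
            raise SpecificationError("dt must be positive")
        if self.stim_duration > self.t_end:
            raise SpecificationError("stimulus outlasts the simulation")


@dataclass
class ActivationMap:
    """Nodal local activation times (ms) and per-element conduction speed."""

    lat: np.ndarray            # ms, NaN where never activated
    cv: np.ndarray | None = None   # mm/ms, NaN where undefined


@dataclass
class MonodomainResult:
    lat: np.ndarray
    times: np.ndarray
    V_samples: np.ndarray | None
    u_final: np.ndarray
    y_final: np.ndarray
    model: IonicModel


def conductivity_tensor(frame: FiberFrame, params: EPParameters,
                        tol: float = 1e-8) -> np.ndarray:
    """Per-element tensor sigma_f f(x)f + sigma_s s(x)s + sigma_n n(x)n.

    The frame must be orthonormal; the result is then symmetric positive
    definite with eigenpairs (sigma_f, f), (sigma_s, s), (sigma_n, n).
    """
    for name, v in (("f", frame.f), ("s", frame.s), ("n", frame.n)):
        if np.max(np.abs(np.linalg.norm(v, axis=1) - 1.0)) > tol:
            raise FrameError(f"{name} vectors are not unit length")
    for a, b in ((frame.f, frame.s), (frame.f, frame.n), (frame.s, frame.n)):
        if np.max(np.abs(np.einsum("ij,ij->i", a, b))) > tol:
            raise FrameError("frame vectors are not pairwise orthogonal")
    t = (params.sigma_f * np.einsum("ei,ej->eij", frame.f, frame.f)
         + params.sigma_s * np.einsum("ei,ej->eij", frame.s, frame.s)
         + params.sigma_n * np.einsum("ei,ej->eij", frame.n, frame.n))
    return t


def _stimulus_nodes(mesh: AnatomyMesh, params: EPParameters) -> np.ndarray:
    if params.stim_nodes is not None:
        nodes = np.asarray(params.stim_nodes, dtype=np.int64).ravel()
    elif params.stim_tag is not None:
        nodes = mesh.nodes_of(params.stim_tag)
    elif params.stim_center is not None:
        d = np.linalg.norm(mesh.nodes - np.asarray(params.stim_center), axis=1)
        nodes = np.flatnonzero(d <= params.stim_radius)
    else:
        raise SpecificationError(
            "no stimulus support: set stim_nodes, stim_tag or stim_center"
        )
    if nodes.size == 0:
        raise SpecificationError("stimulus support contains no nodes")
    return nodes


def simulate_monodomain(mesh: AnatomyMesh, tensors: np.ndarray,
                        model: IonicModel | None = None,
                        params: EPParameters | None = None,
                        sample_every: int = 0,
                        progress: bool = False) -> MonodomainResult:
    """Run the SBDF1 monodomain simulation and stream activation times.

    ``tensors`` is the per-element conductivity (mS/cm).  Per step: advance
    the gating states, evaluate I_ion explicitly with the new states and the
    old potential, then solve the implicit diffusion system.  Activation
    times are recorded on the fly as the first upward crossing of the
    threshold, linearly interpolated between steps.
    """
    from .laplace import assemble_mass, assemble_stiffness

    model = model or TwoCurrentModel()
    params = params or EPParameters()
    params.validate()

    cm_mesh = AnatomyMesh(
        nodes=mesh.nodes / MM_PER_CM,
        elements=mesh.elements,
        boundary_facets=mesh.boundary_facets,
        facet_tags=mesh.facet_tags,
        tag_names=list(mesh.tag_names),
        landmarks=dict(mesh.landmarks),
        node_sets=dict(mesh.node_sets),
        mode=mesh.mode,
        layer=mesh.layer,
    )
    K = assemble_stiffness(cm_mesh, tensors=tensors)
    M = assemble_mass(cm_mesh, lumped=params.lump_mass)
    a = params.chi * params.Cm / params.dt
    A = (a * M + K).tocsc()
    lu = spla.splu(A)

    stim_nodes = _stimulus_nodes(mesh, params)
    stim_vec = np.zeros(mesh.n_nodes)
    stim_vec[stim_nodes] = params.stim_amplitude

    n_steps = int(round(params.t_end / params.dt))
    u = np.full(mesh.n_nodes, model.u_rest)
    y = model.y_rest(mesh.n_nodes)
    u_thr = (params.lat_threshold_mV - model.V_rest) / model.V_amp
    lat = np.full(mesh.n_nodes, LAT_SENTINEL)
    samples = [] if sample_every else None
    times = [] if sample_every else None
    lo, hi = model.u_range

    t = 0.0
    for step in range(n_steps):
        y = model.step_states(y, u, params.dt)
        I_ion = model.I_ion(y, u)
        I_stim = np.zeros(mesh.n_nodes)
        if params.stim_start <= t < params.stim_start + params.stim_duration:
            I_stim = -stim_vec     # positive amplitude depolarizes
        rhs = a * (M @ u) - M @ (I_ion + I_stim)
        u_new = lu.solve(rhs)
        t_new = t + params.dt
        if not np.all(np.isfinite(u_new)) or u_new.min() < lo or u_new.max() > hi:
            raise StabilityError(
                f"potential left [{lo}, {hi}] at t = {t_new:.3f} ms; "
                "reduce dt or refine the mesh"
            )
        crossing = np.isnan(lat) & (u < u_thr) & (u_new >= u_thr)
        if crossing.any():
            frac = (u_thr - u[crossing]) / (u_new[crossing] - u[crossing])
            lat[crossing] = t + frac * params.dt
        u = u_new
        t = t_new
        if sample_every and (step + 1) % sample_every == 0:
            samples.append(model.V_of(u).copy())
            times.append(t)

    return MonodomainResult(
        lat=lat,
        times=np.asarray(times) if times is not None else np.array([]),
        V_samples=np.asarray(samples) if samples else None,
        u_final=u,
        y_final=y,
        model=model,
    )


def compute_lat(V_history: np.ndarray, times: np.ndarray,
                threshold: float = -40.0) -> np.ndarray:
    """First upward threshold crossing per node, linearly interpolated.

    ``V_history`` has shape (n_times, n_nodes) sampled at uniform dt.
    Nodes that never cross get the NaN sentinel.
    """
    V = np.asarray(V_history, dtype=float)
    times = np.asarray(times, dtype=float)
    n_t, n_nodes = V.shape
    lat = np.full(n_nodes, LAT_SENTINEL)
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    for k in range(n_t - 1):
        crossing = np.isnan(lat) & below[k] & above[k]
        if crossing.any():
            frac = (threshold - V[k, crossing]) / (V[k + 1, crossing] - V[k, crossing])
            lat[crossing] = times[k] + frac * (times[k + 1] - times[k])
    return lat


def compute_cv(mesh: AnatomyMesh, lat: np.ndarray,
               min_slowness: float = 1e-6) -> np.ndarray:
    """Conduction speed per element as 1/|grad LAT| (mm/ms).

    NaN where any node of the element is unactivated or where the LAT
    gradient magnitude falls below ``min_slowness`` ms/mm (no resolvable
    wavefront, e.g. inside the stimulus region).
    """
    lat = np.asarray(lat, dtype=float)
    safe = np.where(np.isnan(lat), 0.0, lat)
    grad = element_gradient(mesh, ScalarField("lat", safe))
    slowness = np.linalg.norm(grad, axis=1)
    cv = np.full(mesh.n_elements, np.nan)
    ok = slowness > min_slowness
    cv[ok] = 1.0 / slowness[ok]
    has_nan = np.isnan(lat[mesh.elements]).any(axis=1)
    cv[has_nan] = np.nan
    return cv


def find_bb_stimulus_site(mesh: AnatomyMesh, fields,
                          radius: float = 2.0) -> np.ndarray:
    """Stimulus nodes at the top of the Bachmann's bundle region.

    Picks the epicardial node minimizing |phi2 - 0.5| + |phi3 - 1| — the
    center of the anterior wall at the superior margin — and returns all
    nodes within ``radius`` mm of it.
    """
    if mesh.mode == "volume":
        phi0 = fields.fields["phi0"].values
        epi = phi0 > 0.9
    else:
        epi = np.ones(mesh.n_nodes, dtype=bool)
    cost = (np.abs(fields.fields["phi2"].values - 0.5)
            + np.abs(fields.fields["phi3"].values - 1.0))
    cost = np.where(epi, cost, np.inf)
    center = mesh.nodes[int(np.argmin(cost))]
    d = np.linalg.norm(mesh.nodes - center, axis=1)
    return np.flatnonzero(d <= radius)
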