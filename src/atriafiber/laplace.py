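"""Linear (P1) finite elements for Laplace problems on tet and surface meshes.

Harmonic anatomical coordinates are solutions of ``Δφ = 0`` with Dirichlet
data ``g`` on selected boundary sets, landmark nodes, or interior node sets,
and homogeneous natural (no-flux) conditions elsewhere.  Dirichlet conditions
are imposed by symmetric elimination, so constrained nodes carry ``g``
exactly and the reduced operator stays symmetric positive-definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import AnatomyMesh, MeshError

#: Below this element volume (mm^3) / area (mm^2) an element is degenerate.
DEGENERATE_MEASURE = 1e-12

#: Unknown count above which the solver switches from sparse direct to CG.
DIRECT_SOLVE_LIMIT = 200_000


class SpecificationError(ValueError):
    """Ill-posed boundary-condition specification."""


class SolverError(RuntimeError):
    """Linear solver failed to reach the requested tolerance."""


@dataclass
class ScalarField:
    """A nodal scalar field, e.g. one harmonic coordinate."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.name!r} contains non-finite values")


@dataclass
class DirichletSpec:
    """Dirichlet data as a list of ``(selector, value)`` entries.

    Selectors:

    * ``("tag", name)`` — all nodes of a tagged boundary set,
    * ``("nodes", indices)`` — an explicit node set (landmarks included),
    * ``("field_threshold", field_name, a, b)`` — nodes where a previously
      computed field lies in the closed interval ``[a, b]``.

    Conflicting values at a shared node are rejected; repeated consistent
    values are allowed.
    """

    entries: list = field(default_factory=list)

    def add_tag(self, tag: str, value: float) -> "DirichletSpec":
        self.entries.append((("tag", tag), float(value)))
        return self

    def add_nodes(self, nodes, value: float) -> "DirichletSpec":
        self.entries.append((("nodes", np.asarray(nodes, dtype=np.int64).ravel()),
                             float(value)))
        return self

    def add_field_threshold(self, field_name: str, a: float, b: float,
                            value: float) -> "DirichletSpec":
        self.entries.append((("field_threshold", field_name, float(a), float(b)),
                             float(value)))
        return self

    def resolve(self, mesh: AnatomyMesh,
                fields: dict[str, ScalarField] | None = None):
        """Return ``(node_indices, values)`` arrays, checking conflicts."""
        if not self.entries:
            raise SpecificationError(
                "empty Dirichlet specification: the pure-Neumann Laplace "
                "problem is singular"
            )
        assigned: dict[int, float] = {}
        for selector, value in self.entries:
            kind = selector[0]
            if kind == "tag":
                nodes = mesh.nodes_of(selector[1])
            elif kind == "nodes":
                nodes = np.asarray(selector[1], dtype=np.int64).ravel()
            elif kind == "field_threshold":
                _, fname, a, b = selector
                if not fields or fname not in fields:
                    raise SpecificationError(
                        f"field-threshold selector needs field {fname!r}"
                    )
                v = fields[fname].values
                nodes = np.flatnonzero((v >= a) & (v <= b))
            else:
                raise SpecificationError(f"unknown selector kind {kind!r}")
            for n in nodes.tolist():
                if n in assigned and assigned[n] != value:
                    raise SpecificationError(
                        f"conflicting Dirichlet values {assigned[n]} and "
                        f"{value} at node {n}"
                    )
                assigned[n] = value
        idx = np.fromiter(assigned.keys(), dtype=np.int64)
        vals = np.fromiter(assigned.values(), dtype=np.float64)
        order = np.argsort(idx)
        return idx[order], vals[order]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def shape_gradients(mesh: AnatomyMesh):
    """Per-element P1 shape-function gradients and element measures.

    Returns ``(grads, measure)`` where ``grads`` has shape
    ``(n_elements, nodes_per_element, 3)`` (gradients in 1/mm) and
    ``measure`` is the volume (mm^3) or area (mm^2).  In surface mode the
    gradients are tangential (in-plane) vectors.
    """
    e = mesh.nodes[mesh.elements]
    if mesh.mode == "volume":
        t = e[:, 1:] - e[:, [0]]            # rows are edge vectors
        det = np.linalg.det(t)
        vol = det / 6.0
        bad = np.abs(vol) < DEGENERATE_MEASURE
        if bad.any():
            raise MeshError(
                f"degenerate element {int(np.flatnonzero(bad)[0])} "
                f"(|volume| < {DEGENERATE_MEASURE} mm^3)"
            )
        tinv = np.linalg.inv(t)             # (m, 3, 3)
        g = np.transpose(tinv, (0, 2, 1))   # rows i are grad(lambda_{i+1})
        g0 = -g.sum(axis=1, keepdims=True)
        grads = np.concatenate([g0, g], axis=1)
        return grads, vol
    # surface triangles embedded in 3D
    e1 = e[:, 1] - e[:, 0]
    e2 = e[:, 2] - e[:, 0]
    n = np.cross(e1, e2)
    twoa = np.linalg.norm(n, axis=1)
    bad = twoa / 2.0 < DEGENERATE_MEASURE
    if bad.any():
        raise MeshError(
            f"degenerate element {int(np.flatnonzero(bad)[0])} "
            f"(area < {DEGENERATE_MEASURE} mm^2)"
        )
    nhat = n / twoa[:, None]
    # grad(lambda_i) = nhat x opposite_edge / (2A), oriented inwards
    g0 = np.cross(nhat, e[:, 2] - e[:, 1]) / twoa[:, None]
    g1 = np.cross(nhat, e[:, 0] - e[:, 2]) / twoa[:, None]
    g2 = np.cross(nhat, e[:, 1] - e[:, 0]) / twoa[:, None]
    grads = np.stack([g0, g1, g2], axis=1)
    return grads, twoa / 2.0


def assemble_stiffness(mesh: AnatomyMesh,
                       tensors: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix ``K_ij = ∫ ∇v_i · σ ∇v_j``.

    ``tensors`` is an optional ``(n_elements, 3, 3)`` per-element symmetric
    conductivity; the default is the identity (plain Laplacian).  The matrix
    is symmetric with the constant vector in its null space.
    """
    grads, measure = shape_gradients(mesh)
    if tensors is None:
        flux = grads
    else:
        flux = np.einsum("eab,enb->ena", np.asarray(tensors), grads)
    local = np.einsum("eia,eja,e->eij", grads, flux, measure)
    local = 0.5 * (local + np.transpose(local, (0, 2, 1)))
    npe = mesh.elements.shape[1]
    rows = np.repeat(mesh.elements, npe, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, npe)).ravel()
    K = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return K


def assemble_mass(mesh: AnatomyMesh, lumped: bool = False) -> sp.csr_matrix:
    """P1 mass matrix (consistent by default, optionally row-lumped)."""
    _, measure = shape_gradients(mesh)
    npe = mesh.elements.shape[1]
    if lumped:
        diag = np.zeros(mesh.n_nodes)
        np.add.at(diag, mesh.elements.ravel(),
                  np.repeat(measure / npe, npe))
        return sp.diags(diag).tocsr()
    # consistent P1 mass: measure/20 off-diagonal, measure/10 diagonal (tet);
    # measure/12 and measure/6 for triangles
    off = measure / (20.0 if npe == 4 else 12.0)
    local = np.tile(off[:, None, None], (1, npe, npe))
    idx = np.arange(npe)
    local[:, idx, idx] = 2 * off[:, None]
    rows = np.repeat(mesh.elements, npe, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, npe)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def solve_laplace(mesh: AnatomyMesh, bc: DirichletSpec,
                  fields: dict[str, ScalarField] | None = None,
                  name: str = "phi",
                  stiffness: sp.csr_matrix | None = None,
                  tol: float = 1e-10) -> ScalarField:
    """Solve ``Δφ = 0`` with the given Dirichlet data.

    Constrained nodes are eliminated symmetrically, so they carry their data
    exactly.  Systems up to :data:`DIRECT_SOLVE_LIMIT` unknowns use a sparse
    direct factorization; larger ones fall back to preconditioned conjugate
    gradients with relative tolerance ``tol``.
    """
    K = assemble_stiffness(mesh) if stiffness is None else stiffness
    didx, dval = bc.resolve(mesh, fields)
    phi = np.zeros(mesh.n_nodes)
    phi[didx] = dval
    free = np.ones(mesh.n_nodes, dtype=bool)
    free[didx] = False
    fidx = np.flatnonzero(free)
    if fidx.size:
        A = K[fidx][:, fidx].tocsc()
        b = -K[fidx][:, didx] @ dval
        if fidx.size <= DIRECT_SOLVE_LIMIT:
            x = spla.spsolve(A, b)
        else:
            ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=20)
            M = spla.LinearOperator(A.shape, ilu.solve)
            x, info = spla.cg(A, b, rtol=tol, maxiter=5000, M=M)
            if info != 0:
                res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-30)
                raise SolverError(
                    f"CG did not converge (info={info}, relative residual {res:.3e})"
                )
        phi[fidx] = x
        res = np.linalg.norm(A @ x - b)
        scale = max(np.linalg.norm(b), 1.0)
        if not np.isfinite(res) or res > 1e-6 * scale:
            raise SolverError(f"residual {res:.3e} exceeds tolerance")
    return ScalarField(name=name, values=phi)


def element_gradient(mesh: AnatomyMesh, field: ScalarField) -> np.ndarray:
    """Constant per-element gradient of the P1 interpolant (1/mm).

    In surface mode this is the in-plane surface gradient.
    """
    grads, _ = shape_gradients(mesh)
    vals = field.values[mesh.elements]
    return np.einsum("en,ena->ea", vals, grads)
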