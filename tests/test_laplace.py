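"""P1 Laplace solver: assembly oracles, analytic limits, dense-solve check."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial import Delaunay

from atriafiber import (AnatomyMesh, DirichletSpec, ScalarField,
                        assemble_stiffness, box_mesh, element_gradient,
                        solve_laplace)
from atriafiber.laplace import SpecificationError


def unit_right_tet():
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    return AnatomyMesh(
        nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
        boundary_facets=np.empty((0, 3), int),
        facet_tags=np.empty(0, int), tag_names=[],
    )


def random_delaunay_mesh(n_points=200, seed=3):
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, 3))
    tri = Delaunay(pts)
    tets = tri.simplices.astype(np.int64)
    e = pts[tets]
    vol = np.linalg.det(e[:, 1:] - e[:, [0]]) / 6.0
    flip = np.flatnonzero(vol < 0)
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    keep = np.abs(np.linalg.det(pts[tets][:, 1:] - pts[tets][:, [0]])) > 1e-9
    return AnatomyMesh(
        nodes=pts, elements=tets[keep],
        boundary_facets=np.empty((0, 3), int),
        facet_tags=np.empty(0, int), tag_names=[],
    )


class TestAssembly:
    def test_unit_right_tet_matches_hand_assembly(self):
        # grad(l0) = (-1,-1,-1), grad(li) = e_i, V = 1/6:
        # K = V * G G^T with G rows the gradients
        K = assemble_stiffness(unit_right_tet()).toarray()
        G = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        expected = (G @ G.T) / 6.0
        assert np.allclose(K, expected, atol=1e-14)

    def test_constant_null_space_and_symmetry(self):
        mesh = random_delaunay_mesh()
        K = assemble_stiffness(mesh)
        ones = np.ones(mesh.n_nodes)
        assert np.max(np.abs(K @ ones)) < 1e-12 * sp.linalg.norm(K)
        asym = (K - K.T).tocoo()
        scale = np.abs(K.data).max()
        assert (np.abs(asym.data).max() if asym.nnz else 0.0) < 1e-14 * scale


class TestSolve:
    def test_linear_field_reproduced_exactly(self):
        mesh = box_mesh((1, 1, 1), (4, 4, 4))
        bc = DirichletSpec().add_tag("x0", 0.0).add_tag("x1", 1.0)
        phi = solve_laplace(mesh, bc)
        assert np.max(np.abs(phi.values - mesh.nodes[:, 0])) < 1e-12

    def test_constant_dirichlet_gives_constant_solution(self):
        mesh = box_mesh((1, 1, 1), (3, 3, 3))
        bc = DirichletSpec().add_tag("x0", 0.7).add_tag("z1", 0.7)
        phi = solve_laplace(mesh, bc)
        assert np.max(np.abs(phi.values - 0.7)) < 1e-12

    def test_matches_dense_constrained_solve(self):
        mesh = random_delaunay_mesh()
        rng = np.random.default_rng(11)
        didx = rng.choice(mesh.n_nodes, size=25, replace=False)
        dval = rng.random(25)
        bc = DirichletSpec()
        for i, v in zip(didx, dval):
            bc.add_nodes([i], float(v))
        phi = solve_laplace(mesh, bc)
        K = assemble_stiffness(mesh).toarray()
        free = np.setdiff1d(np.arange(mesh.n_nodes), didx)
        x = np.zeros(mesh.n_nodes)
        x[didx] = dval
        x[free] = np.linalg.solve(K[np.ix_(free, free)],
                                  -K[np.ix_(free, didx)] @ dval)
        assert np.max(np.abs(phi.values - x)) < 1e-10
        assert np.array_equal(phi.values[didx], dval)

    def test_solution_invariant_under_node_reordering(self):
        mesh = box_mesh((1, 1, 1), (3, 3, 3))
        bc = DirichletSpec().add_tag("x0", 0.0).add_tag("x1", 0.8)
        phi = solve_laplace(mesh, bc)
        perm = np.random.default_rng(5).permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        mesh2 = AnatomyMesh(
            nodes=mesh.nodes[perm],
            elements=inv[mesh.elements],
            boundary_facets=inv[mesh.boundary_facets],
            facet_tags=mesh.facet_tags, tag_names=list(mesh.tag_names),
        )
        phi2 = solve_laplace(mesh2, bc)
        assert np.max(np.abs(phi2.values[inv[np.arange(mesh.n_nodes)]]
                             - phi.values)) < 1e-10

    def test_empty_dirichlet_rejected(self):
        with pytest.raises(SpecificationError, match="singular"):
            solve_laplace(box_mesh((1, 1, 1), (2, 2, 2)), DirichletSpec())

    def test_conflicting_values_rejected(self):
        mesh = box_mesh((1, 1, 1), (2, 2, 2))
        bc = DirichletSpec().add_nodes([0], 0.0).add_nodes([0], 1.0)
        with pytest.raises(SpecificationError, match="conflict"):
            solve_laplace(mesh, bc)

    def test_field_threshold_selector_closed_interval(self):
        mesh = box_mesh((1, 1, 1), (2, 2, 2))
        guide = ScalarField("guide", mesh.nodes[:, 0])
        bc = (DirichletSpec()
              .add_field_threshold("guide", 0.0, 0.0, value=1.0)
              .add_tag("x1", 0.0))
        idx, val = bc.resolve(mesh, {"guide": guide})
        # the closed interval [0, 0] captures the whole x = 0 plane
        assert set(idx[val == 1.0]) == set(np.flatnonzero(mesh.nodes[:, 0] == 0))


class TestGradient:
    def test_linear_field_gradient(self):
        mesh = box_mesh((1, 1, 1), (3, 3, 3))
        g = element_gradient(mesh, ScalarField("x", mesh.nodes[:, 0]))
        assert np.max(np.abs(g - [1, 0, 0])) < 1e-12
        gc = element_gradient(mesh, ScalarField("c", np.full(mesh.n_nodes, 4.2)))
        assert np.max(np.abs(gc)) < 1e-12

    def test_single_tet_gradient_matches_hand_solve(self):
        mesh = unit_right_tet()
        vals = np.array([2.0, 5.0, 3.0, 7.0])
        g = element_gradient(mesh, ScalarField("v", vals))
        # affine v = a + b.x with b solving the 3x3 system from edges
        edges = mesh.nodes[1:] - mesh.nodes[0]
        b = np.linalg.solve(edges, vals[1:] - vals[0])
        assert np.allclose(g[0], b, atol=1e-13)


class TestSurfaceMode:
    def make_flat_square(self):
        n = 6
        xs = np.linspace(0, 1, n + 1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros((n + 1) ** 2)])
        tris = []
        for i in range(n):
            for j in range(n):
                a = i * (n + 1) + j
                b = (i + 1) * (n + 1) + j
                tris += [[a, b, a + 1], [b, b + 1, a + 1]]
        left = np.flatnonzero(nodes[:, 0] == 0)
        right = np.flatnonzero(nodes[:, 0] == 1)
        return AnatomyMesh(
            nodes=nodes, elements=np.asarray(tris, np.int64),
            boundary_facets=np.empty((0, 3), int),
            facet_tags=np.empty(0, int), tag_names=[],
            node_sets={"left": left, "right": right},
            mode="surface", layer="endo",
        )

    def test_surface_laplace_linear_exact(self):
        mesh = self.make_flat_square()
        bc = DirichletSpec().add_tag("left", 0.0).add_tag("right", 1.0)
        phi = solve_laplace(mesh, bc)
        assert np.max(np.abs(phi.values - mesh.nodes[:, 0])) < 1e-12
        g = element_gradient(mesh, phi)
        assert np.max(np.abs(g - [1, 0, 0])) < 1e-10
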