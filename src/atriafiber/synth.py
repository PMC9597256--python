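"""Procedural idealized left-atrial anatomies with tagged boundary sets.

The generator emulates a preprocessed patient LA at desk scale: an
ellipsoidal thin-walled chamber (~2 mm wall) with an open mitral-valve (MV)
orifice on the inferior aspect (MV ring in the z = 0 plane), open-ended
pulmonary-vein (PV) tubes on the superior/posterior aspect, and one closed
anterolateral left-atrial-appendage (LAA) tube.  Every boundary facet of the
volume mesh carries exactly one tag (endocardium, epicardium, mv_ring, one
tag per PV rim), and the two landmark nodes (LAA tip, fossa-ovalis center)
are set on the endocardial layer.

Construction: a subdivided icosphere is deformed into the body-plus-tubes
endocardial surface; cap faces at the MV orifice and the PV tube ends are
removed; the surface is extruded through the wall thickness along vertex
normals into prism layers, each split into three tetrahedra with an
index-based rule that keeps shared quad faces conforming.

Coordinate convention: +x septal (right PVs), -x lateral (left PVs and LAA),
+y posterior, +z superior, MV orifice at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import AnatomyMesh, boundary_faces


class GeometryError(ValueError):
    """Infeasible anatomy configuration (e.g. overlapping tubes)."""


@dataclass(frozen=True)
class TubeSpec:
    tag: str
    direction: tuple[float, float, float]
    angular_width: float      # patch half-angle on the unit sphere, rad
    radius: float             # tube radius, mm
    length: float             # tube length, mm
    open_end: bool            # True: end cap removed, rim tagged


@dataclass
class AnatomyConfig:
    """Geometry knobs for the idealized LA.

    Defaults emulate a standard four-PV anatomy with a ~2 mm wall.  PV rim
    tags follow the fixed scheme pv_ls / pv_li / pv_rs / pv_ri /
    pv_racc<N> / pv_lcommon keyed on by the boundary-condition tables.
    """

    n_left_pvs: int = 2           # 2 separate left PVs, or 1 common trunk
    n_right_pvs: int = 2          # 2..4 (superior, inferior, + accessories)
    wall_thickness: float = 2.0   # mm
    body_radii: tuple[float, float, float] = (30.0, 25.0, 22.0)  # mm
    pv_radius: float = 4.5        # mm
    laa_radius: float = 5.0       # mm
    tube_length: float = 10.0     # mm (PVs)
    laa_length: float = 14.0      # mm
    mv_height_fraction: float = 0.72  # ellipsoid center height / c radius
    refine_levels: int = 4        # icosphere subdivisions
    n_layers: int = 3             # elements through the wall
    jitter: float = 0.0           # tangential node jitter amplitude, mm
    seed: int = 0

    def validate(self) -> None:
        if self.wall_thickness <= 0:
            raise GeometryError("wall_thickness must be positive")
        if self.n_left_pvs not in (1, 2):
            raise GeometryError("n_left_pvs must be 1 (common trunk) or 2")
        if not 2 <= self.n_right_pvs <= 4:
            raise GeometryError("n_right_pvs must be between 2 and 4")
        if max(self.pv_radius, self.laa_radius) >= min(self.body_radii):
            raise GeometryError("tube radii must be below the body radii")
        if self.n_layers < 1 or self.refine_levels < 2:
            raise GeometryError("need n_layers >= 1 and refine_levels >= 2")


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def tube_layout(config: AnatomyConfig) -> list[TubeSpec]:
    """Tube directions/sizes for the configured PV variant."""
    c = config
    tubes: list[TubeSpec] = []
    if c.n_left_pvs == 2:
        tubes.append(TubeSpec("pv_ls", (-0.72, 0.42, 0.55), 0.30,
                              c.pv_radius, c.tube_length, True))
        tubes.append(TubeSpec("pv_li", (-0.80, 0.52, -0.10), 0.30,
                              c.pv_radius, c.tube_length, True))
    else:
        tubes.append(TubeSpec("pv_lcommon", (-0.78, 0.47, 0.25), 0.34,
                              1.3 * c.pv_radius, c.tube_length, True))
    tubes.append(TubeSpec("pv_rs", (0.72, 0.42, 0.55), 0.30,
                          c.pv_radius, c.tube_length, True))
    tubes.append(TubeSpec("pv_ri", (0.80, 0.52, -0.10), 0.30,
                          c.pv_radius, c.tube_length, True))
    # accessory right middle PVs sit posteriorly between the two majors
    accessory_dirs = [(0.55, 0.80, 0.23), (0.25, 0.78, 0.57)]
    for k in range(c.n_right_pvs - 2):
        tubes.append(TubeSpec(f"pv_racc{k + 1}", accessory_dirs[k], 0.18,
                              0.6 * c.pv_radius, 0.9 * c.tube_length, True))
    tubes.append(TubeSpec("laa", (-0.50, -0.62, 0.55), 0.32,
                          c.laa_radius, c.laa_length, False))
    return tubes


_FO_DIRECTION = _unit((0.98, 0.12, -0.05))  # septal, mid-posterior

# Tube end caps are removed where m = angle/width < this.  The value sits
# past the cap disk (m < 0.5), so the cut rim lies on the cylindrical tube
# wall and the extruded rim elements stay well-shaped.
_CAP_FRACTION = 0.55
_SEPARATION_MARGIN = 0.02    # rad, minimum clearance between tube patches


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _check_layout(tubes: list[TubeSpec]) -> None:
    dirs = [_unit(t.direction) for t in tubes]
    for i in range(len(tubes)):
        for j in range(i + 1, len(tubes)):
            ang = float(np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1)))
            need = tubes[i].angular_width + tubes[j].angular_width
            if ang < need + _SEPARATION_MARGIN:
                raise GeometryError(
                    f"tubes {tubes[i].tag!r} and {tubes[j].tag!r} overlap: "
                    f"separation {ang:.3f} rad < required {need:.3f} rad"
                )


def _deform(U: np.ndarray, config: AnatomyConfig,
            tubes: list[TubeSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Map unit-sphere vertices to the endocardial surface.

    Returns the deformed positions and an ``(n_vertices, n_tubes)`` array of
    normalized angular coordinates ``m`` (< 1 inside a tube patch).
    """
    a, b, c = config.body_radii
    zc = config.mv_height_fraction * c
    center = np.array([0.0, 0.0, zc])
    P = np.column_stack([a * U[:, 0], b * U[:, 1], c * U[:, 2] + zc])
    M = np.full((len(U), len(tubes)), np.inf)
    for j, t in enumerate(tubes):
        d = _unit(t.direction)
        ang = np.arccos(np.clip(U @ d, -1.0, 1.0))
        m = ang / t.angular_width
        M[:, j] = m
        sel = m < 1.0
        if not np.any(sel):
            continue
        ms = m[sel]
        rel = P[sel] - center
        xi = rel @ d
        perp = rel - xi[:, None] * d
        pr = np.linalg.norm(perp, axis=1)
        phat = perp / np.maximum(pr, 1e-12)[:, None]
        s_len = _smoothstep((1.0 - ms) / 0.5)          # plateau for m <= 0.5
        r_tube = t.radius * _smoothstep(ms / 0.5)      # 0 at apex, R beyond
        blend = _smoothstep((1.0 - ms) / 0.3)          # 1 inside, 0 at edge
        r_new = (1.0 - blend) * pr + blend * r_tube
        P[sel] = (center + (xi + s_len * t.length)[:, None] * d
                  + r_new[:, None] * phat)
    return P, M


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
]


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (bottom v0 v1 v2, top v3 v4 v5) into 3 tets each.

    Uses the smallest-global-index rotation rule, which picks quad-face
    diagonals from vertex indices only, so faces shared between neighboring
    prisms (laterally or through stacked layers) are split identically and
    the tetrahedral mesh conforms.
    """
    out = np.empty((len(prisms), 3, 4), dtype=np.int64)
    for k, pv in enumerate(prisms):
        rot = min(_PRISM_ROTATIONS, key=lambda r: pv[r[0]])
        I = [pv[r] for r in rot]
        if min(I[1], I[5]) < min(I[2], I[4]):
            tets = [(I[0], I[1], I[2], I[5]),
                    (I[0], I[1], I[5], I[4]),
                    (I[0], I[4], I[5], I[3])]
        else:
            tets = [(I[0], I[1], I[2], I[4]),
                    (I[0], I[4], I[2], I[5]),
                    (I[0], I[4], I[5], I[3])]
        out[k] = tets
    return out.reshape(-1, 4)


def generate_idealized_la(config: AnatomyConfig | None = None) -> AnatomyMesh:
    """Generate a tagged tetrahedral idealized-LA shell mesh."""
    config = config or AnatomyConfig()
    config.validate()
    tubes = tube_layout(config)
    _check_layout(tubes)

    base = trimesh.creation.icosphere(subdivisions=config.refine_levels,
                                      radius=1.0)
    U = np.asarray(base.vertices, dtype=np.float64)
    F = np.asarray(base.faces, dtype=np.int64)
    P, M = _deform(U, config, tubes)

    if config.jitter > 0:
        rng = np.random.default_rng(config.seed)
        P = P + config.jitter * rng.standard_normal(P.shape)

    # vertex normals of the closed deformed surface (outward)
    fn = np.cross(P[F[:, 1]] - P[F[:, 0]], P[F[:, 2]] - P[F[:, 0]])
    vnorm = np.zeros_like(P)
    for k in range(3):
        np.add.at(vnorm, F[:, k], fn)
    vnorm /= np.linalg.norm(vnorm, axis=1, keepdims=True)

    # openings: MV orifice (faces below z = 0) and open tube end caps
    centroid_z = P[F].mean(axis=1)[:, 2]
    removed_by: dict[str, np.ndarray] = {"mv_ring": centroid_z < 0.0}
    for j, t in enumerate(tubes):
        if t.open_end:
            mask = M[F, j].mean(axis=1) < _CAP_FRACTION
            # guarantee an opening even when the cap is under-resolved:
            # drop the faces incident to the tube-apex vertex
            apex = int(np.argmin(M[:, j]))
            mask |= np.any(F == apex, axis=1)
            removed_by[t.tag] = mask
    removed = np.zeros(len(F), dtype=bool)
    for mask in removed_by.values():
        removed |= mask
    if removed.all():
        raise GeometryError("all faces removed; check the configuration")

    # A ragged cut can leave faces with all three vertices on a rim loop;
    # the wedge extruded from such a face has every node on the Dirichlet
    # rim and hence a constant harmonic field.  Absorb those faces into the
    # adjacent opening until every kept face has an off-rim vertex.
    while True:
        kept_vertices = set(np.unique(F[~removed]).tolist())
        rim_base: dict[str, set[int]] = {}
        for tag, mask in removed_by.items():
            verts = set(np.unique(F[mask]).tolist()) & kept_vertices
            if not verts:
                raise GeometryError(
                    f"opening {tag!r} produced no rim; the mesh is too "
                    "coarse for this tube (increase refine_levels)"
                )
            rim_base[tag] = verts
        all_rim = set().union(*rim_base.values())
        flat = np.fromiter(
            (all(int(v) in all_rim for v in f) for f in F), dtype=bool
        ) & ~removed
        if not flat.any():
            break
        for k in np.flatnonzero(flat):
            fverts = set(int(v) for v in F[k])
            for tag, verts in rim_base.items():
                if fverts <= verts:
                    removed_by[tag][k] = True
                    break
            else:
                # touches two rims at once; merge into whichever it meets
                tag = next(t for t, verts in rim_base.items()
                           if fverts & verts)
                removed_by[tag][k] = True
            removed[k] = True
    kept_faces = F[~removed]

    # extrude: node (layer l, base vertex i) -> l * n_base + i
    n_base = len(U)
    n_layers = config.n_layers
    dt = config.wall_thickness / n_layers
    sheets = [P + (l * dt) * vnorm for l in range(n_layers + 1)]
    nodes_full = np.vstack(sheets)

    prisms = []
    for l in range(n_layers):
        lo = kept_faces + l * n_base
        hi = kept_faces + (l + 1) * n_base
        prisms.append(np.hstack([lo, hi]))
    tets = split_prisms(np.vstack(prisms))

    # orient for positive volume (face sets, hence conformity, unchanged)
    e = nodes_full[tets]
    vol = np.linalg.det(e[:, 1:] - e[:, [0]]) / 6.0
    flip = np.flatnonzero(vol < 0)
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    # compact node numbering
    used = np.unique(tets)
    remap = -np.ones(nodes_full.shape[0], dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = nodes_full[used]
    tets = remap[tets]

    # classify boundary faces
    bfaces_old = boundary_faces(tets)
    # recover base vertex and layer of each (compacted) node
    base_of = used % n_base
    layer_of = used // n_base
    tag_names = ["endocardium", "epicardium"] + list(removed_by.keys())
    tag_index = {t: i for i, t in enumerate(tag_names)}
    fl = layer_of[bfaces_old]
    facet_tags = np.full(len(bfaces_old), -1, dtype=np.int64)
    facet_tags[np.all(fl == 0, axis=1)] = tag_index["endocardium"]
    facet_tags[np.all(fl == n_layers, axis=1)] = tag_index["epicardium"]
    side = facet_tags < 0
    fb = base_of[bfaces_old]
    for tag, verts in rim_base.items():
        hit = side & np.all(np.isin(fb, list(verts)), axis=1)
        facet_tags[hit] = tag_index[tag]
    if np.any(facet_tags < 0):
        raise GeometryError(
            f"{int((facet_tags < 0).sum())} boundary facets could not be "
            "assigned to an opening rim"
        )

    # landmarks on the endocardial sheet
    laa_dir = _unit(next(t.direction for t in tubes if t.tag == "laa"))
    endo_nodes = np.flatnonzero(layer_of == 0)
    laa_align = U[base_of[endo_nodes]] @ laa_dir
    laa_tip = int(endo_nodes[np.argmax(laa_align)])
    fo_align = U[base_of[endo_nodes]] @ _FO_DIRECTION
    fo_center = int(endo_nodes[np.argmax(fo_align)])

    node_sets = {tag: np.flatnonzero(np.isin(base_of, list(verts)))
                 for tag, verts in rim_base.items()}

    mesh = AnatomyMesh(
        nodes=nodes,
        elements=tets,
        boundary_facets=bfaces_old,
        facet_tags=facet_tags,
        tag_names=tag_names,
        landmarks={"laa_tip": laa_tip, "fo_center": fo_center},
        node_sets=node_sets,
        mode="volume",
    )
    mesh.validate()
    return mesh


def extract_layer_surfaces(mesh: AnatomyMesh) -> tuple[AnatomyMesh, AnatomyMesh]:
    """Extract the endocardial and epicardial triangle surfaces.

    Both surfaces inherit the rim tags as node sets and are oriented with
    outward normals (away from the chamber centroid); the layer flag is set
    to ``endo`` / ``epi`` respectively.
    """
    out = []
    centroid = mesh.nodes.mean(axis=0)
    for tag, layer in (("endocardium", "endo"), ("epicardium", "epi")):
        faces = mesh.facets_of(tag)
        if not len(faces):
            raise GeometryError(f"mesh has no facets tagged {tag!r}")
        used = np.unique(faces)
        remap = -np.ones(mesh.n_nodes, dtype=np.int64)
        remap[used] = np.arange(len(used))
        tri = remap[faces]
        pts = mesh.nodes[used]
        # orient away from the chamber centroid
        fc = pts[tri].mean(axis=1)
        fn = np.cross(pts[tri[:, 1]] - pts[tri[:, 0]],
                      pts[tri[:, 2]] - pts[tri[:, 0]])
        inward = np.einsum("ij,ij->i", fn, fc - centroid) < 0
        tri[np.flatnonzero(inward)] = tri[np.flatnonzero(inward)][:, [0, 2, 1]]
        node_sets = {}
        for rim, vol_nodes in mesh.node_sets.items():
            hit = remap[np.asarray(vol_nodes)]
            hit = hit[hit >= 0]
            if len(hit):
                node_sets[rim] = np.sort(hit)
        landmarks = {}
        for name, idx in mesh.landmarks.items():
            if remap[idx] >= 0:
                landmarks[name] = int(remap[idx])
            else:
                d2 = np.einsum("ij,ij->i", pts - mesh.nodes[idx],
                               pts - mesh.nodes[idx])
                landmarks[name] = int(np.argmin(d2))
        surf = AnatomyMesh(
            nodes=pts,
            elements=tri,
            boundary_facets=np.empty((0, 3), np.int64),
            facet_tags=np.empty(0, np.int64),
            tag_names=[],
            landmarks=landmarks,
            node_sets=node_sets,
            mode="surface",
            layer=layer,
        )
        surf.validate()
        out.append(surf)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# simple structured meshes (test and benchmark geometries)
# ---------------------------------------------------------------------------

def box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4)) -> AnatomyMesh:
    """Structured tetrahedral box with face tags x0/x1/y0/y1/z0/z1.

    Each grid cube is cut into six Kuhn tetrahedra, which conform across
    neighboring cubes.  Used for solver verification and slab/cable
    conduction benchmarks.
    """
    L = np.asarray(lengths, dtype=float)
    nx, ny, nz = (int(d) for d in divisions)
    xs = [np.linspace(0, L[k], n + 1) for k, n in enumerate((nx, ny, nz))]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn triangulation: 6 tets per cube along vertex permutations
    kuhn = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
        (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
    ]
    corner = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
              (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + c[0], j + c[1], k + c[2]) for c in corner]
                for t in kuhn:
                    tets.append([ids[t[0]], ids[t[1]], ids[t[2]], ids[t[3]]])
    tets = np.asarray(tets, dtype=np.int64)
    e = nodes[tets]
    vol = np.linalg.det(e[:, 1:] - e[:, [0]]) / 6.0
    neg = np.flatnonzero(vol < 0)
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]

    bf = boundary_faces(tets)
    fc = nodes[bf].mean(axis=1)
    eps = 1e-9 * max(L)
    tag_names = ["x0", "x1", "y0", "y1", "z0", "z1"]
    conds = [fc[:, 0] < eps, fc[:, 0] > L[0] - eps,
             fc[:, 1] < eps, fc[:, 1] > L[1] - eps,
             fc[:, 2] < eps, fc[:, 2] > L[2] - eps]
    facet_tags = np.full(len(bf), -1, dtype=np.int64)
    for t, cond in enumerate(conds):
        facet_tags[(facet_tags < 0) & cond] = t
    mesh = AnatomyMesh(
        nodes=nodes, elements=tets, boundary_facets=bf,
        facet_tags=facet_tags, tag_names=tag_names,
    )
    mesh.validate()
    return mesh
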