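"""Tagged unstructured meshes for left-atrial anatomy.

The central container is :class:`AnatomyMesh`: a tetrahedral volume mesh (or a
triangle surface mesh in surface mode) whose boundary facets carry string tags
naming the anatomical boundary sets (endocardium, epicardium, mitral-valve
ring, one tag per pulmonary-vein rim) and whose landmark nodes locate the
left-atrial-appendage tip and the fossa-ovalis center.  All indices are
0-based; coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Structural problem with a mesh (topology, orientation, quality)."""


class TaggingError(KeyError):
    """A referenced boundary tag is missing, duplicated, or inconsistent."""


@dataclass
class AnatomyMesh:
    """Unstructured mesh of the left-atrial wall with tagged boundary sets.

    Parameters
    ----------
    nodes:
        ``(n_nodes, 3)`` float array of coordinates in mm.
    elements:
        ``(n_elements, 4)`` int array of tetrahedra (volume mode) or
        ``(n_elements, 3)`` triangles (surface mode).
    boundary_facets:
        ``(n_facets, 3)`` int array of boundary triangles (volume mode only;
        empty in surface mode, where rim tags live in ``node_sets``).
    facet_tags:
        ``(n_facets,)`` int array indexing into ``tag_names``.
    tag_names:
        Ordered list of declared boundary-set names.
    landmarks:
        Map ``{"laa_tip": i, "fo_center": j}`` of node indices.
    node_sets:
        Tagged node sets; always usable for Dirichlet data, and the only tag
        carrier in surface mode (rim nodes inherited from the volume mesh).
    mode:
        ``"volume"`` or ``"surface"``.
    layer:
        In surface mode, which wall layer this surface represents
        (``"endo"`` or ``"epi"``); ``None`` in volume mode.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_facets: np.ndarray
    facet_tags: np.ndarray
    tag_names: list[str]
    landmarks: dict[str, int] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = "volume"
    layer: str | None = None

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.boundary_facets = np.ascontiguousarray(
            np.reshape(self.boundary_facets, (-1, 3)), dtype=np.int64
        )
        self.facet_tags = np.ascontiguousarray(self.facet_tags, dtype=np.int64)
        if len(self.tag_names) != len(set(self.tag_names)):
            raise TaggingError("duplicate boundary tag names")

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def tags(self) -> set[str]:
        names = set(self.tag_names) | set(self.node_sets)
        return names

    def facets_of(self, tag: str) -> np.ndarray:
        """Boundary facets (triples of node indices) carrying ``tag``."""
        if tag not in self.tag_names:
            raise TaggingError(f"unknown boundary tag {tag!r}")
        tid = self.tag_names.index(tag)
        return self.boundary_facets[self.facet_tags == tid]

    def nodes_of(self, tag: str) -> np.ndarray:
        """Sorted unique node indices belonging to a tagged set."""
        if tag in self.node_sets:
            return np.asarray(np.sort(np.unique(self.node_sets[tag])), dtype=np.int64)
        return np.unique(self.facets_of(tag))

    # -- geometry ---------------------------------------------------------

    def element_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (mm^3); triangle areas in surface mode."""
        e = self.nodes[self.elements]
        if self.mode == "surface":
            n = np.cross(e[:, 1] - e[:, 0], e[:, 2] - e[:, 0])
            return 0.5 * np.linalg.norm(n, axis=1)
        t = e[:, 1:] - e[:, [0]]
        return np.linalg.det(t) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def surface_normals(self) -> np.ndarray:
        """Unit per-element normals (surface mode only)."""
        if self.mode != "surface":
            raise MeshError("surface_normals is defined only in surface mode")
        e = self.nodes[self.elements]
        n = np.cross(e[:, 1] - e[:, 0], e[:, 2] - e[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise MeshError/TaggingError."""
        if self.elements.size and self.elements.max() >= self.n_nodes:
            raise MeshError("element refers to a node index out of range")
        for name, idx in self.landmarks.items():
            if not (0 <= int(idx) < self.n_nodes):
                raise MeshError(f"landmark {name!r} index {idx} out of range")
        if self.mode == "volume":
            if self.elements.shape[1] != 4:
                raise MeshError("volume mode requires tetrahedral elements")
            vols = self.element_volumes()
            if vols.size and vols.min() <= 0:
                bad = int(np.argmin(vols))
                raise MeshError(
                    f"non-positive volume {vols[bad]:.3e} mm^3 in element {bad}"
                )
            if self.facet_tags.shape[0] != self.boundary_facets.shape[0]:
                raise TaggingError("facet_tags length mismatch")
            self._check_facets_on_boundary()
        elif self.mode == "surface":
            if self.elements.shape[1] != 3:
                raise MeshError("surface mode requires triangle elements")
            if self.layer not in ("endo", "epi"):
                raise MeshError("surface mode requires layer 'endo' or 'epi'")
        else:
            raise MeshError(f"unknown mesh mode {self.mode!r}")

    def _check_facets_on_boundary(self) -> None:
        """Every tagged facet must be a face of exactly one tetrahedron."""
        faces = element_faces(self.elements)
        key = np.sort(faces.reshape(-1, 3), axis=1)
        order = np.lexsort(key.T[::-1])
        skey = key[order]
        # count occurrences of each face
        new = np.ones(len(skey), dtype=bool)
        new[1:] = np.any(skey[1:] != skey[:-1], axis=1)
        group = np.cumsum(new) - 1
        counts = np.bincount(group)
        starts = np.flatnonzero(new)
        uniq = skey[starts]
        bkey = np.sort(self.boundary_facets, axis=1)
        # locate each boundary facet among the unique faces
        pos = _rows_searchsorted(uniq, bkey)
        missing = pos < 0
        if np.any(missing):
            raise MeshError(
                f"{missing.sum()} boundary facets are not faces of any element"
            )
        if np.any(counts[pos] != 1):
            raise MeshError("a tagged boundary facet is shared by two elements")


def element_faces(elements: np.ndarray) -> np.ndarray:
    """All 4 triangular faces of each tetrahedron, outward-ordered."""
    tets = np.asarray(elements)
    f = np.stack(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ],
        axis=1,
    )
    return f


def boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Faces of the tet mesh that belong to exactly one element."""
    faces = element_faces(elements).reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    skey = key[order]
    new = np.ones(len(skey), dtype=bool)
    new[1:] = np.any(skey[1:] != skey[:-1], axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    single = counts[group] == 1
    return faces[order[single]]


def _rows_searchsorted(sorted_rows: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of each query row in lexicographically sorted rows, -1 if absent."""
    def view(a):
        a = np.ascontiguousarray(a)
        return a.view([("", a.dtype)] * a.shape[1]).ravel()

    s, q = view(sorted_rows), view(query)
    pos = np.searchsorted(s, q)
    pos = np.clip(pos, 0, len(s) - 1)
    ok = s[pos] == q
    return np.where(ok, pos, -1)


def locate_landmark(mesh: AnatomyMesh, point) -> tuple[int, float]:
    """Nearest mesh node to ``point`` (mm), with its distance.

    Ties (equidistant nodes) resolve to the lowest node index.
    """
    p = np.asarray(point, dtype=np.float64).reshape(3)
    d2 = np.einsum("ij,ij->i", mesh.nodes - p, mesh.nodes - p)
    idx = int(np.argmin(d2))  # argmin returns the first (lowest) index on ties
    return idx, float(np.sqrt(d2[idx]))
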