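"""The seven harmonic anatomical coordinates of the left atrium.

Seven Laplace solves (six in surface mode) give normalized distance fields:

* ``phi0`` — transmural, 0 on the endocardium and 1 on the epicardium; its
  gradient is the transmural direction ``s``.  Not solved in surface mode,
  where ``s`` comes from the surface normal.
* ``phi1`` — appendage-to-septum, 0 at the LAA tip landmark and 1 at the
  fossa-ovalis center landmark.  Thresholds on ``phi1`` define the LAA and
  FO regions used by later fields.
* ``phi2`` — lateral-septal sweep: 0 on the left PVs, 1 on the right PVs.
* ``phi3`` — inferior-superior PV sweep separating anterior from posterior:
  1 on superior PVs, 0 on inferior PVs, intermediate values on accessories;
  natural (no-flux) on a left common trunk.
* ``phi4`` — MV-to-PV distance shaping the Bachmann's-bundle band: 1 on the
  MV ring, 0 on the major PVs, 0.1 on right middle (accessory) PVs, and an
  interior constraint on the LAA and FO regions.
* ``phi5`` — antral field: 0 on left PVs and MV ring, 0.5 on the LAA,
  1 on the right PVs.
* ``phi6`` — anterior-wall fiber field: 0 on left PVs, right inferior PV and
  the MV ring, 0.05 on the LAA, 1 on the remaining right PVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laplace import (DirichletSpec, ScalarField, SpecificationError,
                      assemble_stiffness, element_gradient, solve_laplace)
from .mesh import AnatomyMesh

FIELD_NAMES = tuple(f"phi{i}" for i in range(7))


@dataclass
class FieldBCTable:
    """Per-field Dirichlet tables plus the phi1 thresholds for LAA/FO sets."""

    specs: dict[str, DirichletSpec]
    laa_interval: tuple[float, float] = (0.0, 0.05)   # phi1 in [a, b] -> LAA
    fo_interval: tuple[float, float] = (0.95, 1.0)    # phi1 in [a, b] -> FO
    anatomy_variant: str = "standard"

    def __post_init__(self):
        expected = set(FIELD_NAMES)
        got = set(self.specs)
        if got not in (expected, expected - {"phi0"}):
            raise SpecificationError(
                f"need Dirichlet tables for phi0..phi6 (or phi1..phi6 in "
                f"surface mode); got {sorted(got)}"
            )


@dataclass
class HarmonicFieldSet:
    """Solved fields phi0..phi6 with per-element gradients g0..g6."""

    mesh: AnatomyMesh
    fields: dict[str, ScalarField]
    gradients: dict[str, np.ndarray]
    solve_count: int = 0

    def phi(self, i: int) -> ScalarField:
        return self.fields[f"phi{i}"]

    def g(self, i: int) -> np.ndarray:
        return self.gradients[f"phi{i}"]

    def centroid_values(self, i: int) -> np.ndarray:
        """Field value at element centroids (mean of nodal values)."""
        return self.phi(i).values[self.mesh.elements].mean(axis=1)


def _classify_pv_tags(mesh: AnatomyMesh):
    """Group the mesh's PV rim tags by side and superior/inferior role."""
    pv = sorted(t for t in mesh.tags if t.startswith("pv_"))
    left = [t for t in pv if t in ("pv_ls", "pv_li", "pv_lcommon")]
    right = [t for t in pv if t not in left]
    info = {
        "left": left,
        "right": right,
        "common_trunk": "pv_lcommon" in left,
        "right_superior": [t for t in right if t == "pv_rs"],
        "right_inferior": [t for t in right if t == "pv_ri"],
        "right_accessory": sorted(t for t in right if t.startswith("pv_racc")),
    }
    if not left or not right:
        raise SpecificationError(
            f"mesh needs left and right PV rim tags, found {pv}"
        )
    return info


def _accessory_values(n: int) -> list[float]:
    """Evenly spaced interior values in (0, 1), superior-most first."""
    return [(n - k) / (n + 1) for k in range(n)]


def build_bc_tables(mesh: AnatomyMesh,
                    laa_interval=(0.0, 0.05),
                    fo_interval=(0.95, 1.0),
                    phi4_laa: float = 0.5,
                    phi4_fo: float = 0.5,
                    landmark_patch_radius: float = 0.0,
                    split_mv_ring_phi6: bool = False) -> FieldBCTable:
    """Build the Dirichlet tables phi0..phi6 for the mesh's PV variant.

    ``phi4_laa``/``phi4_fo`` default to the 0.5/0.5 convention; the
    alternative 1/0 reading (LAA identically one, FO identically zero) is
    available by passing ``phi4_laa=1.0, phi4_fo=0.0``.
    ``landmark_patch_radius`` (mm) optionally widens the phi1 landmark
    constraints from single nodes to small spherical node patches.
    ``split_mv_ring_phi6`` switches the phi6 MV-ring datum from a uniform 0
    to a septal/lateral half split (1 on the septal half, 0 laterally).
    """
    pv = _classify_pv_tags(mesh)
    lm = mesh.landmarks
    if "laa_tip" not in lm or "fo_center" not in lm:
        raise SpecificationError("mesh needs laa_tip and fo_center landmarks")

    def landmark_nodes(idx):
        if landmark_patch_radius <= 0:
            return np.array([idx], dtype=np.int64)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[idx], axis=1)
        return np.flatnonzero(d <= landmark_patch_radius)

    specs: dict[str, DirichletSpec] = {}
    if mesh.mode == "volume":
        specs["phi0"] = (DirichletSpec()
                         .add_tag("endocardium", 0.0)
                         .add_tag("epicardium", 1.0))

    specs["phi1"] = (DirichletSpec()
                     .add_nodes(landmark_nodes(lm["laa_tip"]), 0.0)
                     .add_nodes(landmark_nodes(lm["fo_center"]), 1.0))

    s2 = DirichletSpec()
    for t in pv["left"]:
        s2.add_tag(t, 0.0)
    for t in pv["right"]:
        s2.add_tag(t, 1.0)
    specs["phi2"] = s2

    # phi3: superior 1, inferior 0, accessories intermediate; a common left
    # trunk gets natural (no Dirichlet) conditions
    s3 = DirichletSpec()
    if not pv["common_trunk"]:
        s3.add_tag("pv_ls", 1.0).add_tag("pv_li", 0.0)
    s3.add_tag("pv_rs", 1.0).add_tag("pv_ri", 0.0)
    for t, v in zip(pv["right_accessory"],
                    _accessory_values(len(pv["right_accessory"]))):
        s3.add_tag(t, v)
    specs["phi3"] = s3

    # phi4: MV 1, major PVs 0, right middle PVs 0.1, LAA/FO interior data
    s4 = DirichletSpec().add_tag("mv_ring", 1.0)
    for t in pv["left"] + pv["right_superior"] + pv["right_inferior"]:
        s4.add_tag(t, 0.0)
    for t in pv["right_accessory"]:
        s4.add_tag(t, 0.1)
    s4.add_field_threshold("phi1", *laa_interval, value=phi4_laa)
    s4.add_field_threshold("phi1", *fo_interval, value=phi4_fo)
    specs["phi4"] = s4

    s5 = DirichletSpec().add_tag("mv_ring", 0.0)
    for t in pv["left"]:
        s5.add_tag(t, 0.0)
    for t in pv["right"]:
        s5.add_tag(t, 1.0)
    s5.add_field_threshold("phi1", *laa_interval, value=0.5)
    specs["phi5"] = s5

    s6 = DirichletSpec()
    if split_mv_ring_phi6:
        # septal (right) half of the ring at 1, lateral half at 0, so the
        # ring datum sits half-way between the right and left PVs
        ring = mesh.nodes_of("mv_ring")
        septal = ring[mesh.nodes[ring, 0] > np.median(mesh.nodes[ring, 0])]
        lateral = np.setdiff1d(ring, septal)
        s6.add_nodes(septal, 1.0).add_nodes(lateral, 0.0)
    else:
        s6.add_tag("mv_ring", 0.0)
    for t in pv["left"] + pv["right_inferior"]:
        s6.add_tag(t, 0.0)
    for t in pv["right_superior"] + pv["right_accessory"]:
        s6.add_tag(t, 1.0)
    s6.add_field_threshold("phi1", *laa_interval, value=0.05)
    specs["phi6"] = s6

    if mesh.mode == "surface":
        specs.pop("phi0", None)

    variant = "common_left_trunk" if pv["common_trunk"] else (
        "accessory_right" if pv["right_accessory"] else "standard")
    return FieldBCTable(specs=specs, laa_interval=laa_interval,
                        fo_interval=fo_interval, anatomy_variant=variant)


def compute_fields(mesh: AnatomyMesh, tables: FieldBCTable,
                   tol: float = 1e-10) -> HarmonicFieldSet:
    """Solve all harmonic fields in dependency order (phi0, phi1, phi2..6).

    phi1 must precede phi4..phi6 because their LAA/FO interior constraints
    are thresholds on phi1.  Exactly seven Laplace solves are performed in
    volume mode, six in surface mode.
    """
    K = assemble_stiffness(mesh)
    solved: dict[str, ScalarField] = {}
    grads: dict[str, np.ndarray] = {}
    count = 0
    order = [n for n in FIELD_NAMES if n in tables.specs]
    for name in order:
        f = solve_laplace(mesh, tables.specs[name], fields=solved,
                          name=name, stiffness=K, tol=tol)
        solved[name] = f
        grads[name] = element_gradient(mesh, f)
        count += 1
    return HarmonicFieldSet(mesh=mesh, fields=solved, gradients=grads,
                            solve_count=count)
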