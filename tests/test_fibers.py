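"""Region decomposition (sequential subtraction) and fiber-frame rules."""

import numpy as np
import pytest
import yaml
from scipy.spatial import cKDTree

from atriafiber import (AnatomyConfig, RegionRule, ThresholdTable,
                        assign_frames, assign_regions, build_bc_tables,
                        characteristic, compute_fields,
                        default_threshold_table, generate_idealized_la,
                        load_threshold_table)
from atriafiber.laplace import SpecificationError

INF = float("inf")


class TestCharacteristic:
    def test_interior_point(self):
        assert characteristic(0.5, 0.2, 0.8) == 1

    def test_boundary_is_excluded(self):
        # the region sets use strict inequalities
        assert characteristic(0.2, 0.2, 0.8) == 0
        assert characteristic(0.8, 0.2, 0.8) == 0

    def test_unbounded_interval_accepts_everything(self):
        vals = np.array([-1e9, 0.0, 1e9])
        assert characteristic(vals, -INF, INF).tolist() == [1, 1, 1]

    def test_invalid_interval_rejected(self):
        with pytest.raises(SpecificationError, match="alpha"):
            characteristic(0.5, 0.8, 0.2)


def rule(label, layer="both", constraints=(), branch="f", gradient=1,
         description=""):
    return RegionRule(label=label, description=description, layer=layer,
                      constraints=tuple(constraints), branch=branch,
                      gradient=gradient)


class TestTableValidation:
    def test_catch_all_required(self):
        with pytest.raises(SpecificationError, match="catch-all"):
            ThresholdTable([rule("A", constraints=[(1, 0.0, 0.5)])])

    def test_bad_interval_in_rule(self):
        with pytest.raises(SpecificationError, match="alpha"):
            rule("A", constraints=[(1, 0.9, 0.1)])

    def test_yaml_round_trip(self, tmp_path):
        table = default_threshold_table()
        assert len(table.rules) == 17
        path = tmp_path / "regions.yaml"
        rows = [{
            "label": r.label, "layer": r.layer,
            "constraints": [{"field": i, "alpha": a, "beta": b}
                            for i, a, b in r.constraints],
            "rule": {"branch": r.branch, "gradient": r.gradient},
        } for r in table.rules]
        path.write_text(yaml.safe_dump(rows))
        back = load_threshold_table(path)
        assert [r.label for r in back.rules] == table.labels
        assert all(a.constraints == b.constraints
                   for a, b in zip(back.rules, table.rules))


class TestSequentialSubtraction:
    def test_first_matching_region_wins(self, la_coarse):
        fields = la_coarse["fields"]
        # two rules with identical constraints: all elements land in the first
        t = ThresholdTable([
            rule("first", constraints=[(2, -INF, INF)], gradient=2),
            rule("second", constraints=[(2, -INF, INF)], gradient=2),
            rule("rest"),
        ])
        lab = assign_regions(fields, t)
        counts = lab.counts()
        assert counts["first"] == fields.mesh.n_elements
        assert counts["second"] == 0 and counts["rest"] == 0

    def test_impossible_constraints_fall_through_to_catch_all(self, la_coarse):
        fields = la_coarse["fields"]
        t = ThresholdTable([
            rule("never", constraints=[(2, 5.0, 6.0)]),  # phi2 <= 1
            rule("all"),
        ])
        lab = assign_regions(fields, t)
        assert lab.counts()["all"] == fields.mesh.n_elements

    def test_partition_is_exhaustive_and_disjoint(self, la_default):
        lab = la_default["labeling"]
        mesh = la_default["mesh"]
        assert lab.region.shape == (mesh.n_elements,)
        assert (lab.region >= 0).all()
        assert sum(lab.counts().values()) == mesh.n_elements

    def test_default_table_yields_17_nonempty_regions(self, la_default):
        assert len(la_default["labeling"].nonempty()) == 17

    def test_layer_flag_matches_midwall_split(self, la_default):
        phi0 = la_default["fields"].centroid_values(0)
        assert np.array_equal(la_default["labeling"].endo, phi0 < 0.5)


class TestFrames:
    def test_orthonormal_right_handed(self, la_default):
        fr = la_default["frame"]
        for v in (fr.f, fr.s, fr.n):
            assert np.max(np.abs(np.linalg.norm(v, axis=1) - 1)) < 1e-12
        assert np.max(np.abs(np.einsum("ij,ij->i", fr.f, fr.s))) < 1e-10
        assert np.max(np.abs(np.einsum("ij,ij->i", fr.f, fr.n))) < 1e-10
        assert np.max(np.abs(fr.n - np.cross(fr.f, fr.s))) < 1e-10

    def test_fallback_fraction_small(self, la_default):
        fr = la_default["frame"]
        assert fr.fallback_count / len(fr.f) < 0.005

    def test_f_branch_worked_example(self):
        # s = z, f-branch with g = (1,0,0): f = x, n = f x s = -y
        fr = _frames_with_overrides(branch="f", g=(1.0, 0.0, 0.0))
        np.testing.assert_allclose(fr["f"], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr["n"], [0, -1, 0], atol=1e-12)

    def test_n_branch_worked_example(self):
        # s = z, gradient (1,0,1)/sqrt(2): projection is x; the transversal
        # branch puts f along the level sets and n = f x s = -x
        fr = _frames_with_overrides(branch="n",
                                    g=(1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)))
        np.testing.assert_allclose(fr["f"], [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(fr["n"]), [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr["n"], np.cross(fr["f"], [0, 0, 1.0]),
                                   atol=1e-12)

    def test_fo_layers_are_nearly_orthogonal(self, la_default):
        lab, fr = la_default["labeling"], la_default["frame"]
        table = la_default["table"]
        cent = la_default["mesh"].element_centroids()
        iD = np.flatnonzero(lab.region == table.labels.index("D"))
        iE = np.flatnonzero(lab.region == table.labels.index("E"))
        assert len(iD) and len(iE)
        _, nn = cKDTree(cent[iE]).query(cent[iD])
        dots = np.abs(np.einsum("ij,ij->i", fr.f[iD], fr.f[iE[nn]]))
        assert (dots < 0.5).mean() > 0.5

    def test_common_trunk_rule_swap_changes_frames(self):
        mesh = generate_idealized_la(
            AnatomyConfig(n_left_pvs=1, refine_levels=3))
        fields = compute_fields(mesh, build_bc_tables(mesh))
        std = default_threshold_table("standard")
        trk = default_threshold_table("common_left_trunk")
        hk = std.labels.index("H")
        assert std.rules[hk].gradient == 3 and trk.rules[hk].gradient == 6
        lab = assign_regions(fields, std)
        sel = lab.region == hk
        assert sel.any()
        f_std = assign_frames(fields, lab, std).f[sel]
        f_trk = assign_frames(fields, lab, trk).f[sel]
        assert np.max(np.linalg.norm(f_std - f_trk, axis=1)) > 0.1

    def test_degenerate_gradient_uses_neighbor_fallback(self, la_coarse):
        fields = la_coarse["fields"]
        # a rule keyed on phi0 makes the gradient parallel to s everywhere
        t = ThresholdTable([
            rule("bad", constraints=[(2, -INF, 0.1)], gradient=0),
            rule("rest", gradient=4, branch="n"),
        ])
        lab = assign_regions(fields, t)
        assert lab.counts()["bad"] > 0
        fr = assign_frames(fields, lab, t)
        assert fr.fallback_count >= lab.counts()["bad"]
        # fallback frames are still orthonormal
        assert np.max(np.abs(np.linalg.norm(fr.f, axis=1) - 1)) < 1e-10
        assert np.max(np.abs(fr.n - np.cross(fr.f, fr.s))) < 1e-10

    def test_deterministic(self, la_default):
        fields, table = la_default["fields"], la_default["table"]
        lab2 = assign_regions(fields, table)
        fr2 = assign_frames(fields, lab2, table)
        assert np.array_equal(lab2.region, la_default["labeling"].region)
        assert np.array_equal(fr2.f, la_default["frame"].f)
        assert np.array_equal(fr2.n, la_default["frame"].n)


def _frames_with_overrides(branch, g):
    """Run assign_frames on one synthetic element with s = +z."""
    from atriafiber.fields import HarmonicFieldSet
    from atriafiber.laplace import ScalarField
    from atriafiber.mesh import AnatomyMesh

    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = AnatomyMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
                       boundary_facets=np.empty((0, 3), int),
                       facet_tags=np.empty(0, int), tag_names=[])
    fields = HarmonicFieldSet(
        mesh=mesh,
        fields={f"phi{i}": ScalarField(f"phi{i}", np.zeros(4))
                for i in range(7)},
        gradients={"phi0": np.array([[0.0, 0, 1]]),
                   **{f"phi{i}": np.array([g], dtype=float)
                      for i in range(1, 7)}},
    )
    t = ThresholdTable([rule("only", branch=branch, gradient=1)])
    lab = assign_regions(fields, t)
    fr = assign_frames(fields, lab, t)
    return {"f": fr.f[0], "s": fr.s[0], "n": fr.n[0]}
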