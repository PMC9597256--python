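"""Anatomical region decomposition and two-layer fiber frames.

The LA wall is split into 17 ordered subregions by thresholded
characteristic functions of the harmonic fields with sequential subtraction:
region k claims the elements satisfying all of its strict threshold
constraints that no earlier region claimed, and the final region is a
catch-all, so the labeling is an exhaustive disjoint partition.  Each region
carries a frame rule naming a field gradient and a branch:

* f-branch — the projected gradient is the fiber direction ``f``
  (longitudinal/oblique regions, fibers along the field's ascent);
* n-branch — the projected gradient is the transversal direction, so ``f``
  runs along the field's level sets (circumferential regions).

The transmural direction ``s`` is the normalized gradient of the transmural
field phi0 (volume mode) or the surface normal (surface mode).  The chosen
gradient is projected onto the plane orthogonal to ``s``, normalized, and
the cross-product branch applied, yielding a right-handed orthonormal triad
{f, s, n} with n = f x s per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .fields import HarmonicFieldSet
from .laplace import SpecificationError

#: |projected gradient| below this (relative to |g|, or absolutely for
#: near-zero g) triggers the degenerate-frame fallback.
DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class RegionRule:
    """One ordered row of the threshold table."""

    label: str                    # e.g. "A" (anterior floor)
    description: str
    layer: str                    # "endo" | "epi" | "both"
    constraints: tuple            # ((field index, alpha, beta), ...)
    branch: str                   # "f" | "n"
    gradient: int                 # which phi gradient feeds the rule

    def __post_init__(self):
        if self.layer not in ("endo", "epi", "both"):
            raise SpecificationError(f"bad layer scope {self.layer!r}")
        if self.branch not in ("f", "n"):
            raise SpecificationError(f"bad frame branch {self.branch!r}")
        for i, a, b in self.constraints:
            if not a < b:
                raise SpecificationError(
                    f"region {self.label!r}: alpha={a} must be < beta={b} "
                    f"for phi{i}"
                )


@dataclass
class ThresholdTable:
    rules: list[RegionRule]

    def __post_init__(self):
        if not self.rules:
            raise SpecificationError("threshold table is empty")
        last = self.rules[-1]
        if last.constraints or last.layer != "both":
            raise SpecificationError(
                "the final region must be an unconstrained both-layer "
                "catch-all so the labeling is exhaustive"
            )
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise SpecificationError("duplicate region labels")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rules]


@dataclass
class RegionLabeling:
    """Per-element region index (row of the table) and endo/epi layer flag."""

    region: np.ndarray            # (n_elements,) int
    endo: np.ndarray              # (n_elements,) bool
    labels: list[str]

    def counts(self) -> dict[str, int]:
        c = np.bincount(self.region, minlength=len(self.labels))
        return {lab: int(n) for lab, n in zip(self.labels, c)}

    def nonempty(self) -> list[str]:
        return [lab for lab, n in self.counts().items() if n > 0]


@dataclass
class FiberFrame:
    """Per-element right-handed orthonormal triad {f, s, n}."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray
    fallback: np.ndarray          # bool mask of fallback-assigned elements

    @property
    def fallback_count(self) -> int:
        return int(self.fallback.sum())


def characteristic(values, alpha: float, beta: float) -> np.ndarray:
    """Strict-interval indicator: 1 where alpha < value < beta."""
    if not alpha < beta:
        raise SpecificationError(f"alpha={alpha} must be < beta={beta}")
    v = np.asarray(values, dtype=float)
    return ((v > alpha) & (v < beta)).astype(np.int8)


def assign_regions(fields: HarmonicFieldSet,
                   table: ThresholdTable) -> RegionLabeling:
    """Label every element with the first region whose constraints it meets.

    Fields are evaluated at element centroids.  Sequential subtraction makes
    the partition order-dependent and exhaustive (the catch-all closes it).
    """
    mesh = fields.mesh
    m = mesh.n_elements
    if mesh.mode == "volume":
        endo = fields.centroid_values(0) < 0.5
    else:
        endo = np.full(m, mesh.layer == "endo")
    centroid_cache: dict[int, np.ndarray] = {}

    def cvals(i):
        if i not in centroid_cache:
            centroid_cache[i] = fields.centroid_values(i)
        return centroid_cache[i]

    region = np.full(m, -1, dtype=np.int64)
    for k, rule in enumerate(table.rules):
        mask = region < 0
        if rule.layer == "endo":
            mask &= endo
        elif rule.layer == "epi":
            mask &= ~endo
        for i, a, b in rule.constraints:
            mask &= characteristic(cvals(i), a, b).astype(bool)
        region[mask] = k
    # the validated catch-all guarantees this
    assert np.all(region >= 0)
    return RegionLabeling(region=region, endo=endo, labels=table.labels)


def assign_frames(fields: HarmonicFieldSet, labeling: RegionLabeling,
                  table: ThresholdTable) -> FiberFrame:
    """Build the per-element orthonormal frame from the region rules.

    The transmural axis ``s`` comes from grad(phi0) (volume) or the surface
    normal (surface mode).  Elements whose chosen gradient is degenerate or
    (anti)parallel to ``s`` copy the frame of the nearest successfully
    assigned element (global +x projection if none exists); the fallback
    mask is returned for QC.
    """
    mesh = fields.mesh
    m = mesh.n_elements
    if mesh.mode == "volume":
        s = fields.g(0).copy()
    else:
        s = mesh.surface_normals().copy()
        if mesh.layer == "endo":
            # keep s pointing endo -> epi (into the wall)
            s = s
    snorm = np.linalg.norm(s, axis=1)
    bad_s = snorm < 1e-14
    s[bad_s] = (0.0, 0.0, 1.0)
    s /= np.linalg.norm(s, axis=1, keepdims=True)

    f = np.zeros((m, 3))
    n = np.zeros((m, 3))
    fallback = bad_s.copy()
    for k, rule in enumerate(table.rules):
        sel = labeling.region == k
        if not sel.any():
            continue
        g = fields.g(rule.gradient)[sel]
        sk = s[sel]
        gperp = g - np.einsum("ij,ij->i", g, sk)[:, None] * sk
        norm = np.linalg.norm(gperp, axis=1)
        scale = np.maximum(np.linalg.norm(g, axis=1), 1.0)
        ok = norm > DEGENERATE_TOL * scale
        ghat = gperp / np.maximum(norm, 1e-300)[:, None]
        if rule.branch == "f":
            fk = ghat
        else:
            # transversal branch: f runs along the level sets of the field
            fk = np.cross(ghat, sk)
        nk = np.cross(fk, sk)
        idx = np.flatnonzero(sel)
        f[idx] = fk
        n[idx] = nk
        fallback[idx[~ok]] = True

    good = np.flatnonzero(~fallback)
    miss = np.flatnonzero(fallback)
    if miss.size:
        cent = mesh.element_centroids()
        if good.size:
            _, nearest = cKDTree(cent[good]).query(cent[miss])
            src = good[nearest]
            f[miss] = f[src]
            n[miss] = n[src]
            # re-orthogonalize the copied frame against the local s
            fp = f[miss] - np.einsum("ij,ij->i", f[miss], s[miss])[:, None] * s[miss]
            fn = np.linalg.norm(fp, axis=1)
            usable = fn > 1e-12
            fp[usable] /= fn[usable, None]
            fp[~usable] = _project_axis(s[miss][~usable])
            f[miss] = fp
            n[miss] = np.cross(f[miss], s[miss])
        else:
            f[miss] = _project_axis(s[miss])
            n[miss] = np.cross(f[miss], s[miss])
    return FiberFrame(f=f, s=s, n=n, fallback=fallback)


def _project_axis(s: np.ndarray) -> np.ndarray:
    """Projection of +x (or +y where degenerate) orthogonal to s, normalized."""
    axis = np.tile(np.array([1.0, 0.0, 0.0]), (len(s), 1))
    p = axis - np.einsum("ij,ij->i", axis, s)[:, None] * s
    norm = np.linalg.norm(p, axis=1)
    swap = norm < 1e-8
    if swap.any():
        alt = np.tile(np.array([0.0, 1.0, 0.0]), (int(swap.sum()), 1))
        p[swap] = alt - np.einsum("ij,ij->i", alt, s[swap])[:, None] * s[swap]
        norm = np.linalg.norm(p, axis=1)
    return p / norm[:, None]


# ---------------------------------------------------------------------------
# default threshold table
# ---------------------------------------------------------------------------

def load_threshold_table(source) -> ThresholdTable:
    """Load a threshold table from YAML (path, text, or parsed list).

    Schema: ordered list of ``{label, description, layer, constraints:
    [{field, alpha, beta}], rule: {branch, gradient}}``; alpha/beta may be
    ``-inf`` / ``inf``.
    """
    import os
    if isinstance(source, (list, tuple)):
        raw = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, (str, os.PathLike)) and os.path.isfile(source):
            with open(source) as fh:
                text = fh.read()
        else:
            text = source
        raw = yaml.safe_load(text)
    rules = []
    for row in raw:
        cons = tuple(
            (int(c["field"]), float(c.get("alpha", -np.inf)),
             float(c.get("beta", np.inf)))
            for c in row.get("constraints", [])
        )
        rules.append(RegionRule(
            label=str(row["label"]),
            description=str(row.get("description", "")),
            layer=str(row.get("layer", "both")),
            constraints=cons,
            branch=str(row["rule"]["branch"]),
            gradient=int(row["rule"]["gradient"]),
        ))
    return ThresholdTable(rules=rules)


def default_threshold_table(variant: str = "standard") -> ThresholdTable:
    """The shipped 17-region table calibrated for the synthetic LA.

    ``variant="common_left_trunk"`` swaps the left-PV frame rule from
    grad(phi3) to grad(phi6), treating the trunk as a single vein without a
    left carina.
    """
    text = resources.files("atriafiber.data").joinpath(
        "regions_default.yaml").read_text()
    table = load_threshold_table(yaml.safe_load(text))
    if variant == "common_left_trunk":
        rules = [
            RegionRule(r.label, r.description, r.layer, r.constraints,
                       r.branch, 6) if r.label == "H" else r
            for r in table.rules
        ]
        table = ThresholdTable(rules=rules)
    return table
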