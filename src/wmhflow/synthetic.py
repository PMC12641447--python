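"""Synthetic ground-truth generators.

Everything downstream of raw imaging is testable against this module: it
produces (a) continuous bifurcating arterial trees with known radii, lengths
and tortuosity, (b) voxelized vessel masks rasterized from those trees,
(c) ellipsoidal lesion / ventricle volumes placed at controlled distances,
and (d) subject cohorts with planted linear effects of hemodynamic features
on log lesion volume.

Trees are generated in continuous mm coordinates and rasterized afterwards,
so exact morphometry (branch count, radii, arc length, arc/chord tortuosity)
is available independently of any grid.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidParameterError
from .graph import VascularNetwork, VesselBranch
from .volume import VoxelVolume

__all__ = [
    "TreeBranch",
    "GroundTruthTree",
    "EllipsoidSpec",
    "CohortSpec",
    "generate_arterial_tree",
    "fit_grid",
    "voxelize_tree",
    "generate_lesion_set",
    "generate_cohort",
    "network_from_tree",
    "tree_to_json",
    "tree_from_json",
]


# --------------------------------------------------------------------------
# continuous arterial trees
# --------------------------------------------------------------------------

@dataclass
class TreeBranch:
    """One branch of a ground-truth tree: straight or gently curved segment."""

    branch_id: int
    parent_id: int | None
    start: np.ndarray          # (3,) mm
    end: np.ndarray            # (3,) mm
    radius: float              # mm, constant along the branch
    waypoints: list = field(default_factory=list)  # interior (3,) points, in order

    def polyline(self) -> np.ndarray:
        pts = [self.start] + [np.asarray(w, dtype=float) for w in self.waypoints] + [self.end]
        return np.asarray(pts, dtype=float)

    @property
    def length(self) -> float:
        p = self.polyline()
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def tortuosity(self) -> float:
        return self.length / self.chord


@dataclass
class GroundTruthTree:
    """A forest of branches with exact geometry; roots are the inflow branches."""

    branches: list
    root_ids: list

    def branch(self, branch_id: int) -> TreeBranch:
        return self._index()[branch_id]

    def _index(self) -> dict:
        return {b.branch_id: b for b in self.branches}

    def children(self, branch_id: int) -> list:
        return [b for b in self.branches if b.parent_id == branch_id]

    def leaves(self) -> list:
        parents = {b.parent_id for b in self.branches if b.parent_id is not None}
        return [b for b in self.branches if b.branch_id not in parents]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) mm over all polyline points, inflated by branch radii."""
        los, his = [], []
        for b in self.branches:
            p = b.polyline()
            los.append(p.min(axis=0) - b.radius)
            his.append(p.max(axis=0) + b.radius)
        return np.min(los, axis=0), np.max(his, axis=0)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to unit vector u."""
    trial = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    return p / np.linalg.norm(p)


def generate_arterial_tree(
    depth: int,
    root_radius: float = 1.5,
    radius_ratios: tuple[float, float] = (0.8, 0.7),
    tortuosity_amp: float = 0.0,
    seed: int = 0,
    root_length: float = 30.0,
    length_decay: float = 0.75,
    branch_angle_deg: float = 35.0,
    n_waypoints: int = 3,
) -> GroundTruthTree:
    """Grow a full binary arterial tree in continuous coordinates.

    Daughter radii are ``parent_radius * radius_ratios``; daughter lengths
    shrink by ``length_decay`` per generation.  The bifurcation plane rotates
    90 degrees each generation so branches splay into 3-D and do not collide.
    When ``tortuosity_amp > 0`` each branch receives ``n_waypoints`` interior
    waypoints displaced sinusoidally by up to ``tortuosity_amp`` mm in a
    seed-determined perpendicular direction, making arc/chord > 1.

    Parameters mirror typical cerebral branch geometry: length/radius ratios
    well above 10 and daughter radii 0.6-0.9 of the parent.
    """
    if depth < 1:
        raise InvalidParameterError(f"depth must be >= 1, got {depth}")
    if root_radius <= 0 or root_length <= 0:
        raise InvalidParameterError("root radius and length must be positive")
    if not all(0 < r <= 1 for r in radius_ratios):
        raise InvalidParameterError(f"radius ratios must lie in (0, 1], got {radius_ratios}")
    if tortuosity_amp < 0:
        raise InvalidParameterError("tortuosity amplitude must be >= 0")

    rng = np.random.default_rng(seed)
    theta = np.deg2rad(branch_angle_deg)
    branches: list[TreeBranch] = []
    next_id = [0]

    def add_branch(parent_id, start, direction, normal, radius, length, level):
        bid = next_id[0]
        next_id[0] += 1
        end = start + direction * length
        waypoints = []
        if tortuosity_amp > 0 and n_waypoints > 0:
            # sinusoidal bump in a random direction perpendicular to the chord
            w = _perpendicular(direction)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            w = np.cos(phi) * w + np.sin(phi) * np.cross(direction, w)
            for k in range(1, n_waypoints + 1):
                t = k / (n_waypoints + 1)
                waypoints.append(start + direction * (length * t)
                                 + w * (tortuosity_amp * np.sin(np.pi * t)))
        branches.append(TreeBranch(bid, parent_id, start.copy(), end, radius, waypoints))
        if level + 1 < depth:
            # daughters deviate +/- theta from the parent axis inside the
            # plane spanned by (direction, normal); next plane is rotated 90deg
            for sign, ratio in zip((+1.0, -1.0), radius_ratios):
                d = np.cos(theta) * direction + sign * np.sin(theta) * normal
                d /= np.linalg.norm(d)
                child_normal = np.cross(d, normal)
                child_normal /= np.linalg.norm(child_normal)
                add_branch(bid, end, d, child_normal, radius * ratio,
                           length * length_decay, level + 1)
        return bid

    root = add_branch(None, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                      np.array([1.0, 0.0, 0.0]), root_radius, root_length, 0)
    return GroundTruthTree(branches=branches, root_ids=[root])


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def fit_grid(
    tree: GroundTruthTree,
    spacing: float | tuple[float, float, float],
    margin_mm: float = 3.0,
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Choose a grid (shape, origin) that contains the tree with a margin.

    The origin is aligned so the first root's start point falls exactly on a
    voxel center: axis-aligned root segments then rasterize with a voxel
    column on the centerline, which keeps 3-D thinning stable (a tube whose
    axis falls symmetrically between voxel centers can otherwise produce an
    even-sided cross-section with no medial column).
    """
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    lo, hi = tree.bounding_box()
    origin = lo - margin_mm
    if tree.root_ids:
        anchor = tree.branch(tree.root_ids[0]).start
        origin = anchor - np.ceil((anchor - origin) / sp) * sp
    shape = np.ceil((hi + margin_mm - origin) / sp).astype(int) + 1
    return tuple(int(s) for s in shape), tuple(float(o) for o in origin)


def voxelize_tree(
    tree: GroundTruthTree,
    spacing: float | tuple[float, float, float],
    shape: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelVolume:
    """Rasterize a tree into a binary mask.

    A voxel is foreground iff its center lies within the local branch radius
    of the centerline (branches carry a constant radius).  Every branch must
    fit inside the field of view with at least a 2-voxel margin.
    """
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    org = np.asarray(origin, dtype=float)
    shp = np.asarray(shape, dtype=int)
    grid = np.zeros(tuple(shp), dtype=bool)
    fov_lo = org + 2.0 * sp
    fov_hi = org + (shp - 3) * sp  # last center minus 2-voxel margin

    for b in tree.branches:
        poly = b.polyline()
        blo = poly.min(axis=0) - b.radius
        bhi = poly.max(axis=0) + b.radius
        if np.any(blo < fov_lo) or np.any(bhi > fov_hi):
            raise GeometryError(
                f"branch {b.branch_id} extends outside the field of view "
                f"(needs [{blo}, {bhi}] within [{fov_lo}, {fov_hi}])"
            )
        # densely sample the centerline, then mark voxels inside the tube
        seg = np.diff(poly, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        step = float(sp.min()) / 2.0
        samples = [poly[0]]
        for p0, d, L in zip(poly[:-1], seg, seg_len):
            n = max(int(np.ceil(L / step)), 1)
            t = np.arange(1, n + 1) / n
            samples.append(p0 + t[:, None] * d)
        samples = np.vstack(samples)

        ilo = np.maximum(np.floor((blo - org) / sp).astype(int), 0)
        ihi = np.minimum(np.ceil((bhi - org) / sp).astype(int) + 1, shp)
        ax = [np.arange(ilo[k], ihi[k]) * sp[k] + org[k] for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        centers = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(samples).query(centers, workers=-1)
        inside = (dist <= b.radius).reshape(X.shape)
        grid[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]] |= inside

    return VoxelVolume(grid=grid, spacing=tuple(sp), origin=tuple(org))


# --------------------------------------------------------------------------
# lesions and ventricles
# --------------------------------------------------------------------------

@dataclass
class EllipsoidSpec:
    """Axis-aligned ellipsoid: center (mm) and semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise InvalidParameterError(f"semi-axes must be positive, got {self.semi_axes}")


def _rasterize_ellipsoid(spec: EllipsoidSpec, sp, org, shp) -> np.ndarray:
    c = np.asarray(spec.center, dtype=float)
    a = np.asarray(spec.semi_axes, dtype=float)
    ax = [(np.arange(shp[k]) * sp[k] + org[k] - c[k]) / a[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return X * X + Y * Y + Z * Z <= 1.0


def _rasterize_box(lo, hi, sp, org, shp) -> np.ndarray:
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    ax = [(np.arange(shp[k]) * sp[k] + org[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return ((X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1])
            & (Z >= lo[2]) & (Z <= hi[2]))


def generate_lesion_set(
    shape: tuple[int, int, int],
    spacing: float | tuple[float, float, float],
    ventricle_spec,
    lesion_specs: list,
    seed: int = 0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[VoxelVolume, VoxelVolume]:
    """Rasterize a ventricle mask and a labelled lesion volume on one grid.

    ``ventricle_spec`` is an :class:`EllipsoidSpec`, a ``("box", lo, hi)``
    tuple (axis-aligned slab in mm), or None for an empty ventricle mask.
    ``lesion_specs`` are ellipsoids, labelled 1..n in order.  Lesions must be
    pairwise disjoint and disjoint from the ventricle mask after
    rasterization.  The seed is accepted for interface symmetry; placement
    itself is deterministic.
    """
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    org = np.asarray(origin, dtype=float)
    shp = np.asarray(shape, dtype=int)

    if ventricle_spec is None:
        vent = np.zeros(tuple(shp), dtype=bool)
    elif isinstance(ventricle_spec, EllipsoidSpec):
        vent = _rasterize_ellipsoid(ventricle_spec, sp, org, shp)
    elif isinstance(ventricle_spec, (tuple, list)) and ventricle_spec[0] == "box":
        vent = _rasterize_box(ventricle_spec[1], ventricle_spec[2], sp, org, shp)
    else:
        raise InvalidParameterError(f"unsupported ventricle spec: {ventricle_spec!r}")

    labels = np.zeros(tuple(shp), dtype=np.int32)
    for i, spec in enumerate(lesion_specs, start=1):
        les = _rasterize_ellipsoid(spec, sp, org, shp)
        if np.any(les & vent):
            raise GeometryError(f"lesion {i} overlaps the ventricle mask")
        if np.any(les & (labels > 0)):
            raise GeometryError(f"lesion {i} overlaps an earlier lesion")
        labels[les] = i

    return (
        VoxelVolume(grid=labels, spacing=tuple(sp), origin=tuple(org)),
        VoxelVolume(grid=vent, spacing=tuple(sp), origin=tuple(org)),
    )


# --------------------------------------------------------------------------
# cohorts with planted effects
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-design parameters for a simulated cohort.

    Defaults reproduce the observed cohort structure: age 68.5 (SD 11.1)
    years, covariate prevalences (female 50.3%, smoking 13.7%, alcohol 6.9%,
    diabetes 28.9%, hyperlipidemia 18.1%, hypertension 65.8%, cardiovascular
    history 17.3%), subject-mean hemodynamic features (flow 7.86 +/- 1.40
    mL/min, pressure 82.4 +/- 7.15 mmHg, pressure drop 0.51 +/- 0.09 mmHg)
    and bivariable effect sizes of those features on natural-log WMH volume
    (0.13 per mL/min, 0.05 per mmHg, 1.80 per mmHg).  Covariates and
    features are drawn independently, so the planted coefficients are both
    the marginal and the adjusted truths.
    """

    n_subjects: int = 2631
    beta_flow: float = 0.13         # per mL/min, on log-volume scale
    beta_pressure: float = 0.05     # per mmHg
    beta_drop: float = 1.80         # per mmHg
    noise_sd: float = 1.3           # residual SD of log volume
    seed: int = 0

    age_mean: float = 68.5
    age_sd: float = 11.1
    prevalences: dict = field(default_factory=lambda: {
        "sex": 0.503,               # 1 = female
        "smoking": 0.137,
        "alcohol": 0.0688,
        "diabetes": 0.289,
        "hyperlipidemia": 0.181,
        "hypertension": 0.658,
        "cardiovascular_history": 0.173,
    })
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.02, "sex": -0.10, "smoking": 0.10, "alcohol": 0.05,
        "diabetes": 0.15, "hyperlipidemia": 0.10, "hypertension": 0.30,
        "cardiovascular_history": 0.20,
    })
    flow_mean: float = 7.86
    flow_sd: float = 1.40
    pressure_mean: float = 82.4
    pressure_sd: float = 7.15
    drop_mean: float = 0.51
    drop_sd: float = 0.09
    intercept: float | None = None  # None: set so mean log-volume = log(6.58 mL)

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidParameterError("cohort needs at least 2 subjects")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        for k, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"prevalence {k}={p} outside [0, 1]")


COVARIATE_COLUMNS = [
    "sex", "smoking", "alcohol", "diabetes",
    "hyperlipidemia", "hypertension", "cardiovascular_history",
]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a subject table with a planted log-linear volume model.

    log total WMH volume (mL) = intercept + beta_flow * meanQ
    + beta_pressure * meanP + beta_drop * meanDP + covariate terms
    + N(0, noise_sd).  Deep WMH volume is a small Beta-distributed fraction
    of the total, matching the strong periventricular predominance of
    observed lesion loads.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    df = pd.DataFrame({"subject_id": np.arange(n)})
    df["age"] = rng.normal(spec.age_mean, spec.age_sd, n)
    for name in COVARIATE_COLUMNS:
        df[name] = (rng.random(n) < spec.prevalences[name]).astype(int)

    df["dbp"] = np.clip(rng.normal(78.0, 10.0, n), 50.0, 120.0)
    df["sbp"] = df["dbp"] + np.clip(rng.normal(45.0, 12.0, n), 10.0, None)

    df["mean_flow"] = rng.normal(spec.flow_mean, spec.flow_sd, n)
    df["mean_pressure"] = rng.normal(spec.pressure_mean, spec.pressure_sd, n)
    df["mean_pressure_drop"] = rng.normal(spec.drop_mean, spec.drop_sd, n)

    linpred = (
        spec.beta_flow * df["mean_flow"]
        + spec.beta_pressure * df["mean_pressure"]
        + spec.beta_drop * df["mean_pressure_drop"]
        + sum(spec.covariate_effects[c] * df[c] for c in ["age"] + COVARIATE_COLUMNS)
    )
    if spec.intercept is None:
        expected = (
            spec.beta_flow * spec.flow_mean
            + spec.beta_pressure * spec.pressure_mean
            + spec.beta_drop * spec.drop_mean
            + spec.covariate_effects["age"] * spec.age_mean
            + sum(spec.covariate_effects[c] * spec.prevalences[c] for c in COVARIATE_COLUMNS)
        )
        intercept = float(np.log(6.58)) - expected
    else:
        intercept = spec.intercept

    df["log_wmh_volume"] = intercept + linpred + rng.normal(0.0, spec.noise_sd, n)
    df["wmh_volume"] = np.exp(df["log_wmh_volume"])
    deep_frac = rng.beta(0.5, 8.0, n)
    df["dwmh_volume"] = df["wmh_volume"] * deep_frac
    df["pwmh_volume"] = df["wmh_volume"] - df["dwmh_volume"]
    return df


# --------------------------------------------------------------------------
# analytic network (no voxelization) and JSON round-trip
# --------------------------------------------------------------------------

def network_from_tree(tree: GroundTruthTree, points_per_branch: int = 21) -> VascularNetwork:
    """Build a solver-ready network directly from continuous geometry.

    Branch polylines are resampled to ``points_per_branch`` points with the
    exact constant radius; junction nodes are shared between parent and
    daughters.  This bypasses voxelization and skeletonization entirely and
    is the reference route for solver tests.
    """
    nodes: dict[int, np.ndarray] = {}
    node_of_point: dict[tuple, int] = {}

    def node_at(p: np.ndarray) -> int:
        key = tuple(np.round(p, 9))
        if key not in node_of_point:
            nid = len(node_of_point)
            node_of_point[key] = nid
            nodes[nid] = np.asarray(p, dtype=float)
        return node_of_point[key]

    branches = []
    for b in tree.branches:
        poly = b.polyline()
        # resample by arc length so lengths are preserved to high accuracy
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.linspace(0.0, s[-1], points_per_branch)
        pts = np.stack([np.interp(t, s, poly[:, k]) for k in range(3)], axis=1)
        u, v = node_at(poly[0]), node_at(poly[-1])
        branches.append(VesselBranch(
            branch_id=b.branch_id,
            points=pts,
            radii=np.full(len(pts), b.radius),
            node_ids=(u, v),
        ))
    net = VascularNetwork(branches=branches, nodes=nodes,
                          inflow_branch_ids=set(tree.root_ids))
    net.assign_roles()
    return net


def tree_to_json(tree: GroundTruthTree, path) -> None:
    payload = {
        "root_ids": list(tree.root_ids),
        "branches": [
            {
                "branch_id": b.branch_id,
                "parent_id": b.parent_id,
                "start": list(map(float, b.start)),
                "end": list(map(float, b.end)),
                "radius": float(b.radius),
                "waypoints": [list(map(float, w)) for w in b.waypoints],
            }
            for b in tree.branches
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def tree_from_json(path) -> GroundTruthTree:
    with open(path) as fh:
        payload = json.load(fh)
    branches = [
        TreeBranch(
            branch_id=d["branch_id"],
            parent_id=d["parent_id"],
            start=np.asarray(d["start"], dtype=float),
            end=np.asarray(d["end"], dtype=float),
            radius=float(d["radius"]),
            waypoints=[np.asarray(w, dtype=float) for w in d["waypoints"]],
        )
        for d in payload["branches"]
    ]
    return GroundTruthTree(branches=branches, root_ids=list(payload["root_ids"]))
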