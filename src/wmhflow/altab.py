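"""Adjacent-to-lesion terminal arterial branches (ALTABs).

A terminal arterial branch is an outlet branch thinner than the network
mean diameter.  For every (lesion, terminal branch) pair the shortest
boundary-to-boundary Euclidean distance is computed between their voxel
sets; the data-driven ALTAB threshold is the mean over lesions of the
distance to the nearest terminal branch, and a branch is an ALTAB for a
lesion when the pair distance does not exceed the threshold (inclusive
comparison).  Morphology and flow features of ALTABs are compared to other
terminal branches with two-sample t-tests at the Bonferroni level 0.05/6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyInputError, InvalidParameterError
from .graph import VascularNetwork
from .stats import safe_ttest
from .volume import VoxelVolume

__all__ = [
    "AltabAssignment",
    "partition_vessel_voxels",
    "lesion_branch_distances",
    "altab_threshold",
    "assign_altab",
    "sweep_thresholds",
    "compare_altab_features",
    "BONFERRONI_ALPHA",
]

BONFERRONI_ALPHA = 0.05 / 6  # six feature comparisons

ALTAB_FEATURES = [
    "length_mm", "tortuosity", "diameter_mm",
    "flow_ml_min", "p_mean_mmhg", "p_drop_mmhg",
]


def partition_vessel_voxels(vessel_mask: VoxelVolume, network: VascularNetwork) -> dict:
    """Assign every vessel voxel to the branch with the nearest centerline point.

    Returns branch_id -> (n, 3) world coordinates of that branch's voxels.
    The partition gives each branch the solid voxel set whose boundary the
    lesion distances are measured to.
    """
    vox = np.argwhere(vessel_mask.grid.astype(bool))
    if len(vox) == 0:
        raise EmptyInputError("vessel mask is empty")
    coords = vessel_mask.world(vox)
    pts, labels = [], []
    for b in network.branches:
        pts.append(b.points)
        labels.append(np.full(len(b.points), b.branch_id))
    pts = np.vstack(pts)
    labels = np.concatenate(labels)
    _, nearest = cKDTree(pts).query(coords, workers=-1)
    owner = labels[nearest]
    return {bid: coords[owner == bid] for bid in np.unique(owner)}


def lesion_branch_distances(
    lesions: list,
    lesion_volume: VoxelVolume,
    network: VascularNetwork,
    vessel_mask: VoxelVolume,
    branch_ids=None,
) -> pd.DataFrame:
    """Shortest Euclidean distance (mm) between each lesion and each branch.

    Distances are between voxel centers of the two solid voxel sets (the
    minimum over full sets equals the minimum over their boundaries, and is
    0 for overlapping sets); anisotropic spacing is honored because both
    sets are expressed in world coordinates.  Rows: lesion_id, columns:
    branch_id.
    """
    lesion_volume.require_same_grid(vessel_mask, "lesion/vessel")
    if not lesions:
        raise EmptyInputError("no lesions to measure")
    voxels_by_branch = partition_vessel_voxels(vessel_mask, network)
    ids = sorted(voxels_by_branch) if branch_ids is None else sorted(branch_ids)

    trees = {}
    for bid in list(ids):
        pts = voxels_by_branch.get(bid)
        if pts is None or len(pts) == 0:
            warnings.warn(f"branch {bid} owns no vessel voxels; excluded from distances")
            ids.remove(bid)
            continue
        trees[bid] = cKDTree(pts)

    rows = {}
    for les in lesions:
        if les.n_voxels == 0:
            warnings.warn(f"lesion {les.lesion_id} has no voxels; excluded")
            continue
        coords = lesion_volume.world(les.voxels)
        rows[les.lesion_id] = {
            bid: float(trees[bid].query(coords, workers=-1)[0].min()) for bid in ids
        }
    D = pd.DataFrame.from_dict(rows, orient="index")
    D.index.name = "lesion_id"
    D.columns.name = "branch_id"
    return D.sort_index()[sorted(D.columns)]


def altab_threshold(D: pd.DataFrame, override: float | None = None) -> float:
    """Mean over lesions of the distance to the nearest branch (mm).

    ``override`` substitutes a fixed threshold for sensitivity sweeps.
    """
    if override is not None:
        if override <= 0:
            raise InvalidParameterError("threshold override must be positive")
        return float(override)
    if D.shape[0] == 0 or D.shape[1] == 0:
        raise EmptyInputError("cannot derive a threshold without lesions and branches")
    return float(D.min(axis=1).mean())


@dataclass
class AltabAssignment:
    threshold_mm: float
    flags: pd.DataFrame            # lesion x branch booleans (distance <= T)
    branch_is_altab: pd.Series     # per terminal branch
    lesion_counts: pd.Series       # ALTABs per lesion
    lesion_category: pd.Series     # "0" | "1" | "2+"


def assign_altab(D: pd.DataFrame, threshold_mm: float, terminal_ids) -> AltabAssignment:
    """Flag ALTABs at an inclusive threshold and count them per lesion."""
    if threshold_mm <= 0:
        raise InvalidParameterError(f"threshold must be positive, got {threshold_mm}")
    cols = [c for c in D.columns if c in set(terminal_ids)]
    sub = D[cols]
    flags = sub <= threshold_mm
    counts = flags.sum(axis=1)
    category = pd.cut(counts, bins=[-0.5, 0.5, 1.5, np.inf], labels=["0", "1", "2+"])
    return AltabAssignment(
        threshold_mm=float(threshold_mm),
        flags=flags,
        branch_is_altab=flags.any(axis=0),
        lesion_counts=counts,
        lesion_category=pd.Series(category, index=counts.index, name="altab_category"),
    )


def sweep_thresholds(D: pd.DataFrame, terminal_ids, thresholds=None) -> pd.DataFrame:
    """ALTAB burden across a range of thresholds (default 6-20 mm, 1 mm steps)."""
    thresholds = np.arange(6.0, 21.0) if thresholds is None else np.asarray(thresholds, float)
    rows = []
    for t in thresholds:
        a = assign_altab(D, t, terminal_ids)
        rows.append({
            "threshold_mm": float(t),
            "n_altab_branches": int(a.branch_is_altab.sum()),
            "n_lesions_with_altab": int((a.lesion_counts > 0).sum()),
            "total_altab_flags": int(a.flags.values.sum()),
        })
    return pd.DataFrame(rows)


def compare_altab_features(
    features: pd.DataFrame,
    is_altab: pd.Series,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Two-sample t-tests of branch features between ALTABs and the rest.

    ``features`` is indexed by branch_id; columns beyond the canonical six
    are ignored.  Returns one row per feature with group means, SDs, t, p
    and significance at the Bonferroni-corrected level.
    """
    mask = is_altab.reindex(features.index).fillna(False).astype(bool)
    g1 = features[mask]
    g0 = features[~mask]
    if len(g1) == 0 or len(g0) == 0:
        warnings.warn("one comparison group is empty; no tests performed")
        return pd.DataFrame(columns=[
            "feature", "altab_mean", "altab_sd", "other_mean", "other_sd",
            "t", "p", "significant"])
    rows = []
    for feat in [f for f in ALTAB_FEATURES if f in features.columns]:
        a = g1[feat].dropna()
        o = g0[feat].dropna()
        t, p = safe_ttest(a, o)
        rows.append({
            "feature": feat,
            "altab_mean": float(a.mean()), "altab_sd": float(a.std(ddof=1)),
            "other_mean": float(o.mean()), "other_sd": float(o.std(ddof=1)),
            "t": float(t), "p": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
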