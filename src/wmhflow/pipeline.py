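"""End-to-end orchestration: masks + subject table -> result bundle.

Stages: network extraction (skeletonize, trace, prune), steady-flow solve,
lesion volumetry/classification, ALTAB spatial analysis, association
statistics.  Every output CSV declares its units in the header row; a
manifest records the configuration hash, seed and library versions so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .altab import (altab_threshold, assign_altab, compare_altab_features,
                    lesion_branch_distances, sweep_thresholds)
from .errors import InvalidParameterError
from .graph import (branch_table, build_network, identify_terminal_branches,
                    network_to_json, skeletonize)
from .hemo import FluidParams, HemoSolution, PressureBoundary, assemble_and_solve, summarize_subject
from .lesions import classify_all, label_lesions, lesion_table
from .stats import association_table, lesion_count_analysis
from .volume import VoxelVolume

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place (YAML-serializable)."""

    viscosity: float = 3.5e-3        # Pa*s
    p_terminal: float = 10.0         # mmHg
    alpha: float = 0.9
    beta: float = 0.6
    length_ratio: float = 50.0
    d_min: float = 0.1               # mm, structured-tree stop diameter
    inlet_mode: str = "flow-split"

    prune_length: float = 2.0        # mm
    snap_dist: float = 3.0           # mm
    min_lesion_voxels: int = 5
    pwmh_distance_mm: float = 10.0
    altab_threshold: float | str = "auto"
    sweep_min_mm: float = 6.0
    sweep_max_mm: float = 20.0

    predictors: list = field(default_factory=lambda: [
        "mean_flow", "mean_pressure", "mean_pressure_drop"])
    outcomes: list = field(default_factory=lambda: ["log_wmh_volume"])
    models: list = field(default_factory=lambda: ["bivariable", "model1", "model2"])

    seed: int = 0

    def __post_init__(self):
        for name in ("prune_length", "snap_dist", "pwmh_distance_mm", "d_min"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.altab_threshold != "auto" and float(self.altab_threshold) <= 0:
            raise InvalidParameterError("altab_threshold must be positive or 'auto'")

    def fluid_params(self) -> FluidParams:
        return FluidParams(viscosity=self.viscosity, p_terminal=self.p_terminal,
                           alpha=self.alpha, beta=self.beta,
                           length_ratio=self.length_ratio, d_min=self.d_min)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    vessel_mask: VoxelVolume,
    wmh_mask: VoxelVolume,
    ventricle_mask: VoxelVolume,
    subjects: pd.DataFrame,
    inflow_seeds,
    out_dir,
) -> dict:
    """Run every stage and write the result bundle to ``out_dir``.

    All three volumes must share one grid.  The first subject row supplies
    the cuff pressures for the imaging-subject flow solve; the full table
    feeds the association models (requiring the mean-feature and
    log-volume columns).  Returns the in-memory tables keyed by stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vessel_mask.require_same_grid(wmh_mask, "vessel/WMH")
    vessel_mask.require_same_grid(ventricle_mask, "vessel/ventricle")
    required = {"sbp", "dbp"}
    if subjects.empty or not required <= set(subjects.columns):
        raise InvalidParameterError(f"subject table must be non-empty with columns {required}")

    results: dict = {}

    # --- stage 1: network extraction -------------------------------------
    try:
        skel = skeletonize(vessel_mask)
        network = build_network(skel, vessel_mask, inflow_seeds,
                                prune_length=config.prune_length,
                                snap_dist=config.snap_dist)
    except Exception as exc:
        raise type(exc)(f"[extract-network] {exc}") from exc
    morpho = branch_table(network)
    network_to_json(network, out / "network.json")
    _write(morpho, out / "branches.csv")
    results["network"] = network
    results["branches"] = morpho

    # --- stage 2: steady flow solve ---------------------------------------
    try:
        row = subjects.iloc[0]
        boundary = PressureBoundary(sbp=float(row["sbp"]), dbp=float(row["dbp"]))
        solution = assemble_and_solve(network, boundary, config.fluid_params(),
                                      inlet_mode=config.inlet_mode)
    except Exception as exc:
        raise type(exc)(f"[solve-hemo] {exc}") from exc
    _write(solution.per_branch, out / "flow.csv")
    summary = pd.DataFrame([{**summarize_subject(solution),
                             "total_inflow_ml_min": solution.total_inflow_ml_min,
                             "map_mmhg": solution.map_mmhg}])
    _write(summary, out / "subject_summary.csv")
    results["flow"] = solution
    results["subject_summary"] = summary

    # --- stage 3: lesion metrics ------------------------------------------
    try:
        lesions = label_lesions(wmh_mask, min_lesion_voxels=config.min_lesion_voxels)
        if lesions:
            classify_all(lesions, ventricle_mask, wmh_mask,
                         threshold_mm=config.pwmh_distance_mm)
        ltab = lesion_table(lesions)
    except Exception as exc:
        raise type(exc)(f"[lesion-metrics] {exc}") from exc
    _write(ltab, out / "lesions.csv")
    results["lesions"] = ltab

    # --- stage 4: ALTAB spatial analysis ----------------------------------
    terminal_ids = identify_terminal_branches(network)
    if lesions and terminal_ids:
        try:
            D = lesion_branch_distances(lesions, wmh_mask, network, vessel_mask,
                                        branch_ids=sorted(terminal_ids))
            override = None if config.altab_threshold == "auto" else float(config.altab_threshold)
            T = altab_threshold(D, override=override)
            assignment = assign_altab(D, T, terminal_ids)
            sweep = sweep_thresholds(
                D, terminal_ids,
                thresholds=np.arange(config.sweep_min_mm, config.sweep_max_mm + 0.5))
            feats = morpho.set_index("branch_id").join(
                solution.per_branch.set_index("branch_id")
                [["flow_ml_min", "p_mean_mmhg", "p_drop_mmhg"]])
            terminal_feats = feats.loc[sorted(terminal_ids)]
            comparison = compare_altab_features(terminal_feats, assignment.branch_is_altab)
        except Exception as exc:
            raise type(exc)(f"[altab] {exc}") from exc
        D.to_csv(out / "distances_mm.csv", float_format="%.10g")
        assign_df = pd.DataFrame({
            "lesion_id": assignment.lesion_counts.index,
            "altab_count": assignment.lesion_counts.values,
            "altab_category": assignment.lesion_category.values,
        })
        _write(assign_df, out / "altab_assignment.csv")
        _write(sweep, out / "threshold_sweep.csv")
        _write(comparison, out / "altab_comparison.csv")
        results.update({"distances": D, "altab": assignment, "sweep": sweep,
                        "altab_comparison": comparison, "altab_threshold": T})
        # lesion-level category analysis
        merged = ltab.merge(assign_df, on="lesion_id", how="left")
        merged["altab_category"] = merged["altab_category"].fillna("0")
        counts = lesion_count_analysis(merged)
        _write(counts, out / "lesion_count_analysis.csv")
        results["lesion_count_analysis"] = counts

    # --- stage 5: association statistics ----------------------------------
    stat_cols = set(config.predictors) | set(config.outcomes)
    if stat_cols <= set(subjects.columns) and len(subjects) > 12:
        try:
            assoc = association_table(subjects, config.outcomes,
                                      config.predictors, tuple(config.models))
        except Exception as exc:
            raise type(exc)(f"[associate] {exc}") from exc
        _write(assoc, out / "associations.csv")
        results["associations"] = assoc

    manifest = {
        "config_sha256": config.digest(),
        "config": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix in (".csv", ".json")
                          and p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import networkx
    import scipy
    import skimage
    import statsmodels

    return {
        "wmhflow": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }
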