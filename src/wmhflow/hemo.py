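"""Steady network hemodynamics.

Each branch obeys the Hagen-Poiseuille relation Q = (P_in - P_out) / R with
R = 8 mu L / (pi r^4); junctions conserve flow and carry a single pressure;
every terminal outlet drains through the lumped resistance of a
self-similar structured tree (daughter radii alpha*r and beta*r, segment
length lambda*r, grown until the segment diameter falls below d_min) to a
fixed terminal pressure.  The inlet boundary is a virtual branch over all
inflow roots: total inflow splits across roots in proportion to
cross-sectional area, and the area-weighted mean of root inlet pressures is
set to the cuff-derived mean arterial pressure.  The resulting linear
system in the node pressures and the total inflow is solved sparsely.

Internally everything is SI (m, Pa, m^3/s); every reported surface uses
mmHg and mL/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sps
import scipy.sparse.linalg as spla

from .errors import InvalidParameterError, TopologyError
from .graph import VascularNetwork, VesselBranch

__all__ = [
    "MMHG_PA",
    "M3S_TO_ML_MIN",
    "FluidParams",
    "PressureBoundary",
    "HemoSolution",
    "map_from_cuff",
    "poiseuille_resistance",
    "branch_resistance",
    "structured_tree_resistance",
    "assemble_and_solve",
    "summarize_subject",
]

MMHG_PA = 133.322387415          # Pa per mmHg
M3S_TO_ML_MIN = 6.0e7            # mL/min per m^3/s


@dataclass(frozen=True)
class FluidParams:
    """Blood and outlet-tree parameters.

    viscosity
        Dynamic viscosity of whole blood, Pa*s.
    p_terminal
        Pressure at the distal end of every structured tree, mmHg
        (venous-side reference).
    alpha, beta
        Daughter-to-parent radius ratios of the structured tree
        (0 < beta <= alpha < 1).
    length_ratio
        Segment length as a multiple of its radius (lambda).
    d_min
        Structured-tree growth stops when a segment's diameter (mm) falls
        below this; that segment drains directly at ``p_terminal``.
    """

    viscosity: float = 3.5e-3
    p_terminal: float = 10.0
    alpha: float = 0.9
    beta: float = 0.6
    length_ratio: float = 50.0
    d_min: float = 0.1

    def __post_init__(self):
        if self.viscosity <= 0:
            raise InvalidParameterError("viscosity must be positive")
        if not (0.0 < self.beta <= self.alpha < 1.0):
            raise InvalidParameterError(
                f"need 0 < beta <= alpha < 1, got alpha={self.alpha}, beta={self.beta}")
        if self.length_ratio <= 0 or self.d_min <= 0:
            raise InvalidParameterError("length ratio and minimum diameter must be positive")


@dataclass(frozen=True)
class PressureBoundary:
    """Cuff pressures; MAP defaults to DBP + (SBP - DBP)/3."""

    sbp: float
    dbp: float
    map: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.sbp > self.dbp > 0:
            raise InvalidParameterError(f"need SBP > DBP > 0, got {self.sbp}/{self.dbp}")
        if self.map is None:
            object.__setattr__(self, "map", map_from_cuff(self.sbp, self.dbp))
        if not self.dbp <= self.map <= self.sbp:
            raise InvalidParameterError("MAP must lie between DBP and SBP")


def map_from_cuff(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from cuff readings: DBP + pulse pressure / 3."""
    if not sbp > dbp > 0:
        raise InvalidParameterError(f"need SBP > DBP > 0, got {sbp}/{dbp}")
    return dbp + (sbp - dbp) / 3.0


def poiseuille_resistance(length_mm: float, radius_mm: float, viscosity: float) -> float:
    """Hagen-Poiseuille resistance 8 mu L / (pi r^4), SI units (Pa*s/m^3)."""
    if radius_mm <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius_mm}")
    if length_mm <= 0:
        raise InvalidParameterError(f"length must be positive, got {length_mm}")
    L = length_mm * 1e-3
    r = radius_mm * 1e-3
    return 8.0 * viscosity * L / (np.pi * r ** 4)


def resistance_mmhg_min_per_ml(resistance_si: float) -> float:
    """Convert Pa*s/m^3 to mmHg*min/mL."""
    return resistance_si / MMHG_PA / 60.0 * 1e-6


def branch_resistance(branch: VesselBranch, viscosity: float) -> float:
    """Segmentwise Poiseuille resistance along a (possibly tapered) branch.

    Consecutive centerline points bound segments whose radius is the mean of
    the two endpoint radii; for a constant-radius branch this reduces
    exactly to 8 mu L / (pi r^4).
    """
    seg_len = np.linalg.norm(np.diff(branch.points, axis=0), axis=1) * 1e-3
    seg_rad = 0.5 * (branch.radii[:-1] + branch.radii[1:]) * 1e-3
    keep = seg_len > 0
    if not keep.any():
        raise InvalidParameterError(f"branch {branch.branch_id} has zero length")
    return float(np.sum(8.0 * viscosity * seg_len[keep] / (np.pi * seg_rad[keep] ** 4)))


def structured_tree_resistance(root_radius_mm: float, params: FluidParams) -> float:
    """Lumped resistance (Pa*s/m^3) of a structured outflow tree.

    Segments of radius r have length ``length_ratio * r`` and Poiseuille
    resistance; daughters (alpha*r, beta*r) combine in parallel and add in
    series.  Growth stops when the segment diameter drops below ``d_min``;
    such segments drain directly.  Radii live on the alpha^i beta^j lattice,
    which makes memoization over (i, j) exact.
    """
    if root_radius_mm <= 0:
        raise InvalidParameterError(f"root radius must be positive, got {root_radius_mm}")
    mu, lam = params.viscosity, params.length_ratio
    memo: dict[tuple[int, int], float] = {}

    def seg(r_mm: float) -> float:
        r = r_mm * 1e-3
        return 8.0 * mu * (lam * r) / (np.pi * r ** 4)

    def rec(i: int, j: int) -> float:
        key = (i, j)
        if key in memo:
            return memo[key]
        r = root_radius_mm * params.alpha ** i * params.beta ** j
        rs = seg(r)
        if 2.0 * r < params.d_min:
            memo[key] = rs
            return rs
        r1 = rec(i + 1, j)
        r2 = rec(i, j + 1)
        total = rs + r1 * r2 / (r1 + r2)
        memo[key] = total
        return total

    return rec(0, 0)


# --------------------------------------------------------------------------
# assembly and solve
# --------------------------------------------------------------------------

@dataclass
class HemoSolution:
    """Per-branch flow features plus subject-level means.

    ``per_branch`` columns: branch_id, role, flow_ml_min, p_in_mmhg,
    p_out_mmhg, p_mean_mmhg, p_drop_mmhg, reoriented.  Pressures follow the
    flow direction, so p_drop >= 0 (up to solver round-off).
    """

    per_branch: pd.DataFrame
    total_inflow_ml_min: float
    map_mmhg: float

    @property
    def mean_flow(self) -> float:
        return float(self.per_branch["flow_ml_min"].mean())

    @property
    def mean_pressure(self) -> float:
        return float(self.per_branch["p_mean_mmhg"].mean())

    @property
    def mean_pressure_drop(self) -> float:
        return float(self.per_branch["p_drop_mmhg"].mean())


def _reachability(network: VascularNetwork):
    adj: dict[int, list] = {n: [] for n in network.nodes}
    for b in network.branches:
        u, v = b.node_ids
        adj[u].append((v, b))
        adj[v].append((u, b))
    order, seen = [], set()
    stack = sorted(network.inflow_inlet_node_ids)
    seen.update(stack)
    branch_dir = {}
    while stack:
        u = stack.pop()
        order.append(u)
        for v, b in adj[u]:
            if b.branch_id not in branch_dir:
                branch_dir[b.branch_id] = (u, v)
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen, branch_dir


def assemble_and_solve(
    network: VascularNetwork,
    boundary: PressureBoundary,
    params: FluidParams | None = None,
    inlet_mode: str = "flow-split",
) -> HemoSolution:
    """Solve the steady network flow and report branch features.

    ``inlet_mode='flow-split'`` (default) is the virtual-branch boundary:
    inflow fractions proportional to root cross-sectional area plus an
    area-weighted mean inlet pressure equal to MAP.  ``'dirichlet'`` instead
    pins every root inlet pressure at MAP.
    """
    params = params or FluidParams()
    if inlet_mode not in ("flow-split", "dirichlet"):
        raise InvalidParameterError(f"unknown inlet mode {inlet_mode!r}")
    if not network.branches:
        raise TopologyError("network has no branches")
    if not network.inflow_inlet_node_ids:
        raise TopologyError("network has no inflow inlet nodes")

    seen, branch_dir = _reachability(network)
    missing = sorted(set(network.nodes) - seen)
    if missing:
        raise TopologyError(
            f"nodes {missing} are disconnected from the inflow roots; "
            "the linear system would be singular")

    node_ids = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n_nodes = len(node_ids)
    inlets = sorted(network.inflow_inlet_node_ids)
    terminals = network.terminal_node_ids()

    R = {b.branch_id: branch_resistance(b, params.viscosity) for b in network.branches}
    g_term = {}
    for t in terminals:
        b = network.branches_at(t)[0]
        g_term[t] = 1.0 / structured_tree_resistance(b.mean_radius, params)

    # inflow split fractions by root cross-sectional area
    inlet_branch = {}
    areas = {}
    for t in inlets:
        b = network.branches_at(t)[0]
        inlet_branch[t] = b
        areas[t] = np.pi * b.mean_radius ** 2
    total_area = sum(areas.values())
    frac = {t: areas[t] / total_area for t in inlets}

    map_pa = boundary.map * MMHG_PA
    pterm_pa = params.p_terminal * MMHG_PA

    # unknowns: node pressures (Pa) then Q_tot (m^3/s)
    A = sps.lil_matrix((n_nodes + 1, n_nodes + 1))
    rhs = np.zeros(n_nodes + 1)
    inlet_set = set(inlets)

    for n in node_ids:
        i = idx[n]
        if n in inlet_set:
            continue
        for b in network.branches_at(n):
            u, v = b.node_ids
            m = v if u == n else u
            g = 1.0 / R[b.branch_id]
            A[i, i] += g
            A[i, idx[m]] -= g
        if n in g_term:
            A[i, i] += g_term[n]
            rhs[i] += g_term[n] * pterm_pa

    if inlet_mode == "flow-split":
        for t in inlets:
            i = idx[t]
            b = inlet_branch[t]
            u, v = b.node_ids
            m = v if u == t else u
            g = 1.0 / R[b.branch_id]
            A[i, idx[t]] += g
            A[i, idx[m]] -= g
            A[i, n_nodes] -= frac[t]
            if t in g_term:  # a root that is also a free end (single tube)
                pass
        # area-weighted mean of inlet pressures equals MAP
        for t in inlets:
            A[n_nodes, idx[t]] += frac[t]
        rhs[n_nodes] = map_pa
    else:
        for t in inlets:
            i = idx[t]
            A[i, idx[t]] = 1.0
            rhs[i] = map_pa
        # define Q_tot as the sum of root branch flows
        A[n_nodes, n_nodes] = 1.0
        for t in inlets:
            b = inlet_branch[t]
            u, v = b.node_ids
            m = v if u == t else u
            g = 1.0 / R[b.branch_id]
            A[n_nodes, idx[t]] -= g
            A[n_nodes, idx[m]] += g

    try:
        x = spla.spsolve(A.tocsr(), rhs)
    except RuntimeError as exc:  # pragma: no cover - umfpack/superlu failure
        raise TopologyError(f"linear system could not be solved: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise TopologyError("singular linear system (disconnected or degenerate network)")

    P = {n: x[idx[n]] for n in node_ids}
    q_tot = x[n_nodes]

    rows = []
    for b in sorted(network.branches, key=lambda b: b.branch_id):
        u, v = branch_dir.get(b.branch_id, b.node_ids)
        q = (P[u] - P[v]) / R[b.branch_id]
        reoriented = False
        if q < 0:
            u, v = v, u
            q = -q
            reoriented = True
        p_in, p_out = P[u] / MMHG_PA, P[v] / MMHG_PA
        rows.append({
            "branch_id": b.branch_id,
            "role": b.role,
            "flow_ml_min": q * M3S_TO_ML_MIN,
            "p_in_mmhg": p_in,
            "p_out_mmhg": p_out,
            "p_mean_mmhg": 0.5 * (p_in + p_out),
            "p_drop_mmhg": p_in - p_out,
            "reoriented": reoriented,
        })
    per_branch = pd.DataFrame(rows)
    if per_branch["reoriented"].any():
        warnings.warn("some branches carried flow against the root-to-leaf "
                      "orientation and were re-oriented in the report")
    return HemoSolution(
        per_branch=per_branch,
        total_inflow_ml_min=float(q_tot * M3S_TO_ML_MIN),
        map_mmhg=boundary.map,
    )


def summarize_subject(solution: HemoSolution) -> dict:
    """Unweighted means of the three flow features over all branches."""
    if solution.per_branch.empty:
        raise InvalidParameterError("solution has no branches")
    return {
        "mean_flow_ml_min": solution.mean_flow,
        "mean_pressure_mmhg": solution.mean_pressure,
        "mean_pressure_drop_mmhg": solution.mean_pressure_drop,
    }
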