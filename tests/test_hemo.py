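"""Hemodynamic solver: resistances, boundary conditions, conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import (dense_network_oracle, naive_structured_tree,
                     symmetric_tree_closed_form)
from wmhflow import synthetic as syn
from wmhflow.errors import InvalidParameterError, TopologyError
from wmhflow.graph import VesselBranch, VascularNetwork
from wmhflow.hemo import (MMHG_PA, M3S_TO_ML_MIN, FluidParams, PressureBoundary,
                          assemble_and_solve, branch_resistance, map_from_cuff,
                          poiseuille_resistance, structured_tree_resistance,
                          summarize_subject)
from conftest import random_tree


class TestMapFromCuff:
    @pytest.mark.parametrize("sbp,dbp,expected", [
        (120.0, 80.0, 80.0 + 40.0 / 3.0),
        (150.0, 90.0, 110.0),
    ])
    def test_formula(self, sbp, dbp, expected):
        assert map_from_cuff(sbp, dbp) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_limit_approaches_pressure(self):
        assert map_from_cuff(100.0, 100.0 - 1e-9) == pytest.approx(100.0)

    @given(st.floats(40.0, 150.0), st.floats(1.0, 120.0))
    def test_map_between_dbp_and_sbp(self, dbp, pulse):
        sbp = dbp + pulse
        m = map_from_cuff(sbp, dbp)
        assert dbp < m < sbp

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InvalidParameterError):
            map_from_cuff(80.0, 120.0)


class TestPoiseuille:
    def test_reference_tube_flow(self):
        # L=10 mm, r=0.5 mm, mu=3.5e-3 Pa*s, dP=100 Pa
        R = poiseuille_resistance(10.0, 0.5, 3.5e-3)
        q = 100.0 / R
        expected = np.pi * 100.0 * (0.5e-3) ** 4 / (8.0 * 3.5e-3 * 10.0e-3)
        assert q == pytest.approx(expected, rel=1e-12)
        assert q * M3S_TO_ML_MIN == pytest.approx(4.2075, abs=5e-5)

    def test_linearity_in_length_and_r4_law(self):
        base = poiseuille_resistance(10.0, 0.5, 3.5e-3)
        assert poiseuille_resistance(20.0, 0.5, 3.5e-3) == pytest.approx(2 * base)
        assert poiseuille_resistance(10.0, 0.25, 3.5e-3) == pytest.approx(16 * base)

    def test_zero_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            poiseuille_resistance(10.0, 0.0, 3.5e-3)

    def test_segmentwise_resistance_reduces_to_closed_form(self):
        pts = np.array([[0, 0, z] for z in np.linspace(0, 10.0, 17)])
        b = VesselBranch(0, pts, np.full(17, 0.5), (0, 1))
        assert branch_resistance(b, 3.5e-3) == pytest.approx(
            poiseuille_resistance(10.0, 0.5, 3.5e-3), rel=1e-12)


class TestStructuredTree:
    def test_root_below_dmin_is_single_segment(self):
        p = FluidParams()
        r = 0.04  # diameter 0.08 mm < 0.1 mm
        expected = 8 * p.viscosity * (p.length_ratio * r * 1e-3) / (np.pi * (r * 1e-3) ** 4)
        assert structured_tree_resistance(r, p) == pytest.approx(expected, rel=1e-12)

    def test_memoized_equals_naive_recursion(self):
        p = FluidParams(alpha=0.75, beta=0.6)
        rng = np.random.default_rng(0)
        for r in rng.uniform(0.05, 0.3, size=10):
            assert structured_tree_resistance(r, p) == pytest.approx(
                naive_structured_tree(r, p), rel=1e-9)

    def test_symmetric_tree_matches_geometric_series(self):
        p = FluidParams(alpha=0.8, beta=0.8)
        for r in (0.08, 0.3, 1.0):
            assert structured_tree_resistance(r, p) == pytest.approx(
                symmetric_tree_closed_form(r, p), rel=1e-12)

    @given(st.floats(0.06, 2.0), st.floats(0.06, 2.0))
    def test_strictly_decreasing_in_root_radius(self, r1, r2):
        if abs(r1 - r2) < 1e-6:
            return
        p = FluidParams()
        lo, hi = sorted((r1, r2))
        assert structured_tree_resistance(lo, p) > structured_tree_resistance(hi, p)

    def test_divergent_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            FluidParams(alpha=1.0, beta=1.0)


def _single_tube_network(radius=0.5, length=10.0):
    pts = np.array([[0, 0, 0], [0, 0, length]])
    b = VesselBranch(0, pts, np.full(2, radius), (0, 1), role="inflow")
    return VascularNetwork(branches=[b], nodes={0: pts[0], 1: pts[1]},
                           inflow_branch_ids={0}, inflow_inlet_node_ids={0})


class TestAssembleAndSolve:
    def test_two_resistor_oracle(self):
        net = _single_tube_network()
        params = FluidParams()
        boundary = PressureBoundary(120.0, 80.0)
        sol = assemble_and_solve(net, boundary, params)
        r_tube = poiseuille_resistance(10.0, 0.5, params.viscosity)
        r_tree = structured_tree_resistance(0.5, params)
        q_expected = (boundary.map - params.p_terminal) * MMHG_PA / (r_tube + r_tree)
        assert sol.per_branch["flow_ml_min"][0] == pytest.approx(
            q_expected * M3S_TO_ML_MIN, rel=1e-10)
        assert sol.per_branch["p_in_mmhg"][0] == pytest.approx(boundary.map, rel=1e-12)

    def test_symmetric_bifurcation_splits_evenly(self):
        tree = syn.generate_arterial_tree(depth=2, root_radius=1.5,
                                          radius_ratios=(0.75, 0.75),
                                          tortuosity_amp=0.0)
        sol = assemble_and_solve(syn.network_from_tree(tree), PressureBoundary(120, 80))
        daughters = sol.per_branch[sol.per_branch["role"] == "terminal-outlet"]
        assert daughters["flow_ml_min"].iloc[0] == pytest.approx(
            daughters["flow_ml_min"].iloc[1], rel=1e-12)

    def test_terminal_outflow_sums_to_total_inflow(self, depth3_tree):
        net = syn.network_from_tree(depth3_tree)
        sol = assemble_and_solve(net, PressureBoundary(130, 85))
        terminal_nodes = set(net.terminal_node_ids())
        out = sol.per_branch[sol.per_branch["branch_id"].isin(
            {b.branch_id for b in net.branches if terminal_nodes & set(b.node_ids)})]
        assert out["flow_ml_min"].sum() == pytest.approx(
            sol.total_inflow_ml_min, rel=1e-9)

    def test_matches_dense_nodal_admittance_oracle(self, depth3_tree):
        net = syn.network_from_tree(depth3_tree)
        params = FluidParams()
        boundary = PressureBoundary(120, 80)
        sol = assemble_and_solve(net, boundary, params)
        _, q_tot, flows = dense_network_oracle(net, boundary.map, params)
        assert sol.total_inflow_ml_min == pytest.approx(q_tot * M3S_TO_ML_MIN, rel=1e-8)
        for _, row in sol.per_branch.iterrows():
            assert row["flow_ml_min"] == pytest.approx(
                abs(flows[row["branch_id"]]) * M3S_TO_ML_MIN, rel=1e-8)

    def test_pressures_bounded_and_monotone(self, depth3_tree):
        params = FluidParams()
        sol = assemble_and_solve(syn.network_from_tree(depth3_tree),
                                 PressureBoundary(120, 80), params)
        pb = sol.per_branch
        assert (pb["p_drop_mmhg"] >= -1e-9).all()
        assert not pb["reoriented"].any()
        assert pb["p_out_mmhg"].min() >= params.p_terminal - 1e-9
        assert pb["p_in_mmhg"].max() <= sol.map_mmhg + 1e-9

    def test_viscosity_scaling_inverts_flow(self, depth3_tree):
        net = syn.network_from_tree(depth3_tree)
        boundary = PressureBoundary(120, 80)
        q1 = assemble_and_solve(net, boundary, FluidParams()).total_inflow_ml_min
        q2 = assemble_and_solve(net, boundary,
                                FluidParams(viscosity=7.0e-3)).total_inflow_ml_min
        assert q1 / q2 == pytest.approx(2.0, rel=1e-9)

    def test_invariant_to_rigid_translation(self, depth3_tree):
        net1 = syn.network_from_tree(depth3_tree)
        net2 = syn.network_from_tree(depth3_tree)
        for b in net2.branches:
            b.points = b.points + np.array([100.0, -50.0, 25.0])
        for n in net2.nodes:
            net2.nodes[n] = net2.nodes[n] + np.array([100.0, -50.0, 25.0])
        s1 = assemble_and_solve(net1, PressureBoundary(120, 80))
        s2 = assemble_and_solve(net2, PressureBoundary(120, 80))
        np.testing.assert_allclose(s1.per_branch["flow_ml_min"],
                                   s2.per_branch["flow_ml_min"], rtol=1e-12)

    def test_invariant_to_branch_reordering(self, depth3_tree):
        net1 = syn.network_from_tree(depth3_tree)
        net2 = syn.network_from_tree(depth3_tree)
        net2.branches = net2.branches[::-1]
        s1 = assemble_and_solve(net1, PressureBoundary(120, 80))
        s2 = assemble_and_solve(net2, PressureBoundary(120, 80))
        m1 = s1.per_branch.set_index("branch_id")["flow_ml_min"]
        m2 = s2.per_branch.set_index("branch_id")["flow_ml_min"]
        np.testing.assert_allclose(m1.sort_index(), m2.sort_index(), rtol=1e-12)

    def test_dirichlet_mode_pins_inlet_pressure(self, depth3_tree):
        sol = assemble_and_solve(syn.network_from_tree(depth3_tree),
                                 PressureBoundary(120, 80), inlet_mode="dirichlet")
        inflow = sol.per_branch[sol.per_branch["role"] == "inflow"]
        assert inflow["p_in_mmhg"].iloc[0] == pytest.approx(map_from_cuff(120, 80))

    def test_disconnected_component_raises(self):
        net = _single_tube_network()
        stray = VesselBranch(1, np.array([[50, 50, 0], [50, 50, 10.0]]),
                             np.full(2, 0.5), (2, 3))
        net.branches.append(stray)
        net.nodes[2] = stray.points[0]
        net.nodes[3] = stray.points[1]
        with pytest.raises(TopologyError):
            assemble_and_solve(net, PressureBoundary(120, 80))


class TestSummaries:
    def test_single_branch_summary_is_itself(self):
        sol = assemble_and_solve(_single_tube_network(), PressureBoundary(120, 80))
        s = summarize_subject(sol)
        assert s["mean_flow_ml_min"] == pytest.approx(sol.per_branch["flow_ml_min"][0])

    def test_summary_is_arithmetic_mean(self, depth3_tree):
        sol = assemble_and_solve(syn.network_from_tree(depth3_tree),
                                 PressureBoundary(120, 80))
        s = summarize_subject(sol)
        assert s["mean_pressure_drop_mmhg"] == pytest.approx(
            sol.per_branch["p_drop_mmhg"].mean(), rel=1e-12)
        # recomputation from the per-branch table is exact
        assert s == summarize_subject(sol)
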