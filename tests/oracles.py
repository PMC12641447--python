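"""Independent oracles used by the test suite.

These deliberately avoid the package's solution paths: the network flow
oracle assembles a dense nodal-admittance system with numpy, the
structured-tree oracles use naive unmemoized recursion and the symmetric
geometric-series closed form.
"""

import numpy as np

MMHG = 133.322387415


def dense_network_oracle(network, map_mmhg, params):
    """Brute-force dense solve of the virtual-inlet network flow problem.

    Unknowns: node pressures (Pa) and total inflow (m^3/s).  Branch
    resistances use the plain Hagen-Poiseuille form 8 mu L / (pi r^4) with
    the branch's polyline length and mean radius.  Returns
    (pressures: dict node->Pa, q_tot, flows: dict branch_id->m^3/s signed
    first-node -> second-node).
    """
    from wmhflow.hemo import structured_tree_resistance

    mu = params.viscosity
    node_ids = sorted(network.nodes)
    pos = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    R = {}
    for b in network.branches:
        L = np.linalg.norm(np.diff(b.points, axis=0), axis=1).sum() * 1e-3
        r = float(b.radii.mean()) * 1e-3
        R[b.branch_id] = 8.0 * mu * L / (np.pi * r ** 4)

    inlets = sorted(network.inflow_inlet_node_ids)
    terminals = set(network.terminal_node_ids())
    areas = {}
    for t in inlets:
        b = network.branches_at(t)[0]
        areas[t] = np.pi * b.mean_radius ** 2
    fr = {t: areas[t] / sum(areas.values()) for t in inlets}

    A = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    for b in network.branches:
        u, v = b.node_ids
        g = 1.0 / R[b.branch_id]
        for a, c in ((u, v), (v, u)):
            if a in inlets:
                continue
            A[pos[a], pos[a]] += g
            A[pos[a], pos[c]] -= g
    for t in terminals:
        b = network.branches_at(t)[0]
        gt = 1.0 / structured_tree_resistance(b.mean_radius, params)
        A[pos[t], pos[t]] += gt
        rhs[pos[t]] += gt * params.p_terminal * MMHG
    for t in inlets:
        b = network.branches_at(t)[0]
        u, v = b.node_ids
        m = v if u == t else u
        g = 1.0 / R[b.branch_id]
        A[pos[t], pos[t]] += g
        A[pos[t], pos[m]] -= g
        A[pos[t], n] -= fr[t]
    for t in inlets:
        A[n, pos[t]] += fr[t]
    rhs[n] = map_mmhg * MMHG

    x = np.linalg.solve(A, rhs)
    P = {nid: x[pos[nid]] for nid in node_ids}
    flows = {b.branch_id: (P[b.node_ids[0]] - P[b.node_ids[1]]) / R[b.branch_id]
             for b in network.branches}
    return P, x[n], flows


def naive_structured_tree(root_radius_mm, params):
    """Unmemoized full recursion over the structured tree (small trees only)."""
    mu, lam = params.viscosity, params.length_ratio

    def rec(r):
        rs = 8.0 * mu * (lam * r * 1e-3) / (np.pi * (r * 1e-3) ** 4)
        if 2.0 * r < params.d_min:
            return rs
        r1 = rec(params.alpha * r)
        r2 = rec(params.beta * r)
        return rs + r1 * r2 / (r1 + r2)

    return rec(root_radius_mm)


def symmetric_tree_closed_form(root_radius_mm, params):
    """Geometric-series sum for the alpha == beta structured tree.

    Level k holds 2^k identical segments of radius r*alpha^k in parallel;
    levels stack in series until the segment diameter falls below d_min.
    """
    assert params.alpha == params.beta
    mu, lam, a = params.viscosity, params.length_ratio, params.alpha
    total = 0.0
    k = 0
    while True:
        r = root_radius_mm * a ** k
        seg = 8.0 * mu * (lam * r * 1e-3) / (np.pi * (r * 1e-3) ** 4)
        total += seg / (2.0 ** k)
        if 2.0 * r < params.d_min:
            return total
        k += 1


def ols_normal_equations(X, y):
    """Plain normal-equations OLS: beta_hat = (X'X)^-1 X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
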