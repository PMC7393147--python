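"""Independent reference implementations used only to check the package.

Everything here deliberately avoids the production code path: linear
programs are solved with scipy.optimize.linprog (HiGHS) on a dense
stoichiometric matrix assembled by hand, GPR rules are evaluated with a
small ast walker, and hierarchical clustering is a literal O(n^3)
agglomeration loop.
"""

from __future__ import annotations

import ast

import numpy as np
from scipy.optimize import linprog


def build_lp(model):
    """Dense S matrix, variable bounds, and index maps from a cobra model."""
    met_idx = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_idx = {r.id: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_idx), len(rxn_idx)))
    bounds = []
    for r in model.reactions:
        j = rxn_idx[r.id]
        for met, coef in r.metabolites.items():
            S[met_idx[met.id], j] = coef
        bounds.append((r.lower_bound, r.upper_bound))
    return S, bounds, rxn_idx


def oracle_optimize(model, objective, extra_bounds=None, extra_rows=None, sense="max"):
    """Solve max/min c.v s.t. S.v = 0, lb <= v <= ub with scipy HiGHS.

    ``objective`` maps reaction id -> coefficient; ``extra_bounds`` maps
    reaction id -> (lb, ub) overrides; ``extra_rows`` is a list of
    (coef dict, lower, upper) linear constraints.  Returns
    (status, objective value, flux dict).
    """
    S, bounds, rxn_idx = build_lp(model)
    if extra_bounds:
        for rid, bd in extra_bounds.items():
            bounds[rxn_idx[rid]] = bd
    c = np.zeros(len(rxn_idx))
    for rid, coef in objective.items():
        c[rxn_idx[rid]] = coef
    A_ub, b_ub = [], []
    if extra_rows:
        for coefs, lo, hi in extra_rows:
            row = np.zeros(len(rxn_idx))
            for rid, coef in coefs.items():
                row[rxn_idx[rid]] = coef
            if hi is not None:
                A_ub.append(row)
                b_ub.append(hi)
            if lo is not None:
                A_ub.append(-row)
                b_ub.append(-lo)
    res = linprog(
        -c if sense == "max" else c,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return "infeasible", float("nan"), {}
    value = float(c @ res.x)
    return "optimal", value, {rid: float(res.x[j]) for rid, j in rxn_idx.items()}


def oracle_fva(model, objective, fraction):
    """Per-reaction min/max holding c.v >= fraction * optimum."""
    status, opt, _ = oracle_optimize(model, objective)
    assert status == "optimal"
    keep = [(objective, fraction * opt, None)]
    out = {}
    for rxn in model.reactions:
        lo = oracle_optimize(model, {rxn.id: 1.0}, extra_rows=keep, sense="min")[1]
        hi = oracle_optimize(model, {rxn.id: 1.0}, extra_rows=keep, sense="max")[1]
        out[rxn.id] = (lo, hi)
    return out


def eval_gpr(rule: str, deleted: set[str]) -> bool:
    """Evaluate a boolean gene rule with ``deleted`` genes absent."""
    if not rule or not rule.strip():
        return True

    def walk(node):
        if isinstance(node, ast.Expression):
            return walk(node.body)
        if isinstance(node, ast.BoolOp):
            vals = [walk(v) for v in node.values]
            return all(vals) if isinstance(node.op, ast.And) else any(vals)
        if isinstance(node, ast.Name):
            return node.id not in deleted
        raise ValueError(f"unexpected GPR node {node!r}")

    return walk(ast.parse(rule, mode="eval"))


def oracle_gene_knockout_bounds(model, gene_id):
    """Bound overrides closing every reaction whose rule fails without the gene."""
    overrides = {}
    for rxn in model.reactions:
        rule = rxn.gene_reaction_rule
        if rule and not eval_gpr(rule, {gene_id}):
            overrides[rxn.id] = (0.0, 0.0)
    return overrides


def oracle_complete_linkage(matrix: np.ndarray, labels: list[str]):
    """Literal agglomeration: merge the closest pair under the max-distance rule.

    Returns the merge history as frozensets of labels with merge heights.
    """
    dist = {
        (i, j): float(np.linalg.norm(matrix[i] - matrix[j]))
        for i in range(len(labels)) for j in range(i + 1, len(labels))
    }
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}

    def d(ca, cb):
        return max(
            dist[(min(i, j), max(i, j))]
            for i in range(len(labels)) if labels[i] in ca
            for j in range(len(labels)) if labels[j] in cb
        )

    merges = []
    keys = list(clusters)
    while len(keys) > 1:
        best = min(
            ((a, b) for ai, a in enumerate(keys) for b in keys[ai + 1:]),
            key=lambda ab: d(clusters[ab[0]], clusters[ab[1]]),
        )
        height = d(clusters[best[0]], clusters[best[1]])
        merged = clusters[best[0]] | clusters[best[1]]
        merges.append((merged, height))
        new_key = max(keys) + 1
        clusters[new_key] = merged
        for k in best:
            keys.remove(k)
            del clusters[k]
        keys.append(new_key)
    return merges
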