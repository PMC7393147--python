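import cobra
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smpcom import fva, maximize_member, phase_plane, robustness_scan, solve_community_fba
from smpcom.fba import _ensure_target_exchange

from conftest import stoich_residual
from _oracle import oracle_fva, oracle_optimize


def chain_model(fixed_uptake=10.0):
    """EX_s (fixed) -> conversion -> biomass: a zero-degree-of-freedom chain."""
    m = cobra.Model("chain")
    s_e = cobra.Metabolite("s_e", compartment="e")
    a_c = cobra.Metabolite("a_c", compartment="c")
    ex = cobra.Reaction("EX_s_e", lower_bound=-fixed_uptake, upper_bound=-fixed_uptake)
    ex.add_metabolites({s_e: -1})
    t = cobra.Reaction("T", lower_bound=0, upper_bound=1000)
    t.add_metabolites({s_e: -1, a_c: 1})
    bio = cobra.Reaction("BIO", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({a_c: -1})
    m.add_reactions([ex, t, bio])
    m.objective = "BIO"
    return m


def test_community_optimum_matches_oracle(community):
    sol = solve_community_fba(community)
    status, opt, _ = oracle_optimize(
        community.model, {rid: 1.0 for rid in community.biomass.values()}
    )
    assert status == "optimal"
    assert sol.optimal
    assert sol.objective_value == pytest.approx(opt, abs=1e-8)


def test_solution_is_steady_state_and_in_bounds(community):
    sol = solve_community_fba(community)
    assert stoich_residual(community.model, sol.fluxes) < 1e-6
    for rxn in community.model.reactions:
        v = float(sol.fluxes[rxn.id])
        assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9


def test_objective_equals_member_growth_sum(community):
    sol = solve_community_fba(community)
    assert sol.objective_value == pytest.approx(sum(sol.member_growth.values()), abs=1e-9)


def test_infeasible_community_reports_empty_fluxes(community):
    # demanding growth far beyond the photon budget is unsatisfiable
    for rid in community.biomass.values():
        community.model.reactions.get_by_id(rid).lower_bound = 500.0
    sol = solve_community_fba(community)
    assert sol.status == "infeasible"
    assert sol.fluxes.empty


def test_maximize_member_matches_oracle(community):
    for member in community.members:
        sol = maximize_member(community, member, partner_floor=0.0)
        partner = [m for m in community.members if m != member][0]
        status, opt, _ = oracle_optimize(
            community.model,
            {community.biomass[member]: 1.0},
            extra_bounds={community.biomass[partner]: (0.0, 1000.0)},
        )
        assert sol.growth(member) == pytest.approx(opt, abs=1e-8)


def test_maximize_member_floor_above_partner_max_is_infeasible(community):
    sol = maximize_member(community, "H", partner_floor=1e5)
    assert sol.status == "infeasible"


def test_fva_collapses_at_full_optimum_on_chain():
    m = chain_model()
    ranges = fva(m, fraction=1.0).ranges
    for rid, v in (("EX_s_e", -10.0), ("T", 10.0), ("BIO", 10.0)):
        assert ranges.loc[rid, "minimum"] == pytest.approx(v, abs=1e-8)
        assert ranges.loc[rid, "maximum"] == pytest.approx(v, abs=1e-8)


def test_fva_relaxation_widens_ranges(community):
    tight = fva(community, fraction=1.0).ranges
    loose = fva(community, fraction=0.0).ranges
    assert (loose["minimum"] <= tight["minimum"] + 1e-8).all()
    assert (loose["maximum"] >= tight["maximum"] - 1e-8).all()


@pytest.mark.parametrize("fraction", [1.0, 0.5])
def test_fva_matches_oracle(community, fraction):
    ranges = fva(community, fraction=fraction).ranges
    oracle = oracle_fva(
        community.model, {rid: 1.0 for rid in community.biomass.values()}, fraction
    )
    for rid, (lo, hi) in oracle.items():
        assert ranges.loc[rid, "minimum"] == pytest.approx(lo, abs=1e-6), rid
        assert ranges.loc[rid, "maximum"] == pytest.approx(hi, abs=1e-6), rid


def test_fva_rejects_bad_fraction(community):
    with pytest.raises(ValueError):
        fva(community, fraction=1.5)


def test_robustness_zero_flux_transfer_is_neutral(community):
    table = robustness_scan(community)
    # amino acid and acetate transfers carry no flux at the parsimonious optimum
    for met in ("aa_e", "ac_e"):
        sub = table[(table.metabolite == met)]
        assert not sub.vital.any()
        base = solve_community_fba(community)
        for _, row in sub.iterrows():
            for member in community.members:
                assert row[f"growth_{member}"] == pytest.approx(
                    base.member_growth[member], abs=1e-6
                )


def test_robustness_sole_carbon_transfer_is_vital(community):
    table = robustness_scan(community)
    sucr = table[(table.metabolite == "sucr_e") & (table["mode"] == "zero")]
    assert sucr.vital.all()
    assert (sucr["growth_H"] < 1e-6).all()


def test_robustness_doubling_nonbinding_bound_changes_nothing(community):
    base = solve_community_fba(community)
    table = robustness_scan(community)
    doubled = table[table["mode"] == "double"].set_index("metabolite")
    for met in ("sucr_e", "nh4_e", "co2_e"):
        for member in community.members:
            assert doubled.loc[met, f"growth_{member}"] == pytest.approx(
                base.member_growth[member], abs=1e-6
            )


def test_phase_plane_zero_rate_reproduces_optimum(community):
    base = solve_community_fba(community)
    pp = phase_plane(community, "ac_e", [0.0, 0.5])
    assert pp.growth.loc[0.0, "community_growth"] == pytest.approx(
        base.objective_value, abs=1e-8
    )


def test_phase_plane_growth_nonincreasing(community):
    grid = [0.0, 0.25, 0.5, 1.0, 1.5, 2.0]
    pp = phase_plane(community, "ac_e", grid)
    growth = pp.growth["community_growth"].to_numpy()
    assert (np.diff(growth) <= 1e-8).all()


def test_phase_plane_matches_fine_grid_oracle(community):
    """Coarse sweep values coincide with an oracle run at 10x resolution."""
    coarse = [0.0, 0.5, 1.0]
    pp = phase_plane(community, "ac_e", coarse)
    work, ex_id = _ensure_target_exchange(community, "ac_e")
    fine = [round(0.05 * i, 10) for i in range(21)]
    for rate in fine:
        status, opt, _ = oracle_optimize(
            work.model,
            {rid: 1.0 for rid in work.biomass.values()},
            extra_bounds={ex_id: (rate, 1000.0)},
        )
        if rate in coarse:
            assert pp.growth.loc[rate, "community_growth"] == pytest.approx(opt, abs=1e-8)
    # infeasible points are recorded, not raised
    pp_far = phase_plane(community, "ac_e", [0.0, 1e4])
    assert not pp_far.growth.loc[1e4, "feasible"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    rxn_index=st.integers(min_value=0, max_value=22),
    shrink=st.floats(min_value=0.0, max_value=1.0),
)
def test_tightening_bounds_never_increases_optimum(rxn_index, shrink):
    """Monotonicity: shrinking any reaction's flux window cannot help growth."""
    from smpcom.synthetic import make_toy_community

    cm = make_toy_community()
    base = solve_community_fba(cm).objective_value
    rxn = sorted(cm.model.reactions, key=lambda r: r.id)[rxn_index]
    lb, ub = rxn.bounds
    mid_lo = lb + (1 - shrink) * 0.5 * (ub - lb)
    mid_hi = ub - (1 - shrink) * 0.5 * (ub - lb)
    rxn.bounds = (mid_lo, max(mid_lo, mid_hi))
    tightened = solve_community_fba(cm)
    if tightened.optimal:
        assert tightened.objective_value <= base + 1e-7
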