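import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smpcom import (
    classify_syntrophy,
    compare_flux_expression,
    expression_to_pathway,
    normalize_by_growth,
    pathway_aggregate,
    pathway_fold_change,
    sample_fluxes,
    solve_fba,
    subsystem_index,
)
from smpcom.synthetic import simulate_expression

from test_fba import chain_model
from _oracle import oracle_fva


def test_sampling_is_deterministic_under_seed(community):
    s1 = sample_fluxes(community, n=40, seed=3, thinning=10)
    s2 = sample_fluxes(community, n=40, seed=3, thinning=10)
    assert (s1.samples.values == s2.samples.values).all()
    s3 = sample_fluxes(community, n=40, seed=4, thinning=10)
    assert not (s1.samples.values == s3.samples.values).all()


def test_samples_lie_inside_released_fva_ranges(community):
    samples = sample_fluxes(community, n=60, seed=5, thinning=10).samples
    objective = {rid: 1.0 for rid in community.biomass.values()}
    ranges = oracle_fva(community.model, objective, fraction=0.0)
    for rid in samples.columns:
        lo, hi = ranges[rid]
        assert samples[rid].min() >= lo - 1e-6, rid
        assert samples[rid].max() <= hi + 1e-6, rid


def test_samples_satisfy_steady_state(community):
    from conftest import stoich_residual

    samples = sample_fluxes(community, n=20, seed=6, thinning=10).samples
    kept = set(samples.columns)
    for _, row in samples.head(5).iterrows():
        # residual over the reduced network (blocked reactions removed)
        worst = 0.0
        for met in community.model.metabolites:
            total = sum(
                coef * float(row[rxn.id])
                for rxn in met.reactions if rxn.id in kept
                for m2, coef in rxn.metabolites.items() if m2 is met
            )
            worst = max(worst, abs(total))
        assert worst < 1e-6


def test_degenerate_polytope_gives_constant_samples():
    m = chain_model(fixed_uptake=10.0)  # zero degrees of freedom
    samples = sample_fluxes(m, n=15, seed=1, thinning=5).samples
    assert np.allclose(samples["BIO"], 10.0, atol=1e-6)
    assert np.allclose(samples.std(axis=0), 0.0, atol=1e-6)


def test_sampling_mean_converges_to_polytope_centroid():
    """A one-degree-of-freedom chain has centroid at the interval midpoint."""
    import cobra

    m = chain_model(fixed_uptake=10.0)
    m.reactions.EX_s_e.bounds = (-10.0, 0.0)  # free the single degree of freedom
    samples = sample_fluxes(m, n=3000, seed=2, thinning=10).samples
    assert samples["BIO"].mean() == pytest.approx(5.0, abs=0.5)


def test_normalize_by_growth():
    v = pd.Series({"a": 0.5, "b": 0.0})
    out = normalize_by_growth(v, 0.1)
    assert out["a"] == pytest.approx(5.0)
    assert out["b"] == 0.0
    with pytest.raises(ValueError):
        normalize_by_growth(v, 0.0)


def test_pathway_aggregate_sums_and_scales():
    normed = pd.Series({"r1": 2.0, "r2": 3.0, "r3": 10.0, "r4": -10.0})
    index = {"small": ["r1", "r2"], "anchor": ["r3"], "neg": ["r4"]}
    act = pathway_aggregate(normed, index)
    assert act.table.loc["small", "pathway_flux"] == pytest.approx(5.0)
    assert act.table.loc["small", "sn"] == pytest.approx(0.5)
    # the largest-magnitude subsystem anchors Sn at +/-1
    assert act.table.loc["anchor", "sn"] == pytest.approx(1.0)
    assert act.table.loc["neg", "sn"] == pytest.approx(-1.0)
    assert act.sn.abs().max() <= 1.0
    assert act.burden.sum() == pytest.approx(1.0)


def test_pathway_aggregate_sign_variant_collapses_to_signs():
    normed = pd.Series({"r1": -4.0, "r2": 2.0})
    index = {"a": ["r1"], "b": ["r2"]}
    act = pathway_aggregate(normed, index, sign_variant=True)
    assert act.table.loc["a", "sn"] == -1.0
    assert act.table.loc["b", "sn"] == 1.0


def test_pathway_aggregate_requires_subsystems():
    with pytest.raises(ValueError):
        pathway_aggregate(pd.Series(dtype=float), {})


@pytest.mark.parametrize(
    "mono,co,cls,direction",
    [
        (0.2, 0.6, "syntrophically_active", "uptake-side"),
        (0.4, 0.4, "neutrally_active", "none"),
        (0.6, 0.2, "deactivated", "secretion-side"),
        (-0.2, -0.6, "syntrophically_active", "secretion-side"),
    ],
)
def test_classify_syntrophy_cases(mono, co, cls, direction):
    call = classify_syntrophy(
        pd.Series({"s": mono}), pd.Series({"s": co}), epsilon=0.05
    )[0]
    assert call.syntrophy_class == cls
    assert call.direction == direction


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    sn_mono=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    sn_co=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    scale=st.floats(min_value=0.05, max_value=1.0),
)
def test_classification_invariant_under_common_rescaling(sn_mono, sn_co, scale):
    """Scaling both Sn vectors (and epsilon) by one constant changes nothing."""
    idx = ["a", "b", "c"]
    a, b = pd.Series(sn_mono, index=idx), pd.Series(sn_co, index=idx)
    eps = 0.05
    base = classify_syntrophy(a, b, epsilon=eps)
    scaled = classify_syntrophy(a * scale, b * scale, epsilon=eps * scale)
    assert [c.syntrophy_class for c in base] == [c.syntrophy_class for c in scaled]


def test_fold_change_cases():
    mono = pathway_aggregate(pd.Series({"r1": 1.0, "r2": 0.0}), {"a": ["r1"], "b": ["r2"]})
    co = pathway_aggregate(pd.Series({"r1": 1.0, "r2": 1.0}), {"a": ["r1"], "b": ["r2"]})
    out = pathway_fold_change(mono, co)
    assert out.loc["b", "flag"] == "activated_from_zero"
    assert np.isnan(out.loc["b", "fold_change"])
    same = pathway_fold_change(mono, mono)
    assert same.loc["a", "fold_change"] == pytest.approx(1.0)


def test_expression_concentrated_on_one_subsystem(phototroph):
    genes = [g.id for g in phototroph.genes]
    expr = pd.DataFrame(0.0, index=genes, columns=["s1"])
    expr.loc["gP1"] = 100.0  # all reads on the carbon-fixation gene
    median, shares = expression_to_pathway(expr, phototroph)
    assert median["Carbon fixation"] == pytest.approx(1.0)


def test_expression_uniform_reads_track_gene_counts(phototroph):
    genes = [g.id for g in phototroph.genes]
    expr = pd.DataFrame(1.0, index=genes, columns=["s1", "s2"])
    median, _ = expression_to_pathway(expr, phototroph)
    # Transport holds two genes (gP4, gP5) of five: burden 2/5
    assert median["Transport"] == pytest.approx(0.4)
    assert median.sum() == pytest.approx(1.0)


def test_expression_requires_gene_overlap(phototroph):
    expr = pd.DataFrame([[1.0]], index=["not_a_gene"], columns=["s1"])
    with pytest.raises(ValueError, match="no gene ids"):
        expression_to_pathway(expr, phototroph)


def test_concordance_recovers_flux_burden_at_low_noise(spec, phototroph_fed, phototroph):
    """Synthetic expression generated from fluxes at sigma = 0.1 correlates
    with the pathway flux burden at Pearson > 0.8."""
    sol = solve_fba(phototroph_fed)
    expr = simulate_expression(phototroph, sol.fluxes, sigma=0.1, seed=spec.seed,
                               n_replicates=3)
    median, _ = expression_to_pathway(expr, phototroph)
    act = pathway_aggregate(
        normalize_by_growth(sol.fluxes, sol.objective_value),
        subsystem_index(phototroph), member="P",
    )
    flux_burden = act.burden.loc[median.index]  # genic subsystems only
    result = compare_flux_expression(flux_burden, median)
    assert result["pearson_r"] > 0.8


def test_compare_flux_expression_identity_and_negation():
    v = pd.Series({"a": 0.1, "b": 0.5, "c": 0.4})
    assert compare_flux_expression(v, v)["pearson_r"] == pytest.approx(1.0)
    flipped = -v + v.mean() * 2  # affine negation keeps it a valid vector
    assert compare_flux_expression(v, flipped)["pearson_r"] == pytest.approx(-1.0)


def test_compare_flux_expression_matches_textbook_formulas():
    """Pearson r and the two-sided t statistic recomputed from first principles."""
    rng = np.random.default_rng(0)
    x = pd.Series(rng.random(6), index=list("abcdef"))
    y = pd.Series(rng.random(6), index=list("abcdef"))
    result = compare_flux_expression(x, y)
    xm, ym = x - x.mean(), y - y.mean()
    r_direct = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    assert result["pearson_r"] == pytest.approx(r_direct, abs=1e-12)

    a = pd.DataFrame(rng.random((6, 4)), index=x.index)
    b = pd.DataFrame(rng.random((6, 4)), index=x.index)
    tests = compare_flux_expression(x, y, a, b)["tests"]
    i = "c"
    na, nb = 4, 4
    sp = ((na - 1) * a.loc[i].var(ddof=1) + (nb - 1) * b.loc[i].var(ddof=1)) / (na + nb - 2)
    t_direct = (a.loc[i].mean() - b.loc[i].mean()) / np.sqrt(sp * (1 / na + 1 / nb))
    assert tests.loc[i, "t"] == pytest.approx(t_direct, abs=1e-12)
    assert {"p_value", "p_adjusted"} <= set(tests.columns)
    assert (tests["p_adjusted"] >= tests["p_value"] - 1e-12).all()


def test_compare_flux_expression_needs_replicates_for_tests():
    v = pd.Series({"a": 0.1, "b": 0.5, "c": 0.4})
    one_col = pd.DataFrame({"r1": v})
    assert compare_flux_expression(v, v, one_col, one_col)["tests"] is None
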