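"""Flux sampling, pathway-level normalization, syntrophy classes, and
flux-expression concordance.

The pathway statistics work on growth-normalized fluxes: each reaction
flux is divided by the member's growth rate, summed (signed) within its
subsystem, and the per-subsystem totals are scaled by the largest
absolute total so the normalized subsystem activity Sn lies in [-1, 1].
Comparing Sn between monoculture and coculture classifies each pathway
as syntrophically active (more flux in coculture), neutrally active, or
deactivated.  Expression tables aggregated over the same subsystems give
the transcriptional counterpart (burden shares) for concordance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import cobra
from cobra.exceptions import Infeasible
from cobra.flux_analysis import find_blocked_reactions
from cobra.sampling import ACHRSampler, OptGPSampler
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommunityModel

UNASSIGNED = "unassigned"
DEFAULT_EPSILON = 0.05

__all__ = [
    "FluxSampleSet",
    "PathwayActivity",
    "SyntrophyCall",
    "subsystem_index",
    "sample_fluxes",
    "normalize_by_growth",
    "pathway_aggregate",
    "classify_syntrophy",
    "pathway_fold_change",
    "expression_to_pathway",
    "compare_flux_expression",
]


@dataclass
class FluxSampleSet:
    """Uniform samples of the steady-state flux polytope."""

    samples: pd.DataFrame  # rows samples, columns reaction ids
    seed: int
    thinning: int
    method: str

    @property
    def mean(self) -> pd.Series:
        return self.samples.mean(axis=0)


@dataclass
class PathwayActivity:
    """Per-subsystem normalized flux for one member under one condition."""

    member: str
    condition: str  # monoculture | coculture
    table: pd.DataFrame  # index subsystem; columns pathway_flux, sn, burden, n_reactions

    @property
    def sn(self) -> pd.Series:
        return self.table["sn"]

    @property
    def burden(self) -> pd.Series:
        return self.table["burden"]


@dataclass
class SyntrophyCall:
    subsystem: str
    member: str
    syntrophy_class: str  # syntrophically_active | neutrally_active | deactivated
    direction: str  # uptake-side | secretion-side | none


def subsystem_index(model: cobra.Model, reactions: list[str] | None = None) -> dict[str, list[str]]:
    """Map subsystem -> reaction ids; unannotated reactions pool as 'unassigned'."""
    keep = set(reactions) if reactions is not None else None
    index: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if keep is not None and rxn.id not in keep:
            continue
        index.setdefault(rxn.subsystem or UNASSIGNED, []).append(rxn.id)
    return index


def sample_fluxes(
    target: CommunityModel | cobra.Model,
    n: int,
    seed: int,
    thinning: int = 100,
    warmup: int | None = None,
    method: str = "optgp",
) -> FluxSampleSet:
    """Uniformly sample the flux solution space of a (reduced) model.

    The model is first reduced by removing blocked reactions (FVA with
    the objective released), then sampled with a hit-and-run scheme
    (OptGP by default, ACHR available) with the stated thinning.  Fixed
    seeds give identical sample matrices.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    model = (target.model if isinstance(target, CommunityModel) else target).copy()
    if np.isnan(model.slim_optimize()):
        raise Infeasible("model is infeasible; nothing to sample")
    blocked = find_blocked_reactions(model, open_exchanges=False)
    model.remove_reactions(list(blocked), remove_orphans=True)
    try:
        if method == "optgp":
            sampler = OptGPSampler(model, processes=1, thinning=thinning, seed=seed)
        elif method == "achr":
            sampler = ACHRSampler(model, thinning=thinning, seed=seed)
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        samples = sampler.sample(n)
    except ValueError as exc:
        if "single point" not in str(exc):
            raise
        # zero-degree-of-freedom polytope: the unique flux vector, n times
        from cobra.flux_analysis import flux_variability_analysis

        point = flux_variability_analysis(model, fraction_of_optimum=0.0)["minimum"]
        samples = pd.DataFrame(
            np.tile(point.values, (n, 1)), columns=point.index
        )
    return FluxSampleSet(samples=samples, seed=seed, thinning=thinning, method=method)


def normalize_by_growth(fluxes: pd.Series, mu: float) -> pd.Series:
    """Divide a member's flux vector by its growth rate (per-growth fluxes)."""
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    return fluxes / mu


def pathway_aggregate(
    normalized: pd.Series,
    index: dict[str, list[str]],
    member: str = "model",
    condition: str = "monoculture",
    sign_variant: bool = False,
) -> PathwayActivity:
    """Signed per-subsystem flux totals, Sn in [-1, 1], and burden shares.

    Default Sn = pathway flux / max_k |pathway flux| (continuous scaling
    into [-1, 1]).  ``sign_variant`` switches to the degenerate
    flux/|flux| form, which collapses Sn onto {-1, 0, 1}.
    Burden = |pathway flux| / sum_k |pathway flux|.
    """
    if not index:
        raise ValueError("empty subsystem index")
    rows = []
    for subsystem, rxn_ids in sorted(index.items()):
        present = [r for r in rxn_ids if r in normalized.index]
        total = float(normalized.loc[present].sum()) if present else 0.0
        rows.append({"subsystem": subsystem, "pathway_flux": total, "n_reactions": len(present)})
    table = pd.DataFrame(rows).set_index("subsystem")
    abs_flux = table["pathway_flux"].abs()
    if sign_variant:
        table["sn"] = np.sign(table["pathway_flux"])
    else:
        scale = abs_flux.max()
        table["sn"] = table["pathway_flux"] / scale if scale > 0 else 0.0
    total_abs = abs_flux.sum()
    table["burden"] = abs_flux / total_abs if total_abs > 0 else 0.0
    return PathwayActivity(member=member, condition=condition, table=table)


def classify_syntrophy(
    sn_mono: pd.Series,
    sn_co: pd.Series,
    epsilon: float = DEFAULT_EPSILON,
    member: str = "model",
) -> list[SyntrophyCall]:
    """Per-subsystem syntrophy class from mono- vs coculture Sn.

    |Sn_co| > |Sn_mono| + eps -> syntrophically active (pathway gained
    flux in the community); the mirror case is deactivated; otherwise
    neutrally active.  Direction reports which way Sn moved: toward
    positive = uptake-side (mass flowing from the pool into the network),
    toward negative = secretion-side.
    """
    sn_mono, sn_co = sn_mono.align(sn_co, join="inner")
    calls = []
    for subsystem in sn_mono.index:
        a, b = float(sn_mono[subsystem]), float(sn_co[subsystem])
        if abs(b) > abs(a) + epsilon:
            cls = "syntrophically_active"
        elif abs(b) < abs(a) - epsilon:
            cls = "deactivated"
        else:
            cls = "neutrally_active"
        if cls == "neutrally_active" or b == a:
            direction = "none"
        else:
            direction = "uptake-side" if b > a else "secretion-side"
        calls.append(SyntrophyCall(subsystem=subsystem, member=member,
                                   syntrophy_class=cls, direction=direction))
    return calls


def pathway_fold_change(
    mono: PathwayActivity, co: PathwayActivity, zero_tol: float = 1e-9
) -> pd.DataFrame:
    """Coculture/monoculture ratio of burden shares per subsystem.

    Subsystems essentially inactive in monoculture are flagged
    ``activated_from_zero`` instead of being divided.
    """
    if set(mono.table.index) != set(co.table.index):
        raise ValueError("activities cover different subsystem sets")
    out = pd.DataFrame(index=mono.table.index.copy())
    out["burden_mono"] = mono.burden
    out["burden_co"] = co.burden.reindex(out.index)
    zero = out["burden_mono"] < zero_tol
    out["fold_change"] = np.where(zero, np.nan, out["burden_co"] / out["burden_mono"])
    out["flag"] = np.where(
        zero & (out["burden_co"] >= zero_tol), "activated_from_zero",
        np.where(zero, "inactive", ""),
    )
    return out


def gene_subsystems(model: cobra.Model) -> dict[str, set[str]]:
    """Map gene id -> subsystems of the reactions its GPR participates in."""
    out: dict[str, set[str]] = {}
    for rxn in model.reactions:
        sub = rxn.subsystem or UNASSIGNED
        for gene in rxn.genes:
            out.setdefault(gene.id, set()).add(sub)
    return out


def expression_to_pathway(
    expression: pd.DataFrame, model: cobra.Model
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate a gene x sample count table into subsystem burden shares.

    A gene appearing in several subsystems counts in each.  Returns the
    per-sample median burden (Series over subsystems) and the full
    subsystem x sample burden table.
    """
    mapping = gene_subsystems(model)
    common = [g for g in expression.index if g in mapping]
    if not common:
        raise ValueError("expression table shares no gene ids with the model")
    subsystems = sorted({s for g in common for s in mapping[g]})
    agg = pd.DataFrame(0.0, index=subsystems, columns=expression.columns)
    for gene in common:
        for sub in mapping[gene]:
            agg.loc[sub] += expression.loc[gene].astype(float)
    shares = agg / agg.sum(axis=0)
    return shares.median(axis=1), shares


def compare_flux_expression(
    flux_burden: pd.Series,
    expression_burden: pd.Series,
    replicates_a: pd.DataFrame | None = None,
    replicates_b: pd.DataFrame | None = None,
) -> dict:
    """Concordance between pathway flux burden and expression burden.

    Pearson correlation across common subsystems; when two replicate
    burden tables (subsystem x replicate, e.g. monoculture vs coculture
    expression) are supplied, a per-subsystem two-sided t-test is run
    with raw and Benjamini-Hochberg adjusted p-values side by side.
    """
    flux_burden, expression_burden = flux_burden.align(expression_burden, join="inner")
    if len(flux_burden) < 3:
        raise ValueError("need at least 3 common subsystems for a correlation")
    r, p = stats.pearsonr(flux_burden.values, expression_burden.values)
    result = {"pearson_r": float(r), "pearson_p": float(p),
              "n_subsystems": int(len(flux_burden)), "tests": None}
    if replicates_a is not None and replicates_b is not None:
        if replicates_a.shape[1] < 2 or replicates_b.shape[1] < 2:
            return result  # not enough replicates to test
        a, b = replicates_a.align(replicates_b, join="inner", axis=0)
        tstat, pvals = stats.ttest_ind(a.values, b.values, axis=1)
        reject, p_adj, *_ = multipletests(pvals, method="fdr_bh")
        result["tests"] = pd.DataFrame(
            {"t": tstat, "p_value": pvals, "p_adjusted": p_adj, "significant_bh": reject},
            index=a.index,
        )
    return result
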