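"""Linear-programming core: community FBA, FVA, robustness, phase planes.

The community objective is the unweighted sum of member biomass fluxes
(joint growth maximization).  Because flux balance problems are highly
degenerate, every reported flux vector is the parsimonious one: the
objective is first fixed at its optimum and the total absolute flux is
then minimized, so exchange profiles are unique up to genuinely
alternate optima.  FVA ranges are available to quantify that remaining
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import cobra
from cobra.exceptions import Infeasible, OptimizationError
from cobra.flux_analysis import flux_variability_analysis, pfba

from .community import CommunityModel

FEASIBILITY_TOL = 1e-9
ZERO_TOL = 1e-6
LETHALITY_THRESHOLD = 1e-6  # h^-1; below this a member counts as not growing

__all__ = [
    "FluxSolution",
    "FvaResult",
    "PhasePlane",
    "solve_community_fba",
    "solve_fba",
    "maximize_member",
    "fva",
    "robustness_scan",
    "phase_plane",
    "LETHALITY_THRESHOLD",
]


@dataclass
class FluxSolution:
    """A steady-state flux vector plus per-member growth rates."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series
    member_growth: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def growth(self, member: str) -> float:
        return self.member_growth.get(member, float("nan"))


_INFEASIBLE = lambda: FluxSolution("infeasible", float("nan"), pd.Series(dtype=float))


def _pfba_solution(model: cobra.Model) -> FluxSolution | None:
    """Parsimonious FBA on the model's current objective; None if infeasible."""
    try:
        sol = pfba(model, fraction_of_optimum=1.0)
    except (Infeasible, OptimizationError):
        return None
    coefs = {r.id: r.objective_coefficient for r in model.reactions if r.objective_coefficient}
    objective = float(sum(c * sol.fluxes[rid] for rid, c in coefs.items()))
    return FluxSolution("optimal", objective, sol.fluxes)


def solve_fba(model: cobra.Model) -> FluxSolution:
    """Parsimonious FBA of a single-organism model on its own objective."""
    sol = _pfba_solution(model)
    if sol is None:
        return _INFEASIBLE()
    sol.member_growth = {model.id or "model": sol.objective_value}
    return sol


def solve_community_fba(cm: CommunityModel) -> FluxSolution:
    """Maximize the summed member biomass fluxes, with parsimony tie-break."""
    with cm.model as m:
        sol = _pfba_solution(m)
    if sol is None:
        return _INFEASIBLE()
    sol.member_growth = {
        member: float(sol.fluxes[rid]) for member, rid in cm.biomass.items()
    }
    return sol


def maximize_member(cm: CommunityModel, member: str, partner_floor: float = 0.0) -> FluxSolution:
    """Maximize one member's growth subject to partner growth >= ``partner_floor``.

    This resolves the allocation degeneracy of the joint objective: a
    member's achievable growth is judged against the best the community
    can do *for it* while the partner remains feasible at the floor.
    """
    if partner_floor < 0:
        raise ValueError("partner_floor must be >= 0")
    if member not in cm.biomass:
        raise KeyError(f"unknown member {member!r}")
    if any(
        partner_floor > cm.model.reactions.get_by_id(rid).upper_bound
        for other, rid in cm.biomass.items() if other != member
    ):
        return _INFEASIBLE()
    with cm.model as m:
        for other, rid in cm.biomass.items():
            if other != member:
                m.reactions.get_by_id(rid).lower_bound = partner_floor
        m.objective = m.reactions.get_by_id(cm.biomass[member])
        sol = _pfba_solution(m)
    if sol is None:
        return _INFEASIBLE()
    sol.member_growth = {
        mbr: float(sol.fluxes[rid]) for mbr, rid in cm.biomass.items()
    }
    return sol


@dataclass
class FvaResult:
    """Per-reaction flux ranges at a stated objective-retention fraction."""

    fraction: float
    ranges: pd.DataFrame  # index reaction id, columns minimum/maximum

    def bounds(self, reaction_id: str) -> tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])

    def to_tsv(self, path) -> None:
        self.ranges.to_csv(path, sep="\t")


def fva(cm: CommunityModel | cobra.Model, fraction: float = 1.0,
        reactions: list[str] | None = None) -> FvaResult:
    """Flux variability holding the objective at >= ``fraction`` x optimum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    model = cm.model if isinstance(cm, CommunityModel) else cm
    with model as m:
        if np.isnan(m.slim_optimize()):
            raise Infeasible("model is infeasible; FVA undefined")
        ranges = flux_variability_analysis(
            m, reaction_list=reactions, fraction_of_optimum=fraction
        )
    return FvaResult(fraction=fraction, ranges=ranges)


def robustness_scan(
    cm: CommunityModel,
    exchanged: list[str] | None = None,
    lethality_threshold: float = LETHALITY_THRESHOLD,
) -> pd.DataFrame:
    """Sensitivity of member growth to each exchanged metabolite.

    For every SMP metabolite (default: all with a transfer reaction), the
    transfer bounds are set to zero flux and to twice the flux magnitude
    the transfer carries at the parsimonious optimum; the community is
    re-solved each time.  An exchange is *vital* when zeroing it drives
    either member below the lethality threshold.
    """
    base = solve_community_fba(cm)
    if not base.optimal:
        raise Infeasible("community model is infeasible")
    mets = exchanged or sorted({met for met, _m in cm.transfers})
    rows = []
    for met in mets:
        rxn_ids = cm.transfer_ids_for(met)
        if not rxn_ids:
            raise KeyError(f"metabolite {met!r} has no transfer reactions")
        for mode in ("zero", "double"):
            with cm.model as m:
                for rid in rxn_ids:
                    rxn = m.reactions.get_by_id(rid)
                    if mode == "zero":
                        rxn.bounds = (0.0, 0.0)
                    else:
                        mag = 2.0 * abs(float(base.fluxes.get(rid, 0.0)))
                        rxn.bounds = (max(rxn.lower_bound, -mag), min(rxn.upper_bound, mag))
                sol = _pfba_solution(m)
            growths = (
                {mbr: float(sol.fluxes[rid]) for mbr, rid in cm.biomass.items()}
                if sol is not None
                else {mbr: 0.0 for mbr in cm.members}
            )
            rows.append({
                "metabolite": met,
                "mode": mode,
                "feasible": sol is not None,
                **{f"growth_{mbr}": growths[mbr] for mbr in cm.members},
            })
    df = pd.DataFrame(rows)
    zero = df[df["mode"] == "zero"].set_index("metabolite")
    vital = {
        met: any(zero.loc[met, f"growth_{mbr}"] < lethality_threshold for mbr in cm.members)
        for met in mets
    }
    df["vital"] = df["metabolite"].map(vital)
    return df


@dataclass
class PhasePlane:
    """Growth response and exchange profile along a forced-production sweep."""

    target: str
    growth: pd.DataFrame     # index rate; columns per-member growth, community growth, feasible
    exchanges: pd.DataFrame  # index rate; columns transfer reaction ids

    def to_tsv(self, path) -> None:
        self.growth.join(self.exchanges, how="left").to_csv(path, sep="\t")


def _ensure_target_exchange(cm: CommunityModel, target: str) -> tuple[CommunityModel, str]:
    """A community copy whose ``target`` SMP metabolite has an environment exchange."""
    work = cm.copy()
    if target not in work.smp_metabolites:
        # accept member extracellular metabolites too: route them via the pool
        holders = [m for m in work.members
                   if (m + "__" + target) in [x.id for x in work.model.metabolites]]
        if not holders:
            raise KeyError(f"{target!r} is neither an SMP metabolite nor extracellular in any member")
        stem = target[:-2] if target.endswith("_e") else target
        smp_met = cobra.Metabolite(f"{stem}_smp", compartment="smp")
        work.model.add_metabolites([smp_met])
        work.smp_metabolites[target] = smp_met.id
        for member in holders:
            rxn = cobra.Reaction(f"T_{member}__{target}", lower_bound=0.0, upper_bound=1000.0)
            rxn.add_metabolites({
                work.model.metabolites.get_by_id(member + "__" + target): -1.0,
                smp_met: 1.0,
            })
            rxn.subsystem = "SMP transfer"
            work.model.add_reactions([rxn])
            work.transfers[(target, member)] = rxn.id
    if target not in work.environment_exchanges:
        smp_id = work.smp_metabolites[target]
        ex = cobra.Reaction(f"EX_{smp_id}", lower_bound=0.0, upper_bound=1000.0)
        ex.add_metabolites({work.model.metabolites.get_by_id(smp_id): -1.0})
        ex.subsystem = "SMP exchange"
        work.model.add_reactions([ex])
        work.environment_exchanges[target] = ex.id
    return work, work.environment_exchanges[target]


def phase_plane(cm: CommunityModel, target: str, grid: list[float],
                probe_floor: float | None = None) -> PhasePlane:
    """Community growth and exchange fluxes while forcing target secretion >= r.

    Infeasible grid points are recorded with ``feasible = False`` and NaN
    growths rather than raised.  With ``probe_floor`` set, each grid
    point additionally records ``both_can_grow``: whether a solution
    exists in which *every* member grows at least that fast.  The probe
    is separate from the reported fluxes because the parsimonious joint
    optimum is free to park one member at zero growth even when
    solutions supporting both exist.
    """
    work, ex_id = _ensure_target_exchange(cm, target)
    transfer_ids = sorted(work.transfers.values())
    growth_rows, exchange_rows = [], []
    ex_ub = work.model.reactions.get_by_id(ex_id).upper_bound
    for rate in grid:
        if rate > ex_ub:  # demanded rate exceeds the exchange capacity
            probe_col = {} if probe_floor is None else {"both_can_grow": False}
            growth_rows.append({"rate": rate, "feasible": False, "community_growth": np.nan,
                                **{f"growth_{mbr}": np.nan for mbr in work.members},
                                **probe_col})
            exchange_rows.append({"rate": rate, **{rid: np.nan for rid in transfer_ids}})
            continue
        can_grow = None
        if probe_floor is not None:
            with work.model as m:
                m.reactions.get_by_id(ex_id).lower_bound = float(rate)
                for rid in work.biomass.values():
                    m.reactions.get_by_id(rid).lower_bound = probe_floor
                can_grow = not np.isnan(m.slim_optimize())
        with work.model as m:
            ex = m.reactions.get_by_id(ex_id)
            ex.lower_bound = float(rate)
            sol = _pfba_solution(m)
        probe_col = {} if can_grow is None else {"both_can_grow": can_grow}
        if sol is None:
            growth_rows.append({"rate": rate, "feasible": False, "community_growth": np.nan,
                                **{f"growth_{mbr}": np.nan for mbr in work.members},
                                **probe_col})
            exchange_rows.append({"rate": rate, **{rid: np.nan for rid in transfer_ids}})
            continue
        growths = {mbr: float(sol.fluxes[rid]) for mbr, rid in work.biomass.items()}
        growth_rows.append({
            "rate": rate, "feasible": True,
            "community_growth": sum(growths.values()),
            **{f"growth_{mbr}": growths[mbr] for mbr in work.members},
            **probe_col,
        })
        exchange_rows.append({"rate": rate, **{rid: float(sol.fluxes[rid]) for rid in transfer_ids}})
    growth = pd.DataFrame(growth_rows).set_index("rate")
    exchanges = pd.DataFrame(exchange_rows).set_index("rate")
    return PhasePlane(target=target, growth=growth, exchanges=exchanges)
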