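"""Community production capability scans, yields, and exchange clustering.

A metabolite counts as *producible* when the community can be forced to
secrete it above 1e-2 mmol gDW^-1 h^-1 while both members keep growing.
The scan sweeps a forced-secretion grid over [0, 2] mmol gDW^-1 h^-1
(the production window of interest for value-added compounds) and takes
the largest feasible grid rate as the maximum production rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist

from .community import SEP, CommunityModel
from .fba import LETHALITY_THRESHOLD, phase_plane
from .model_io import formula_weight

FEASIBILITY_THRESHOLD = 1e-2  # mmol gDW^-1 h^-1
DEFAULT_GRID = np.round(np.linspace(0.0, 2.0, 101), 10)

__all__ = [
    "ProductionResult",
    "YieldResult",
    "default_grid",
    "scan_metabolite",
    "scan_all_metabolites",
    "compute_yield",
    "cluster_exchanges",
    "FEASIBILITY_THRESHOLD",
]


def default_grid() -> list[float]:
    return [float(r) for r in DEFAULT_GRID]


@dataclass
class ProductionResult:
    """Feasibility and growth response of forcing one metabolite's secretion."""

    metabolite: str
    feasible: bool
    max_rate: float
    growth: pd.DataFrame     # per grid rate: member growths, community growth, feasible
    exchanges: pd.DataFrame  # per grid rate: transfer fluxes


@dataclass
class YieldResult:
    """Mass yield of a product per gram dry weight of community biomass."""

    metabolite: str
    yield_g_per_gdw: float
    production_flux: float
    community_growth: float
    formula_weight_g_per_mmol: float


def scan_metabolite(
    cm: CommunityModel,
    metabolite: str,
    grid: list[float] | None = None,
    lethality_threshold: float = LETHALITY_THRESHOLD,
) -> ProductionResult:
    """Force secretion of one metabolite along ``grid`` and classify feasibility.

    A grid rate is good when some flux solution at that forced rate lets
    *both* members grow above the lethality threshold (probed with
    floored biomasses); the growth/exchange tables still report the
    parsimonious joint optimum, which may idle a member.
    """
    grid = default_grid() if grid is None else list(grid)
    if grid != sorted(grid) or grid[0] != 0.0:
        raise ValueError("grid must be ascending and start at 0")
    pp = phase_plane(cm, metabolite, grid, probe_floor=lethality_threshold)
    ok = pp.growth["feasible"].astype(bool) & pp.growth["both_can_grow"].astype(bool)
    feasible_rates = [r for r, good in ok.items() if good and r > FEASIBILITY_THRESHOLD]
    max_rate = max(feasible_rates) if feasible_rates else 0.0
    return ProductionResult(
        metabolite=metabolite,
        feasible=bool(feasible_rates),
        max_rate=float(max_rate),
        growth=pp.growth,
        exchanges=pp.exchanges,
    )


def scan_all_metabolites(
    cm: CommunityModel,
    grid: list[float] | None = None,
    metabolites: list[str] | None = None,
    lethality_threshold: float = LETHALITY_THRESHOLD,
) -> list[ProductionResult]:
    """Production scan over every model metabolite (or a stated subset).

    Member metabolites are identified by their in-member id (namespace
    stripped), so "the same" compound in both members is scanned once and
    may be supplied by either.  SMP metabolites are scanned under their
    extracellular id.
    """
    if metabolites is None:
        seen: dict[str, None] = {}
        for met in cm.model.metabolites:
            if met.compartment == "smp":
                continue
            base = met.id
            for member in cm.members:
                prefix = member + SEP
                if base.startswith(prefix):
                    base = base[len(prefix):]
                    break
            seen.setdefault(base, None)
        metabolites = sorted(seen)
    return [
        scan_metabolite(cm, met, grid=grid, lethality_threshold=lethality_threshold)
        for met in metabolites
    ]


def results_table(results: list[ProductionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"metabolite": r.metabolite, "feasible": r.feasible, "max_rate": r.max_rate}
         for r in results]
    ).set_index("metabolite")


def compute_yield(
    result: ProductionResult,
    formula: str,
    rate: float | None = None,
) -> YieldResult:
    """g of product per gDW of biomass at a production rate (default: max rate).

    yield = production flux x formula weight / community growth, with the
    community growth read off the scan at that rate.
    """
    rate = result.max_rate if rate is None else float(rate)
    if rate == 0.0:
        return YieldResult(result.metabolite, 0.0, 0.0, float("nan"), formula_weight(formula))
    row = result.growth.loc[rate]
    mu = float(row["community_growth"])
    if not row["feasible"] or not np.isfinite(mu) or mu <= 0:
        raise ValueError(f"community growth not positive at rate {rate}")
    fw = formula_weight(formula)
    return YieldResult(
        metabolite=result.metabolite,
        yield_g_per_gdw=rate * fw / mu,
        production_flux=rate,
        community_growth=mu,
        formula_weight_g_per_mmol=fw,
    )


def cluster_exchanges(
    profiles: pd.DataFrame, normalizer: pd.Series | None = None
) -> tuple[list[str], np.ndarray, str]:
    """Complete-linkage clustering of exchange-flux profiles.

    Rows are metabolites (or genes), columns grid points / transfer
    reactions.  When ``normalizer`` is given (e.g. community growth per
    column) the matrix is divided column-wise first.  Returns the leaf
    order, the SciPy linkage matrix, and a Newick rendering of the tree.
    """
    mat = profiles.astype(float)
    if normalizer is not None:
        mat = mat.div(normalizer, axis=1)
    if not np.isfinite(mat.values).all():
        raise ValueError("profile matrix must be finite")
    labels = list(mat.index.astype(str))
    if len(labels) == 1:
        return labels, np.empty((0, 4)), f"{labels[0]};"
    link = linkage(pdist(mat.values, metric="euclidean"), method="complete")
    order = [labels[i] for i in leaves_list(link)]
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(link, labels)
    newick = str(tree).strip()
    return order, link, newick
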