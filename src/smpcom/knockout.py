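"""Single-gene deletion scans, community rescue, and growth benchmarking.

A gene is deleted by evaluating every GPR (gene-protein-reaction boolean
rule) with the gene absent and closing the reactions whose rule turns
false.  Lethality is an absolute growth threshold (default 1e-6 h^-1).
In a community, a member's post-knockout growth is judged with
:func:`smpcom.fba.maximize_member` at partner floor 0, i.e. the member
counts as rescued when *some* feasible partner behavior lets it grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import cobra
import pandas as pd

from .community import SEP, CommunityModel
from .fba import LETHALITY_THRESHOLD, maximize_member, solve_fba

__all__ = [
    "KnockoutResult",
    "RescueSummary",
    "BenchmarkTable",
    "delete_gene",
    "single_gene_deletion_scan",
    "lethal_genes",
    "rescue_percentage",
    "benchmark",
]


@dataclass
class KnockoutResult:
    gene: str
    condition: str  # monoculture | coculture
    disabled_reactions: tuple[str, ...]
    member_growth: dict[str, float]
    lethal: dict[str, bool]


@dataclass
class RescueSummary:
    """Reduction in lethal knockouts from monoculture to coculture."""

    member: str
    lethal_monoculture: int
    lethal_coculture: int
    percent_reduction: float
    undefined: bool = False  # no monoculture-lethal genes to rescue


@dataclass
class BenchmarkTable:
    """Confusion-matrix statistics for growth/no-growth predictions."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def mcc(self) -> float:
        d = math.sqrt(
            (self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if d == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv,
                "npv": self.npv, "mcc": self.mcc,
            }]
        )


def delete_gene(model: cobra.Model, gene_id: str) -> cobra.Model:
    """Copy of ``model`` with one gene removed and dependent reactions closed."""
    if gene_id not in model.genes:
        raise KeyError(f"unknown gene {gene_id!r}")
    out = model.copy()
    out.genes.get_by_id(gene_id).knock_out()
    return out


def _disabled_by(model: cobra.Model, gene_id: str) -> tuple[str, ...]:
    gene = model.genes.get_by_id(gene_id)
    disabled = []
    for rxn in gene.reactions:
        if not rxn.gpr.eval(knockouts={gene_id}):
            disabled.append(rxn.id)
    return tuple(sorted(disabled))


def single_gene_deletion_scan(
    target: CommunityModel | cobra.Model,
    genes: list[str] | None = None,
    lethality_threshold: float = LETHALITY_THRESHOLD,
) -> list[KnockoutResult]:
    """Knock out each gene in turn and record growth and lethality.

    Monoculture: plain (parsimonious) FBA on the single model.
    Community: each member's growth is its :func:`maximize_member`
    optimum with the partner floored at 0, and lethality is called per
    member; an infeasible model counts as zero growth for everyone.
    """
    if isinstance(target, CommunityModel):
        return _community_scan(target, genes, lethality_threshold)
    return _mono_scan(target, genes, lethality_threshold)


def _mono_scan(model, genes, threshold):
    gene_ids = genes or sorted(g.id for g in model.genes)
    member = model.id or "model"
    results = []
    for gid in gene_ids:
        if gid not in model.genes:
            raise KeyError(f"unknown gene {gid!r}")
        with model as m:
            m.genes.get_by_id(gid).knock_out()
            sol = solve_fba(m)
        growth = sol.objective_value if sol.optimal else 0.0
        results.append(
            KnockoutResult(
                gene=gid,
                condition="monoculture",
                disabled_reactions=_disabled_by(model, gid),
                member_growth={member: growth},
                lethal={member: growth < threshold},
            )
        )
    return results


def _community_scan(cm: CommunityModel, genes, threshold):
    gene_ids = genes or sorted(g.id for g in cm.model.genes)
    results = []
    for gid in gene_ids:
        if gid not in cm.model.genes:
            raise KeyError(f"unknown gene {gid!r}")
        growths: dict[str, float] = {}
        with cm.model as m:
            m.genes.get_by_id(gid).knock_out()
            for member in cm.members:
                sol = maximize_member(cm, member, partner_floor=0.0)
                growths[member] = sol.growth(member) if sol.optimal else 0.0
        results.append(
            KnockoutResult(
                gene=gid,
                condition="coculture",
                disabled_reactions=_disabled_by(cm.model, gid),
                member_growth=growths,
                lethal={mbr: g < threshold for mbr, g in growths.items()},
            )
        )
    return results


def results_table(results: list[KnockoutResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"gene": r.gene, "condition": r.condition}
        for mbr, g in r.member_growth.items():
            row[f"growth_{mbr}"] = g
            row[f"lethal_{mbr}"] = r.lethal[mbr]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def lethal_genes(results: list[KnockoutResult], member: str) -> set[str]:
    """Genes of ``member`` whose deletion is lethal to it, by base gene id.

    Community-scan genes carry the member namespace prefix; it is
    stripped so monoculture and coculture sets are directly comparable.
    """
    out = set()
    prefix = member + SEP
    for r in results:
        if r.condition == "coculture":
            if r.gene.startswith(prefix) and r.lethal.get(member):
                out.add(r.gene[len(prefix):])
        elif r.lethal.get(member, False):
            out.add(r.gene)
    return out


def rescue_percentage(mono_lethal: set[str] | int, co_lethal: set[str] | int,
                      member: str = "") -> RescueSummary:
    """Percent of monoculture-lethal genes that become viable in coculture."""
    n_mono = mono_lethal if isinstance(mono_lethal, int) else len(mono_lethal)
    n_co = co_lethal if isinstance(co_lethal, int) else len(co_lethal)
    if n_mono == 0:
        return RescueSummary(member, 0, n_co, 0.0, undefined=True)
    return RescueSummary(member, n_mono, n_co, 100.0 * (n_mono - n_co) / n_mono)


def benchmark(predicted: list[bool], observed: list[bool]) -> BenchmarkTable:
    """Confusion matrix of growth calls (growth = positive) plus statistics."""
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed call lists differ in length")
    tp = sum(1 for p, o in zip(predicted, observed) if p and o)
    tn = sum(1 for p, o in zip(predicted, observed) if not p and not o)
    fp = sum(1 for p, o in zip(predicted, observed) if p and not o)
    fn = sum(1 for p, o in zip(predicted, observed) if not p and o)
    return BenchmarkTable(tp=tp, tn=tn, fp=fp, fn=fn)
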