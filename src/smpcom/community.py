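"""Merging two organism models through a Shared Metabolite Pool (SMP).

The SMP is a dedicated compartment standing between the community members
and the environment.  Every metabolite a member is allowed to exchange —
either because substrate-utilization evidence (BIOLOG-style assays,
literature, or the model itself) says so, or because the medium supplies
it — gets one SMP metabolite, one transfer reaction per participating
member, and, for medium components, one environment exchange.  Member
models keep their full interior network but lose their private exchange
reactions, so *all* inter-member and member-environment traffic is
observable on the transfer reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
import yaml
from cobra.manipulation import rename_genes

from .model_io import ENV_COMPARTMENT, MediumSpec, exchange_reactions

SEP = "__"
SMP_COMPARTMENT = "smp"
DIRECTIONS = ("uptake", "secretion", "both")
SOURCES = ("biolog", "literature", "model")

__all__ = [
    "SEP",
    "SmpEvidence",
    "ConstraintSet",
    "CommunityModel",
    "namespace_member",
    "merge_models",
    "community_summary",
    "unique_reactions",
]


@dataclass(frozen=True)
class SmpEvidence:
    """Curated table of which members may exchange which metabolites.

    Rows are ``(metabolite, member, direction, source)`` with directions
    relative to the member (``secretion`` = member to pool, ``uptake`` =
    pool to member) and sources from the closed vocabulary
    ``{biolog, literature, model}``.
    """

    rows: tuple[tuple[str, str, str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for met, member, direction, source in self.rows:
            if direction not in DIRECTIONS:
                raise ValueError(f"direction {direction!r} not in {DIRECTIONS}")
            if source not in SOURCES:
                raise ValueError(f"source {source!r} not in {SOURCES}")
            key = (met, member)
            if key in seen:
                raise ValueError(f"duplicate evidence row for {key}")
            seen.add(key)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "SmpEvidence":
        return cls(rows=tuple(tuple(r) for r in rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SmpEvidence":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["metabolite", "member", "direction", "source"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"evidence table missing columns {missing}")
        return cls.from_rows(df[required].itertuples(index=False, name=None))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            list(self.rows), columns=["metabolite", "member", "direction", "source"]
        ).to_csv(path, sep="\t", index=False)

    @property
    def metabolites(self) -> list[str]:
        return sorted({met for met, *_ in self.rows})


@dataclass(frozen=True)
class ConstraintSet:
    """Named bound overrides applied after merging.

    The study-condition example is a secretion floor on the phototroph's
    sucrose transporter (0.182 mmol gDW^-1 h^-1 for the engineered
    cscB+ strain the framework emulates).
    """

    bounds: Mapping[str, tuple[float, float]]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstraintSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(bounds={k: (float(v[0]), float(v[1])) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.bounds.items()}, fh, sort_keys=True)

    def apply(self, model: cobra.Model) -> None:
        for rxn_id, (lb, ub) in self.bounds.items():
            if rxn_id not in model.reactions:
                raise KeyError(f"constraint references unknown reaction {rxn_id!r}")
            model.reactions.get_by_id(rxn_id).bounds = (lb, ub)


@dataclass
class CommunityModel:
    """Two namespaced members joined through a Shared Metabolite Pool.

    ``model`` is a plain :class:`cobra.Model`; the remaining fields index
    its community structure: biomass reaction per member, transfer
    reactions keyed by (extracellular metabolite id, member), SMP
    metabolites, and SMP-environment exchanges keyed by metabolite id.
    """

    model: cobra.Model
    members: tuple[str, str]
    biomass: dict[str, str]
    transfers: dict[tuple[str, str], str] = field(default_factory=dict)
    smp_metabolites: dict[str, str] = field(default_factory=dict)
    environment_exchanges: dict[str, str] = field(default_factory=dict)

    def member_of(self, item_id: str) -> str | None:
        for member in self.members:
            if item_id.startswith(member + SEP):
                return member
        return None

    def member_reactions(self, member: str) -> list[cobra.Reaction]:
        prefix = member + SEP
        return [r for r in self.model.reactions if r.id.startswith(prefix)]

    def member_genes(self, member: str) -> list[cobra.Gene]:
        prefix = member + SEP
        return [g for g in self.model.genes if g.id.startswith(prefix)]

    def transfer_ids_for(self, metabolite: str) -> list[str]:
        return [rid for (met, _m), rid in self.transfers.items() if met == metabolite]

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            model=self.model.copy(),
            members=self.members,
            biomass=dict(self.biomass),
            transfers=dict(self.transfers),
            smp_metabolites=dict(self.smp_metabolites),
            environment_exchanges=dict(self.environment_exchanges),
        )


def namespace_member(model: cobra.Model, member_id: str) -> cobra.Model:
    """Return a copy with every metabolite, reaction, and gene id prefixed.

    The prefix is ``member_id + "__"``; double underscores keep the ids
    valid SBML SIds and valid identifiers inside boolean GPR strings.
    Already-prefixed models pass through unchanged (idempotent).
    """
    if not member_id:
        raise ValueError("member_id must be non-empty")
    if SEP in member_id:
        raise ValueError(f"member_id may not contain the separator {SEP!r}")
    prefix = member_id + SEP
    out = model.copy()
    if all(x.id.startswith(prefix) for x in out.reactions):
        return out
    rename_genes(out, {g.id: prefix + g.id for g in out.genes if not g.id.startswith(prefix)})
    for met in out.metabolites:
        if not met.id.startswith(prefix):
            met.id = prefix + met.id
    for rxn in out.reactions:
        if not rxn.id.startswith(prefix):
            rxn.id = prefix + rxn.id
    out.repair()
    return out


def _smp_id(extracellular_id: str) -> str:
    stem = extracellular_id
    if stem.endswith("_" + ENV_COMPARTMENT):
        stem = stem[: -(len(ENV_COMPARTMENT) + 1)]
    return f"{stem}_{SMP_COMPARTMENT}"


_TRANSFER_BOUNDS = {
    # transfer stoichiometry is member_e -> SMP, so positive flux = secretion
    "secretion": (0.0, 1000.0),
    "uptake": (-1000.0, 0.0),
    "both": (-1000.0, 1000.0),
}


def merge_models(
    a: cobra.Model,
    b: cobra.Model,
    evidence: SmpEvidence,
    constraints: ConstraintSet | None = None,
    medium: MediumSpec | None = None,
    member_ids: tuple[str, str] | None = None,
) -> CommunityModel:
    """Join two organism models through a Shared Metabolite Pool.

    Construction, in order: namespace both members; drop their private
    environment exchanges; add one SMP metabolite plus one directional
    transfer reaction per evidence row; add reversible transfers and
    SMP-environment exchanges for every medium metabolite a member can
    see; set the objective to the unweighted sum of member biomasses;
    apply constraint overrides last.
    """
    member_ids = member_ids or (a.id or "A", b.id or "B")
    if member_ids[0] == member_ids[1]:
        raise ValueError("member ids must differ")
    medium = medium or MediumSpec(entries={})
    sources = {member_ids[0]: a, member_ids[1]: b}

    community = cobra.Model(f"{member_ids[0]}-{member_ids[1]}")
    biomass: dict[str, str] = {}
    extracellular: dict[str, set[str]] = {}
    for member, source in sources.items():
        spaced = namespace_member(source, member)
        obj = [r for r in spaced.reactions if r.objective_coefficient]
        if len(obj) != 1:
            raise ValueError(f"member {member!r} must have exactly one objective reaction")
        biomass[member] = obj[0].id
        prefix = member + SEP
        extracellular[member] = {
            met.id[len(prefix):]
            for met in spaced.metabolites
            if met.compartment == ENV_COMPARTMENT
        }
        spaced.remove_reactions(exchange_reactions(spaced), remove_orphans=False)
        community.add_reactions(list(spaced.reactions))

    cm = CommunityModel(model=community, members=tuple(sources), biomass=biomass)

    def ensure_smp_met(ext_id: str) -> cobra.Metabolite:
        sid = _smp_id(ext_id)
        if sid in community.metabolites:
            return community.metabolites.get_by_id(sid)
        met = cobra.Metabolite(sid, compartment=SMP_COMPARTMENT, name=f"{ext_id} (shared pool)")
        community.add_metabolites([met])
        cm.smp_metabolites[ext_id] = sid
        return met

    def add_transfer(ext_id: str, member: str, bounds: tuple[float, float]) -> None:
        if (ext_id, member) in cm.transfers:
            # widen an existing transfer rather than duplicating it
            rxn = community.reactions.get_by_id(cm.transfers[(ext_id, member)])
            rxn.bounds = (min(rxn.lower_bound, bounds[0]), max(rxn.upper_bound, bounds[1]))
            return
        smp_met = ensure_smp_met(ext_id)
        member_met = community.metabolites.get_by_id(member + SEP + ext_id)
        rxn = cobra.Reaction(f"T_{member}{SEP}{ext_id}", lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.add_metabolites({member_met: -1.0, smp_met: 1.0})
        rxn.subsystem = "SMP transfer"
        community.add_reactions([rxn])
        cm.transfers[(ext_id, member)] = rxn.id

    for met_id, member, direction, _source in evidence.rows:
        if member not in sources:
            raise ValueError(f"evidence row names unknown member {member!r}")
        if not any(met_id in exts for exts in extracellular.values()):
            raise ValueError(
                f"evidence metabolite {met_id!r} is absent from both members' "
                f"extracellular space"
            )
        if met_id not in extracellular[member]:
            raise ValueError(
                f"evidence metabolite {met_id!r} is not in the extracellular "
                f"space of member {member!r}"
            )
        add_transfer(met_id, member, _TRANSFER_BOUNDS[direction])

    for met_id, rate in medium.entries.items():
        holders = [m for m in sources if met_id in extracellular[m]]
        if not holders:
            raise ValueError(f"medium metabolite {met_id!r} unknown to both members")
        for member in holders:
            add_transfer(met_id, member, _TRANSFER_BOUNDS["both"])
        smp_met = ensure_smp_met(met_id)
        ex = cobra.Reaction(f"EX_{_smp_id(met_id)}", lower_bound=-float(rate), upper_bound=1000.0)
        ex.add_metabolites({smp_met: -1.0})
        ex.subsystem = "SMP exchange"
        community.add_reactions([ex])
        cm.environment_exchanges[met_id] = ex.id

    community.objective = {
        community.reactions.get_by_id(rid): 1.0 for rid in biomass.values()
    }
    if constraints is not None:
        constraints.apply(community)
    return cm


def community_summary(cm: CommunityModel) -> pd.DataFrame:
    """Genes / reactions / metabolites counts, overall and per member."""
    rows = {}
    for member in cm.members:
        prefix = member + SEP
        rows[member] = {
            "genes": sum(1 for g in cm.model.genes if g.id.startswith(prefix)),
            "reactions": sum(1 for r in cm.model.reactions if r.id.startswith(prefix)),
            "metabolites": sum(1 for m in cm.model.metabolites if m.id.startswith(prefix)),
        }
    rows["community"] = {
        "genes": len(cm.model.genes),
        "reactions": len(cm.model.reactions),
        "metabolites": len(cm.model.metabolites),
    }
    return pd.DataFrame(rows).T[["genes", "reactions", "metabolites"]]


def unique_reactions(a: cobra.Model, b: cobra.Model) -> tuple[set[str], set[str]]:
    """Reaction ids found only in ``a`` and only in ``b`` (symmetric difference)."""
    ids_a = {r.id for r in a.reactions}
    ids_b = {r.id for r in b.reactions}
    return ids_a - ids_b, ids_b - ids_a
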