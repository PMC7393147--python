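"""Reading, validating, and constraining single-organism metabolic models.

Models are held as :class:`cobra.Model` objects.  Two on-disk dialects are
supported: the widely used COBRA JSON schema and SBML level 3 with the
``fbc`` (flux balance constraints) package, which is how curated
genome-scale reconstructions are normally distributed.

Conventions used throughout the package:

* flux units are mmol/gDW/h (growth in 1/h),
* uptake is negative flux on an exchange reaction,
* an exchange reaction is a boundary reaction whose single metabolite
  lives in the environment compartment (``e`` by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
import yaml
from cobra.core.gene import GPR
from cobra.flux_analysis import flux_variability_analysis
from cobra.io import (
    load_json_model,
    read_sbml_model,
    save_json_model,
    write_sbml_model,
)

ENV_COMPARTMENT = "e"

__all__ = [
    "MediumSpec",
    "ValidationReport",
    "read_model",
    "write_model",
    "validate_model",
    "apply_medium",
    "exchange_reactions",
    "find_exchange",
]


class ModelFormatError(ValueError):
    """A model file failed to parse or violates structural invariants."""


@dataclass(frozen=True)
class MediumSpec:
    """Maximum uptake rates for environment metabolites.

    ``entries`` maps an environment metabolite id (e.g. ``"sucr_e"``) to a
    non-negative maximum uptake rate.  Applying a medium closes the uptake
    of every exchange not listed, which is the usual minimal-medium
    semantics of constraint-based analysis.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for met, rate in self.entries.items():
            if rate < 0:
                raise ValueError(f"uptake rate for {met!r} must be >= 0, got {rate}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MediumSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(entries={str(k): float(v) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.entries), fh, sort_keys=True)


@dataclass
class ValidationReport:
    """Outcome of the structural/numerical QC checks on one model."""

    model_id: str
    bound_violations: list[str] = field(default_factory=list)
    blocked_reactions: list[str] = field(default_factory=list)
    bad_gprs: list[str] = field(default_factory=list)
    imbalanced_reactions: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def is_valid(self) -> bool:
        return not self.bound_violations and not self.bad_gprs

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.bound_violations:
            rows.append({"check": "bounds", "reaction": r, "detail": "lower > upper"})
        for r in self.blocked_reactions:
            rows.append({"check": "blocked", "reaction": r, "detail": "no feasible flux"})
        for r in self.bad_gprs:
            rows.append({"check": "gpr", "reaction": r, "detail": "unparsable rule"})
        for r, imbal in self.imbalanced_reactions.items():
            detail = ", ".join(f"{el}:{v:+g}" for el, v in sorted(imbal.items()))
            rows.append({"check": "mass_balance", "reaction": r, "detail": detail})
        return pd.DataFrame(rows, columns=["check", "reaction", "detail"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_model(path: str | Path, dialect: str | None = None) -> cobra.Model:
    """Read a single-organism model from JSON or SBML-fbc.

    When ``dialect`` is omitted it is inferred from the file suffix
    (``.json`` vs ``.xml``/``.sbml``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "json" if path.suffix == ".json" else "sbml-fbc"
    try:
        if dialect == "json":
            model = load_json_model(str(path))
        elif dialect in ("sbml-fbc", "sbml"):
            model = read_sbml_model(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except ValueError:
        raise
    except Exception as exc:  # parse errors from libsbml / json machinery
        raise ModelFormatError(f"could not parse {path} as {dialect}: {exc}") from exc
    _check_structure(model, path)
    return model


def write_model(model: cobra.Model, path: str | Path, dialect: str | None = None) -> None:
    """Write a model as COBRA JSON or SBML-fbc, chosen by suffix or ``dialect``."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix == ".json" else "sbml-fbc"
    if dialect == "json":
        save_json_model(model, str(path))
    elif dialect in ("sbml-fbc", "sbml"):
        write_sbml_model(model, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _check_structure(model: cobra.Model, path: Path) -> None:
    declared = {m.id for m in model.metabolites}
    for rxn in model.reactions:
        for met in rxn.metabolites:
            if met.id not in declared:
                raise ModelFormatError(
                    f"{path}: reaction {rxn.id!r} cites undeclared metabolite {met.id!r}"
                )
    objective_rxns = [r for r in model.reactions if r.objective_coefficient]
    if not objective_rxns:
        raise ModelFormatError(f"{path}: model declares no objective (biomass) reaction")


def exchange_reactions(model: cobra.Model, env_compartment: str = ENV_COMPARTMENT):
    """Boundary reactions with exactly one metabolite in the environment compartment."""
    out = []
    for rxn in model.reactions:
        mets = list(rxn.metabolites)
        if len(mets) == 1 and mets[0].compartment == env_compartment:
            out.append(rxn)
    return out


def find_exchange(model: cobra.Model, metabolite_id: str,
                  env_compartment: str = ENV_COMPARTMENT) -> cobra.Reaction:
    """The exchange reaction for one environment metabolite, or raise with candidates."""
    for rxn in exchange_reactions(model, env_compartment):
        if next(iter(rxn.metabolites)).id == metabolite_id:
            return rxn
    candidates = sorted(next(iter(r.metabolites)).id for r in exchange_reactions(model, env_compartment))
    raise KeyError(
        f"no exchange reaction for metabolite {metabolite_id!r}; "
        f"exchangeable metabolites: {candidates}"
    )


def validate_model(model: cobra.Model, check_blocked: bool = True) -> ValidationReport:
    """Run QC checks and return a report; never raises on QC findings.

    Checks: (a) reaction bounds ordered, (b) blocked reactions (FVA with
    all exchange uptakes opened), (c) GPR strings parse to a boolean tree,
    (d) elemental balance for interior reactions whose metabolites all
    carry formulas (boundary reactions and drains such as biomass are
    exempt).  The model is *valid* iff (a) and (c) are clean.
    """
    report = ValidationReport(model_id=model.id or "<unnamed>")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            report.bound_violations.append(rxn.id)
        try:
            GPR.from_string(rxn.gene_reaction_rule)
        except Exception:
            report.bad_gprs.append(rxn.id)
        # elemental balance only where every participant has a formula and
        # the reaction actually has two sides (drains/sinks are exempt)
        if rxn.boundary or not rxn.reactants or not rxn.products:
            continue
        if any(not met.formula for met in rxn.metabolites):
            continue
        imbalance = rxn.check_mass_balance()
        imbalance = {k: v for k, v in imbalance.items() if abs(v) > 1e-9 and k != "charge"}
        if imbalance:
            report.imbalanced_reactions[rxn.id] = imbalance

    if check_blocked and not report.bound_violations:
        with model as m:
            for ex in exchange_reactions(m):
                ex.lower_bound = min(ex.lower_bound, -1000.0)
            fva = flux_variability_analysis(m, fraction_of_optimum=0.0)
        for rxn_id, row in fva.iterrows():
            if max(abs(row["minimum"]), abs(row["maximum"])) < 1e-9:
                report.blocked_reactions.append(rxn_id)
    return report


def apply_medium(model: cobra.Model, medium: MediumSpec,
                 env_compartment: str = ENV_COMPARTMENT) -> cobra.Model:
    """Return a copy of ``model`` constrained to ``medium``.

    Listed metabolites get exchange lower bound ``-rate``; the uptake of
    every unlisted exchange is closed (lower bound 0).  Secretion (upper)
    bounds are untouched.
    """
    out = model.copy()
    listed = {}
    for met_id, rate in medium.entries.items():
        ex = find_exchange(out, met_id, env_compartment)  # raises with candidates
        listed[ex.id] = rate
    for ex in exchange_reactions(out, env_compartment):
        if ex.id in listed:
            ex.lower_bound = -float(listed[ex.id])
        else:
            ex.lower_bound = 0.0
    return out


def formula_weight(formula: str) -> float:
    """Molecular weight in g mmol^-1 from an elemental formula string."""
    met = cobra.Metabolite("tmp", formula=formula, compartment="c")
    weight = met.formula_weight
    if weight is None or math.isnan(weight) or weight <= 0:
        raise ValueError(f"cannot compute weight of formula {formula!r}")
    return weight / 1000.0
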