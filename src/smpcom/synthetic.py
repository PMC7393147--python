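"""Toy phototroph/heterotroph models with closed-form ground truth.

The pair emulates the biology of a sucrose-secreting cyanobacterium fed
on light and CO2, cocultured with a heterotroph living off that sucrose
— the canonical engineered phototrophic community — at a size (about
ten reactions per member) where every optimum is an exact rational and
every essential-gene call can be derived by hand.  Stoichiometries are
integer-valued on a single "carb" carbon currency:

* phototroph P: photon + co2 -> carb; 2 carb + nh4 -> aa;
  2 carb -> sucrose; biomass = 0.5 carb + 0.5 aa
  => 1.5 carb per biomass unit, mu_P = photon_cap / 1.5.
* heterotroph H: sucrose -> 2 carb; 2 carb + nh4 -> aa (switchable
  auxotrophy); acetate overflow 2 carb -> ac; biomass = 0.5 carb + 0.5 aa.

Transfers through the pool are carbon-lossless, so the joint community
optimum stays photon_cap / 1.5 however growth is split; a sucrose
secretion floor (default the 0.182 mmol gDW^-1 h^-1 of the engineered
cscB+ strain) plus the parsimony tie-break pins the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import cobra
from cobra import Metabolite, Reaction

from .community import CommunityModel, ConstraintSet, SmpEvidence, merge_models
from .model_io import MediumSpec, write_model

SUCROSE_FLOOR = 0.182  # mmol gDW^-1 h^-1, engineered cscB+ secretion rate

__all__ = [
    "ToyCommunitySpec",
    "make_toy_phototroph",
    "make_toy_heterotroph",
    "make_toy_community",
    "ground_truth",
    "simulate_expression",
    "write_fixture_bundle",
]

_FORMULAS = {
    "photon_e": "",
    "co2_e": "CO2",
    "nh4_e": "H4N",
    "carb_c": "CH2O",
    "aa_c": "C2H8NO2",
    "aa_e": "C2H8NO2",
    "sucr_c": "C2H4O2",
    "sucr_e": "C2H4O2",
    "ac_e": "C2H4O2",
}


@dataclass(frozen=True)
class ToyCommunitySpec:
    """Study conditions for the toy pair.

    ``photon_cap`` plays the role of the imported light-uptake
    constraint; ``sucrose_floor`` the engineered secretion rate;
    ``aa_synthesis`` switches the heterotroph's amino-acid autotrophy
    (off = obligate auxotroph); ``sucrose_transport`` disables the
    sucrose uptake system (the K-12-like variant); ``sigma`` is the
    lognormal noise of the expression simulator.
    """

    photon_cap: float = 10.0
    sucrose_carb_units: int = 2
    sucrose_floor: float = SUCROSE_FLOOR
    aa_synthesis: bool = True
    sucrose_transport: bool = True
    share_amino_acid: bool = True
    sigma: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def evidence_rows(self) -> list[tuple[str, str, str, str]]:
        rows = [
            ("sucr_e", "P", "secretion", "model"),
            ("sucr_e", "H", "uptake", "biolog"),
            ("ac_e", "H", "secretion", "model"),
        ]
        if self.share_amino_acid:
            rows += [
                ("aa_e", "P", "secretion", "model"),
                ("aa_e", "H", "both", "literature"),
            ]
        return rows


def _met(mid: str, compartment: str) -> Metabolite:
    return Metabolite(mid, formula=_FORMULAS.get(mid, ""), compartment=compartment,
                      name=mid.rsplit("_", 1)[0])


def _rxn(mid: str, sto, lb, ub, gpr="", subsystem="") -> Reaction:
    r = Reaction(mid, lower_bound=lb, upper_bound=ub)
    r.add_metabolites(sto)
    r.gene_reaction_rule = gpr
    r.subsystem = subsystem
    return r


def make_toy_phototroph(spec: ToyCommunitySpec = ToyCommunitySpec()) -> cobra.Model:
    """Light/CO2-driven secreting organism: 11 reactions, 5 genes.

    Closed-form optimum on photon cap L with forced sucrose secretion s:
    mu_P = (L - 2 s) / 1.5.
    """
    m = cobra.Model("P")
    photon, co2, nh4 = _met("photon_e", "e"), _met("co2_e", "e"), _met("nh4_e", "e")
    carb, aa_c, sucr_c = _met("carb_c", "c"), _met("aa_c", "c"), _met("sucr_c", "c")
    sucr_e, aa_e = _met("sucr_e", "e"), _met("aa_e", "e")
    k = spec.sucrose_carb_units
    m.add_reactions([
        _rxn("EX_photon_e", {photon: -1}, -spec.photon_cap, 0.0, subsystem="Exchange"),
        _rxn("EX_co2_e", {co2: -1}, -1000.0, 1000.0, subsystem="Exchange"),
        _rxn("EX_nh4_e", {nh4: -1}, -1000.0, 1000.0, subsystem="Exchange"),
        _rxn("FIX", {photon: -1, co2: -1, carb: 1}, 0.0, 1000.0, "gP1", "Carbon fixation"),
        _rxn("AAS", {carb: -2, nh4: -1, aa_c: 1}, 0.0, 1000.0, "gP2", "Amino acid biosynthesis"),
        _rxn("SUC", {carb: -k, sucr_c: 1}, 0.0, 1000.0, "gP3", "Sucrose biosynthesis"),
        _rxn("TR_sucr", {sucr_c: -1, sucr_e: 1}, 0.0, 1000.0, "gP4", "Transport"),
        _rxn("TR_aa", {aa_c: -1, aa_e: 1}, 0.0, 1000.0, "gP5", "Transport"),
        _rxn("BIOMASS_P", {carb: -0.5, aa_c: -0.5}, 0.0, 1000.0, subsystem="Biomass"),
        _rxn("EX_sucr_e", {sucr_e: -1}, 0.0, 1000.0, subsystem="Exchange"),
        _rxn("EX_aa_e", {aa_e: -1}, 0.0, 1000.0, subsystem="Exchange"),
    ])
    m.objective = "BIOMASS_P"
    return m


def make_toy_heterotroph(spec: ToyCommunitySpec = ToyCommunitySpec()) -> cobra.Model:
    """Sucrose-consuming heterotroph: 9 reactions, 4 genes.

    On sucrose uptake S (each worth 2 carb) with working amino-acid
    synthesis: mu_H = 2 S / 1.5.  With ``aa_synthesis`` off the organism
    is an amino-acid auxotroph.  ``sucrose_transport`` off removes the
    uptake system entirely (K-12-like variant).
    """
    m = cobra.Model("H")
    sucr_e, aa_e, nh4, ac = _met("sucr_e", "e"), _met("aa_e", "e"), _met("nh4_e", "e"), _met("ac_e", "e")
    carb, aa_c = _met("carb_c", "c"), _met("aa_c", "c")
    aas_ub = 1000.0 if spec.aa_synthesis else 0.0
    reactions = [
        _rxn("EX_sucr_e", {sucr_e: -1}, -1000.0, 1000.0, subsystem="Exchange"),
        _rxn("EX_aa_e", {aa_e: -1}, -1000.0, 1000.0, subsystem="Exchange"),
        _rxn("EX_nh4_e", {nh4: -1}, -1000.0, 1000.0, subsystem="Exchange"),
        _rxn("EX_ac_e", {ac: -1}, 0.0, 1000.0, subsystem="Exchange"),
        _rxn("AAU", {aa_e: -1, aa_c: 1}, 0.0, 1000.0, "gH2", "Transport"),
        _rxn("AASH", {carb: -2, nh4: -1, aa_c: 1}, 0.0, aas_ub, "gH3", "Amino acid biosynthesis"),
        _rxn("OVF", {carb: -2, ac: 1}, 0.0, 1000.0, "gH4", "Overflow metabolism"),
        _rxn("BIOMASS_H", {carb: -0.5, aa_c: -0.5}, 0.0, 1000.0, subsystem="Biomass"),
    ]
    if spec.sucrose_transport:
        reactions.insert(
            4, _rxn("SUT", {sucr_e: -1, carb: spec.sucrose_carb_units}, 0.0, 1000.0,
                    "gH1", "Sucrose catabolism"))
    m.add_reactions(reactions)
    m.objective = "BIOMASS_H"
    return m


def phototroph_medium(spec: ToyCommunitySpec = ToyCommunitySpec()) -> MediumSpec:
    return MediumSpec(entries={"photon_e": spec.photon_cap, "co2_e": 1000.0, "nh4_e": 1000.0})


def heterotroph_medium(sucrose: float = 10.0, amino_acid: float = 0.0) -> MediumSpec:
    entries = {"sucr_e": sucrose, "nh4_e": 1000.0}
    if amino_acid > 0:
        entries["aa_e"] = amino_acid
    return MediumSpec(entries=entries)


def community_medium(spec: ToyCommunitySpec = ToyCommunitySpec()) -> MediumSpec:
    return phototroph_medium(spec)


def community_constraints(spec: ToyCommunitySpec = ToyCommunitySpec()) -> ConstraintSet:
    return ConstraintSet(bounds={"P__TR_sucr": (spec.sucrose_floor, 1000.0)})


def make_toy_community(spec: ToyCommunitySpec = ToyCommunitySpec(),
                       with_floor: bool = True) -> CommunityModel:
    """Merge the toy pair on the photoautotrophic community medium."""
    return merge_models(
        make_toy_phototroph(spec),
        make_toy_heterotroph(spec),
        SmpEvidence.from_rows(spec.evidence_rows()),
        constraints=community_constraints(spec) if with_floor else None,
        medium=community_medium(spec),
        member_ids=("P", "H"),
    )


def ground_truth(spec: ToyCommunitySpec = ToyCommunitySpec()) -> dict:
    """Closed-form reference values for the toy pair, derived by hand.

    Carbon accounting: one biomass unit costs 0.5 carb directly plus
    0.5 aa at 2 carb each = 1.5 carb; transfers are carbon-lossless, so
    at sucrose floor s the phototroph keeps (L - 2s) carb and the
    heterotroph receives 2s.
    """
    L, s = spec.photon_cap, spec.sucrose_floor
    mu_p_mono = L / 1.5
    mu_p_floor = (L - 2 * s) / 1.5
    mu_h_co = 2 * s / 1.5
    return {
        "phototroph_mono_growth": mu_p_mono,
        "phototroph_mono_growth_at_floor": mu_p_floor,
        "community_growth": L / 1.5,
        "member_growth": {"P": mu_p_floor, "H": mu_h_co},
        # plain monoculture models carry no secretion floor
        "essential_mono": {
            "P": ["gP1", "gP2"],
            "H": ["gH1", "gH3"],
        },
        # a floored model additionally needs sucrose synthesis: closing
        # SUC leaves the transporter floor unsatisfiable.  Deleting the
        # transporter gene itself (gP4) *vacates* the floor — the bound
        # override sits on the reaction the knockout closes — so the
        # engineered secretion demand disappears with its transporter.
        "essential_mono_with_floor": {
            "P": ["gP1", "gP2"] + (["gP3"] if s > 0 else []),
        },
        # community scan at partner floor 0: sucrose synthesis stays
        # essential to the phototroph via the floor; aa synthesis is
        # rescued iff the amino acid is shared via the pool
        "essential_co": {
            "P": ["gP1", "gP2", "gP3"] if s > 0 else ["gP1", "gP2"],
            "H": ["gH1"] + ([] if spec.share_amino_acid else ["gH3"]),
        },
        "rescued_genes": {"H": ["gH3"] if spec.share_amino_acid else []},
        "rescue_percent": {"H": 50.0 if spec.share_amino_acid else 0.0},
    }


def simulate_expression(
    model: cobra.Model,
    fluxes: pd.Series,
    sigma: float = 0.1,
    seed: int = 0,
    n_replicates: int = 3,
    baseline: float = 1.0,
    scale: float = 1000.0,
    library_factors: list[float] | None = None,
) -> pd.DataFrame:
    """Gene x sample count table whose signal tracks per-gene flux load.

    The expected count of a gene is ``baseline + scale * sum(|flux|)``
    over the reactions whose GPR contains it, multiplied per sample by a
    mean-1 lognormal noise factor (sd ``sigma``) and a library-size
    factor.  Deterministic under a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_replicates < 1:
        raise ValueError("need n_replicates >= 1")
    rng = np.random.default_rng(seed)
    lib = library_factors or [1.0] * n_replicates
    if len(lib) != n_replicates:
        raise ValueError("library_factors length must equal n_replicates")
    genes = sorted(g.id for g in model.genes)
    load = pd.Series(0.0, index=genes)
    for rxn in model.reactions:
        v = abs(float(fluxes.get(rxn.id, 0.0)))
        for gene in rxn.genes:
            load[gene.id] += v
    expected = baseline + scale * load
    # lognormal with mean exactly 1: exp(N(-sigma^2/2, sigma))
    noise = (
        np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(len(genes), n_replicates)))
        if sigma > 0
        else np.ones((len(genes), n_replicates))
    )
    counts = expected.values[:, None] * noise * np.asarray(lib)[None, :]
    return pd.DataFrame(counts, index=genes,
                        columns=[f"sample_{i + 1}" for i in range(n_replicates)])


def write_fixture_bundle(spec: ToyCommunitySpec, directory: str | Path) -> dict[str, Path]:
    """Write the toy pair plus evidence/medium/expression files and a manifest.

    Everything goes through the package's own writers so the bundle
    exercises the real readers end to end.  The manifest records the
    closed-form ground truth; tests hold the pipeline to it.
    """
    from .fba import solve_community_fba, solve_fba  # local import, avoids cycle
    from .model_io import apply_medium

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p, h = make_toy_phototroph(spec), make_toy_heterotroph(spec)
    paths: dict[str, Path] = {}
    for model, stem in ((p, "phototroph"), (h, "heterotroph")):
        for suffix in (".json", ".xml"):
            path = directory / f"{stem}{suffix}"
            write_model(model, path)
            paths[f"{stem}{suffix}"] = path
    SmpEvidence.from_rows(spec.evidence_rows()).to_tsv(directory / "evidence.tsv")
    paths["evidence.tsv"] = directory / "evidence.tsv"
    community_medium(spec).to_yaml(directory / "medium.yml")
    paths["medium.yml"] = directory / "medium.yml"
    phototroph_medium(spec).to_yaml(directory / "medium_phototroph.yml")
    paths["medium_phototroph.yml"] = directory / "medium_phototroph.yml"
    heterotroph_medium(sucrose=10.0).to_yaml(directory / "medium_heterotroph.yml")
    paths["medium_heterotroph.yml"] = directory / "medium_heterotroph.yml"
    community_constraints(spec).to_yaml(directory / "constraints.yml")
    paths["constraints.yml"] = directory / "constraints.yml"

    mono = solve_fba(apply_medium(p, phototroph_medium(spec)))
    for condition, fluxes in (("monoculture", mono.fluxes),):
        expr = simulate_expression(p, fluxes, sigma=spec.sigma, seed=spec.seed,
                                   n_replicates=spec.n_replicates)
        path = directory / f"expression_phototroph_{condition}.tsv"
        expr.to_csv(path, sep="\t")
        paths[path.name] = path

    truth = ground_truth(spec)
    cm = make_toy_community(spec)
    sol = solve_community_fba(cm)
    manifest = {
        "spec": {k: getattr(spec, k) for k in (
            "photon_cap", "sucrose_carb_units", "sucrose_floor", "aa_synthesis",
            "sucrose_transport", "share_amino_acid", "sigma", "n_replicates", "seed")},
        "ground_truth": truth,
        "solved": {
            "community_growth": sol.objective_value,
            "member_growth": sol.member_growth,
        },
        "counts": {
            "phototroph_reactions": len(p.reactions),
            "phototroph_genes": len(p.genes),
            "heterotroph_reactions": len(h.reactions),
            "heterotroph_genes": len(h.genes),
            "community_reactions": len(cm.model.reactions),
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = directory / "manifest.json"
    return paths
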