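# Methods

## The modeling framework

`smpcom` implements community constraint-based modeling for two-member
phototroph–heterotroph consortia. Each organism is an ordinary
genome-scale (or toy) metabolic model: a stoichiometric matrix *S*, flux
bounds, a biomass objective, and gene–protein–reaction (GPR) boolean
rules. Two organisms are joined through a **Shared Metabolite Pool
(SMP)**: a dedicated compartment holding one pool metabolite per
exchangeable compound. Members connect to the pool through *transfer
reactions* (one per evidence row, directional per the evidence), and the
pool connects to the environment only for metabolites the medium
supplies. Member-private exchange reactions are removed during the
merge, so every molecule entering or leaving an organism crosses an
observable transfer reaction — exchange profiling is then simply a read
of those fluxes.

Which metabolites may be shared is *evidence-gated*: a TSV of
`(metabolite, member, direction, source)` rows, with sources from
`{biolog, literature, model}` mirroring how such tables are curated from
substrate-utilization assays, the literature, and the reconstructions
themselves. A metabolite in the pool with no environment exchange obeys
strict steady-state conservation: whatever one member secretes the other
must take up.

## Community growth

Community FBA maximizes the **unweighted sum of member biomass fluxes**

maximize Σⱼ μⱼ s.t. S·v = 0, lb ≤ v ≤ ub.

Flux balance problems are degenerate, so the reported flux vector is the
parsimonious one (objective fixed at its optimum within 1e-6, then total
|v| minimized). Two consequences matter:

* Exchange profiles are unique up to genuinely alternate optima; FVA
  ranges are available to quantify the remaining freedom.
* When carbon transfer is lossless the joint optimum does not determine
  the growth *split*; parsimony pins it at the least-flux allocation
  (minimal exchange). A per-member view is provided by
  `maximize_member`, which maximizes one member's growth with the
  partner's biomass floored (default 0). This is the lens used for
  lethality: a member is viable after a knockout iff *some* feasible
  community behavior lets it grow.

Constraint overrides represent engineered phenotypes. The default study
condition is a sucrose-secretion floor of 0.182 mmol gDW⁻¹ h⁻¹ on the
phototroph's sucrose transporter, emulating a cscB⁺-type strain. A floor
interacts with knockouts in one subtle way, documented here because both
behaviors are defensible: knocking out the transporter's gene closes the
reaction and thereby *vacates* the floor — the engineered secretion
demand disappears with its transporter. Hence deleting the transporter
gene is non-lethal (and can exceed floored wild-type growth), while
deleting the upstream synthesis gene leaves the floor unsatisfiable and
is lethal. The "knockouts never help" invariant therefore holds exactly
on floor-free models, and that is where the test suite asserts it.

## Production scans and yields

For every metabolite, a secretion route through the pool is added (if
absent) and the forced secretion rate is swept over a grid — default 101
points on [0, 2] mmol gDW⁻¹ h⁻¹ (the interval of interest for
value-added compounds; the resolution is this package's choice). A rate
is *achievable with both members alive* when an LP with both biomasses
floored at the lethality threshold is feasible. This probe is separate
from the parsimonious solve that fills the growth/exchange tables,
because the parsimonious joint optimum may park one member at zero
growth even when both-grow solutions exist (on the toy acetate sweep it
always does). A metabolite is *producible* when some achievable grid
rate exceeds 1e-2 mmol gDW⁻¹ h⁻¹; the maximum production rate is the
largest achievable grid value.

Yield is mass-based: `rate × formula weight / community growth`
(g product per gDW biomass formed). The denominator is the community
(summed) growth rate — published g gDW⁻¹ figures rarely state a
basis, so this one is explicit and configurable at call sites.

Exchange profiles across forced-production grids (or across knockouts)
are compared by complete-linkage hierarchical clustering on Euclidean
distances, with the dendrogram exported as Newick text.

## Knockouts, rescue, benchmarking

A gene deletion closes exactly the reactions whose GPR evaluates false
without it. Lethality is an absolute growth threshold of 1e-6 h⁻¹
(relative thresholds misbehave when wild-type growth is itself near
zero; configurable everywhere). Monoculture scans use plain pFBA;
community scans judge each member by `maximize_member` at partner floor
0, so "rescued" means the community *can* carry the damaged member.
Rescue is summarized as `100 × (|lethal_mono| − |lethal_co|) /
|lethal_mono|`, reported as 0 with an `undefined` flag when no
monoculture-lethal genes exist.

Growth/no-growth benchmarking derives accuracy, sensitivity,
specificity, PPV, NPV, and the Matthews correlation coefficient from the
confusion matrix; MCC uses its standard form and is defined as 0 when
its denominator vanishes (e.g. all-positive predictions).

## Pathway activity, syntrophy, concordance

Flux vectors are growth-normalized (divided by the member's μ under the
condition at hand), summed with sign per subsystem ("pathway flux"), and
scaled by the largest absolute pathway flux, giving the normalized
subsystem activity Sn ∈ [−1, 1]. A literal sign-function variant
(pathway flux / |pathway flux| ∈ {−1, 0, 1}) is available behind
`sign_variant=True`; it is not the default because it discards the
stated continuous range. Burden shares are |pathway flux| normalized to
sum to 1 per member/condition.

Comparing Sn between monoculture (m1) and coculture (m2) with tolerance
ε (default 0.05 on the [−1,1] scale, this package's choice) classifies
each pathway: |Sn_m2| > |Sn_m1| + ε → *syntrophically active*,
|Sn_m2| < |Sn_m1| − ε → *deactivated*, otherwise *neutrally active*.
Direction is the sign of the shift — toward positive = uptake-side
(mass drawn from the pool into the network), toward negative =
secretion-side. The direction rule is an interpretation (the published
inequality pair is typographically degenerate) and is flagged as such.

Solution-space structure beyond single optima comes from hit-and-run
sampling (OptGP, single process for determinism; ACHR available) after
removing blocked reactions; fixed seeds give identical matrices, and a
zero-degree-of-freedom polytope returns its unique flux vector tiled.

Expression tables (gene × sample counts) are aggregated to subsystem
burden shares through the GPRs (a gene in several subsystems counts in
each), medianed across samples, and compared with flux burden shares by
Pearson correlation over the genic subsystems; with replicate tables for
two conditions, per-subsystem two-sided t-tests are reported with raw
and Benjamini–Hochberg-adjusted p-values side by side (raw values match the
conventional single-test analysis; the adjusted ones are there for
honesty about multiplicity).

## The synthetic community

The toy generator emulates the canonical engineered system — a
sucrose-secreting cyanobacterium feeding a heterotroph — at a size where
every reference value is an exact rational:

* **Phototroph P** (11 reactions, 5 genes): photon/CO₂/NH₄ exchanges;
  fixation `photon + co2 → carb` (gP1); amino-acid synthesis
  `2 carb + nh4 → aa` (gP2); sucrose synthesis `2 carb → sucr` (gP3);
  sucrose and amino-acid secretion transporters (gP4, gP5); biomass
  `0.5 carb + 0.5 aa`. One biomass unit costs 1.5 carbon units, so
  μ_P = photon_cap / 1.5 (20/3 at the default cap of 10), and a forced
  secretion s gives μ_P = (cap − 2s)/1.5.
* **Heterotroph H** (9 reactions, 4 genes): sucrose catabolism
  `sucr → 2 carb` (gH1; absent in the transport-less variant),
  amino-acid uptake (gH2), amino-acid synthesis (gH3; the auxotrophy
  switch), acetate overflow `2 carb → ac` (gH4), biomass as in P.

Defaults are the study conditions the package emulates: photon cap 10
mmol gDW⁻¹ h⁻¹, sucrose floor 0.182 mmol gDW⁻¹ h⁻¹, expression noise
σ = 0.1 with 3 replicates. Under the floor the community optimum stays
20/3 h⁻¹ with the parsimonious split μ_P = 6.424, μ_H = 0.2427.
Ground-truth essential sets, the gH3 rescue (lethal alone, viable when
the amino acid is shared, lethal again without that evidence row), and
all optima are written into the fixture manifest and enforced by tests.

The expression simulator draws each gene's expected count proportional
to the total |flux| of the reactions it gates (plus a pseudocount),
multiplied by mean-1 lognormal noise and a library-size factor.
Lognormal noise is the standard over-dispersion model at this scale; the
simulator does not attempt read-level artifacts (positional bias, counts
discreteness at low depth, batch structure), so concordance tests show
that the pathway aggregation recovers a signal that is present by
construction — they do not validate the biology of real RNA-seq.

What the toys do not exercise: thermodynamic infeasibility, cofactor
balancing, multi-compartment transport chains, alternate-optima
landscapes of genome-scale size, or >2-member communities (the merge
does not hard-fail on more members, but nothing is tested there).

## Numerical choices

* Solver GLPK via optlang; feasibility tolerance 1e-9, reported-zero
  threshold 1e-6; steady state enforced to ‖S·v‖∞ < 1e-6.
* Lethality threshold 1e-6 h⁻¹ absolute; production feasibility
  threshold 1e-2 mmol gDW⁻¹ h⁻¹; syntrophy ε 0.05.
* Transfer bounds ±1000 (one-sided for directional evidence); transfers
  carry no GPR — transport genetics are abstracted.
* Sampling: thinning 100 by default (10 in tests), OptGP with one
  process so fixed seeds reproduce bit-exactly.
* Degenerate inputs: infeasible models yield `status="infeasible"` with
  empty fluxes rather than exceptions in solve paths; forced rates above
  an exchange's capacity are recorded infeasible; zero-variance
  polytopes are returned as repeated unique vectors; fold-changes from
  ~zero monoculture burden are flagged `activated_from_zero`, never
  divided.

## Limitations

* The joint-sum objective with a lexicographic parsimony step is a
  deterministic stand-in for bilevel community optimization (OptCom);
  allocation among members at a flat optimum is a modeling convention,
  not a prediction.
* Evidence gating is static; no kinetics, regulation, or dynamic
  community composition.
* Yield and burden denominators are conventions (community growth; sum
  of |pathway flux|) and should be quoted alongside any reported number.
* Reported exchange fluxes are single parsimonious solutions; always
  pair them with FVA ranges before interpreting a specific molecule's
  traffic as required.
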