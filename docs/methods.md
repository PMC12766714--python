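# Methods

This note documents the models and procedures implemented in `ebpr_gem`, the
assumptions they make, the parameters that matter, and what the synthetic
fixtures do and do not establish about real data.

## The cycle-based dynamic FBA model

### Model representation

A `MetabolicModel` is a stoichiometric network with flux bounds
(mmol·gDW⁻¹·h⁻¹) in which four kinds of reactions are first-class: the
biomass drain (whose flux is the growth rate μ in h⁻¹), the non-growth
associated maintenance (NGAM) ATP demand, exchange reactions (negative flux =
uptake, the COBRA community convention), and storage sinks. Storage sinks are
the boundary between the quasi-steady-state LP and the explicit storage
polymers of a polyphosphate-accumulating organism (PAO): each sink drains one
pool-compartment metabolite (a C4 PHA unit, a C6 glucosyl glycogen unit, or a
P1 polyphosphate unit), so a positive sink flux accumulates the polymer and a
negative flux mobilizes it. Every metabolite row, including extracellular and
pool species, is balanced in the LP; exchanges and sinks carry the boundary
flux. SBML Level 3 + FBC input/output goes through cobrapy; the extra
annotations (metabolite roles, atom counts, reaction tags) ride in SBML notes
and round-trip structurally.

### The three solves

* **FBA** — maximize (or minimize) one flux subject to steady state and
  bounds.
* **pFBA** — fix biomass at its optimum scaled by (1 − 10⁻⁶) to avoid
  numerical infeasibility, then minimize Σ|v| over *all* reactions via the
  standard split of each flux into two non-negative halves. The L1 norm
  includes exchange reactions; this is a documented choice, and sensitivity
  to it is limited on the fixture networks because exchange fluxes are pinned
  by the phase constraints.
* **Minimum total flux** — fix one carbon exchange at a given uptake rate and
  minimize Σ|v| with no growth objective. This is the anaerobic-phase
  objective: with maintenance as the only hard demand, the least-flux
  distribution routes carbon into storage through the fewest enzymatic steps,
  an LP stand-in for energy-efficient storage metabolism.

All LPs are solved with HiGHS (`scipy.optimize.linprog`) at 10⁻⁹
primal/dual feasibility tolerance. A status other than optimal or infeasible
raises; infeasibility is reported as data, not an exception, because the
substrate screen interprets it.

### Phase constraints

Anaerobic: the O₂ exchange lower bound is set to 0 (secretion still allowed)
and every ETC-tagged reaction is fixed to zero; ETC membership comes from
reaction tags supplied at model load (with a configurable id-keyword fallback
for models lacking annotations). Aerobic: O₂ uptake is restored to the
model's configured limit (default −1000, i.e. unbounded for practical
purposes), all carbon-source exchanges are closed for uptake, and storage
sinks are opened in the pool-consuming direction. Amino-acid exchanges are
deliberately not carbon exchanges: aerobic constraints leave them alone. Both
operations are idempotent and return modified copies.

### The cycle integrator

One cycle is 1.5 h anaerobic then 3.5 h aerobic at Δt = 0.2 h. Because
1.5/0.2 is not an integer, the final step of each phase is truncated (seven
0.2 h steps plus one 0.1 h step) so phase boundaries land exactly on the
configured durations. Each step solves an LP and advances the explicit
quantities by forward Euler: Q ← Q + v_Q·X·Δt for substrate, CO₂ and pools
(absolute amounts, 1 L reactor volume so mmol and mM coincide), and
X ← X·(1 + μΔt) for biomass. Anaerobic growth is fixed to zero — the
anaerobic objective is storage, not growth — and the effective uptake each
step is min(configured rate, remaining substrate / (X·Δt)), which prevents
the pool from going negative under Euler. The same rule caps pool-consuming
sink fluxes at pool/(atoms·X·Δt). An infeasible step terminates the
trajectory with a status flag; the substrate screen reads that flag as "not
utilizable" rather than aborting a batch.

Because every reaction in the synthetic network is carbon-balanced and the
bookkeeping is applied uniformly, the discrete carbon budget (substrate in,
CO₂ + storage + biomass carbon out, with a bucket for any other carbon
crossing an exchange) closes to LP solver tolerance at any Δt; `carbon_balance`
reports the residual so that any non-conservative model edit is caught
immediately.

### Aerobic storage replenishment

Under a biomass-maximizing aerobic objective there is no incentive to
resynthesize glycogen or polyphosphate, and pFBA's flux minimization sets the
replenishment routes to zero. This is the documented default; real PAOs
replenish both aerobically, so aerobic polyP/glycogen trajectories from this
simulator describe availability, not the full physiological cycle. The knob
that would change this (objective weights on the replenishment sinks) is
deliberately out of scope of the default configuration.

## The synthetic PAO network

`make_pao_model` builds a ~150-reaction network: five carbon sources
(acetate, propionate, lactate, glucose, glycerol) with exchange + transport
pairs, condensed glycolysis/TCA, an ETC lump (NADH + ½O₂ → 2 ATP), the three
storage pools with synthesis/degradation/sink reactions, NGAM, twenty lumped
amino-acid biosynthesis branches (2 acetyl-CoA + 2 ATP + NADH + NH₄⁺ per C4
amino acid) with reversible transporters, and a biomass reaction drawing
0.5 mmol of each amino acid plus 40 mmol ATP per gDW (40 C-mmol of biomass
carbon per gDW, close to the ~40 C-mmol·gDW⁻¹ of real cells).

Three calibration choices matter and are fixed once:

* **Activation costs.** Acetate and propionate activation cost 0.7 ATP per
  molecule. Combined with polyphosphate-driven ATP regeneration this puts the
  anaerobic phosphate-release : carbon-uptake ratio near 0.3 P-mol/C-mol,
  the range measured for VFA-fed PAO enrichments.
* **Degradation capacities.** PHA depolymerization (1.0 unit·gDW⁻¹·h⁻¹),
  glycogen phosphorolysis (0.3) and polyphosphate hydrolysis (2.6) carry
  finite Vmax bounds. These model enzyme capacity; without them a
  growth-maximizing LP drains an entire pool in one Euler step and the hard
  NGAM bound then makes the remaining steps infeasible. With the bounds, the
  aerobic phase consumes PHA over ~2.5 h and polyphosphate covers maintenance
  through the end of the cycle.
* **Anaerobic storage shunts.** With the ETC off, reduced substrates cannot
  re-oxidize surplus NADH, so lactate, glycerol and propionyl-CoA condense
  directly into PHA (with CO₂ loss) and glucose into glycogen — mirroring the
  substrate-dependent storage-polymer chemistry of real PAOs, at toy
  stoichiometry.

Default cycle pools (per gDW: 15 P-mmol polyP ≈ 0.47 g P/gDW, 2 C-mmol
glycogen, 0.1 C-mmol PHA, 5 mmol substrate in the reactor, uptake rate
3 mmol·gDW⁻¹·h⁻¹) are fixture calibrations chosen so that a polyP-rich PAO
inoculum sustains maintenance over a full cycle; they are reported in the
trajectory output and are not fitted to any measured cycle.

Knockouts are by name: one of the twenty amino-acid codes removes that
biosynthesis branch; transporter names (`lactate_transporter`, `lldP`,
`lctP`, `ptsG`, `manX`, `glpF`, …) remove membrane transport reactions while
leaving the exchange in place, which is exactly the genotype the substrate
screen's `no_transporter` failure stage detects.

## Screens

**Auxotrophy.** Aerobic minimal medium: one carbon source (acetate by
default), inorganic ions, O₂, all twenty amino-acid uptakes open at
−10 mmol·gDW⁻¹·h⁻¹, storage sinks closed (pools are not a medium component).
Twenty FBA solves, each with exactly one amino-acid uptake closed; a model is
auxotrophic for an amino acid when μ drops below 0.01 h⁻¹. Because closing a
bound can only shrink the feasible region, per-amino-acid growth never
exceeds the baseline — a property the tests check on every fixture.

**Secretion.** Same medium with amino-acid uptake closed. Growth is pinned at
a fraction (default 0.5) of its optimum and each amino-acid exchange is
maximized in turn (an FVA-style per-exchange maximization); export above
10⁻⁶ mmol·gDW⁻¹·h⁻¹ makes the amino acid secretable. The criterion
(growth fraction, flux tolerance) is this package's operationalization of an
otherwise under-specified notion of "secretion capacity"; both knobs are
exposed, and the secretable set shrinks monotonically as the growth fraction
rises.

**Substrate utilization.** One full cycle per model × substrate. A substrate
is utilizable when the cycle completes and the biomass yield — ΔX over
C-mmol consumed — exceeds 10⁻⁶ gDW/C-mmol (separating real from
numerically-zero yields). Failure stages are ordered: missing
exchange/transport route (`no_transporter`), anaerobic LP infeasibility,
then zero yield. Both anaerobic feasibility and aerobic yield are required;
requiring only one is a config-level change.

## Comparative-genomics procedures

**Core / clade-specific partitioning.** A family is core when present in at
least ⌈0.8·n⌉ genomes (n = 136 gives ≥ 109); clade-specific when present in
strictly more than 75% of one clade's members and absent from every genome
outside it. Both are pure counting rules; column order is irrelevant.

**Wagner parsimony.** Sankoff dynamic program over integer copy-number
states 0..max_count with edge cost 2·gains + 1·losses (penalties
configurable). No root prior: the root state minimizes total cost, matching
unrooted-style parsimony. Backtrace ties prefer the smallest ancestral count,
a deterministic rule that biases toward gains being recent and may differ
from other implementations' internal tie-breaking; total cost is unaffected
by tie-breaking and is verified against exhaustive enumeration. With unit
penalties and binary states the per-family event counts coincide with Fitch
parsimony changes, which the tests use as a second oracle. Families are
classified *ancestral* when the reconstructed count at the designated
last-common-ancestor node is positive, *derived* when zero there but positive
below. The DP state space is bounded by capping counts at the per-family
observed maximum (truncation warns).

**Dereplication.** QS = completeness − 5 × contamination. Pairs join when
symmetrized ANI and aligned fraction both meet the thresholds
(99% / 0.85 for strain-level dereplication, 95% / 0.30 for species
clusters; boundaries inclusive), asymmetric orientations symmetrized by the
maximum. Clusters are single-linkage connected components — a deliberate
simplification of dRep's two-stage greedy algorithm that is exact on
well-separated inputs and may split or merge differently near thresholds on
real data. Representatives maximize QS with lexicographic tie-breaking, so
output is independent of input order.

**Spacer matching.** Ungapped, both strands, full-spacer windows slid along
each contig (partial overlap at contig ends allowed down to the coverage
threshold); identity = matches/aligned length, coverage = aligned
length/spacer length; a match is retained only when identity ≥ 97%,
coverage ≥ 90% and mismatches ≤ 1 jointly. "At most one mismatch" is the
reading adopted for the mismatch rule (the strict end of the ambiguity).
With ≤ 1 mismatch allowed, gapped alignment cannot add hits, so no indel
handling exists. Non-ACGT characters always count as mismatches. Coordinates
are 0-based half-open on the contig forward strand. The infection rate is
the truncated whole-percent share of genomes with ≥ 1 retained link
(92/136 → 67); the exact fraction is reported alongside.

**Ecology.** Representative samples minimize Bray-Curtis dissimilarity
(Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ), via scipy) to the within-plant mean profile, ties and
all-zero degenerate plants resolving to the lexicographically smallest
sample id. Continental clade proportions normalize summed focal abundances
per continent (rows sum to 1 where the total is positive). The co-occurrence
network computes all-pairs Spearman ρ with mid-rank ties, two-sided p-values
(t approximation above n = 10, exact permutation at or below — exhaustive
and therefore exact, at factorial cost that is only paid for tiny sample
sets), Benjamini–Hochberg adjustment across all tested pairs (constant-taxon
pairs are skipped before adjustment), and retains |ρ| > 0.3 with q < 0.05.

## Synthetic data and what the tests show

Every generator is a pure function of its arguments; a global seed fans out
to per-generator substreams via SHA-256 of `(seed, label)`, so adding a
generator never changes existing fixtures. Gene matrices evolve binary
families root-to-leaves under per-branch Bernoulli gain/loss with recorded
event history; ANI fixtures are jittered block matrices with planted
partitions; spacer fixtures embed protospacers at controlled mismatch counts
and strands among decoys; abundance fixtures use a Gaussian copula for
planted rank correlations, log-normal marginals, and jittered within-plant
replicates.

Passing the recovery tests establishes that each procedure implements its
stated rule exactly and recovers planted truth under the generating model.
It does not establish performance on real data: the synthetic networks are
far smaller and cleaner than genome-scale reconstructions (no gap-filling
artifacts, no thermodynamically dubious loops beyond those pFBA suppresses),
gene-family evolution here is independent across families with homogeneous
rates, ANI blocks have no intermediate-identity chains, and abundance tables
have neither compositional closure effects nor zero inflation. The
Wagner-parsimony origin recovery (≈ 93–95% at 20 leaves, 500 families,
gain ≪ loss) quantifies reconstruction accuracy under the simulation's own
assumptions only.

## Problem sizes

Default test and acceptance runs use the desk-scale sizes the procedures
are specified at: ≤ 150-reaction networks (26 LP solves per cycle), 12-model
screen batches, 20-leaf / 500-family parsimony instances with exhaustive
oracles on ≤ 6-leaf trees, 9-genome ANI fixtures, 20 kb contigs with ≤ 50
spacers, and ≤ 80-sample abundance tables. These sizes exercise every code
path; scaling to study-size inputs (136 genomes, 10⁵ vOTUs, 828 samples) is
a matter of runtime, not algorithm.
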