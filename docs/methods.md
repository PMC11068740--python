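# Methods

## Model

A community of n species, each given as a genome-scale metabolic model, is
merged into one compartmentalised stoichiometric system. Member k's
metabolites and reactions are suffixed `_org<k>` (1-based). Each member
exchange reaction `EX_x(e)` is rewired into a transfer between the member's
extracellular metabolite and a shared pool metabolite `x(e)[u]`; one
community-level exchange reaction per pooled metabolite (named after the
untagged exchange id, so diet tables written against AGORA-style ids apply
directly) drains the pool to the environment with coefficient −1. The pool
mass-balance row then enforces that the community exchange flux of every
metabolite equals the sum of the member exchange fluxes — the constraint
that permits cross-feeding. Flux sign follows the COBRA convention
(positive = secretion, negative = uptake); all fluxes are mmol/gDW-h,
biomass fluxes h⁻¹.

Because maximising the summed biomass could otherwise let a non-growing
member run its metabolism as a pure bioreactor, every non-biomass reaction
of member k carries two coupling rows

    v_j^k − c·v_bio^k ≤ u      and      −v_j^k − c·v_bio^k ≤ u.

Both flux directions are coupled; a one-sided row would leave reversible
reactions uncoupled in reverse. Member pool-transfer (exchange) reactions
are coupled too by default (`include_exchanges=False` restricts coupling to
internal reactions). The constants are not dictated by the formulation; the
defaults c = 400 and u = 0.01 mmol/gDW-h follow the convention established
for coupled community models built from AGORA reconstructions, and both are
exposed as parameters.

Diets are tables of community exchange bounds. The default policy is
*closed*: exchanges absent from the diet get lower bound 0 (nothing
supplied), since diet files enumerate what the environment provides. An
*open* policy leaves unlisted exchanges at the built default (±1000
mmol/gDW-h, the COBRA "operational infinity"; truly infinite bounds would
break MILP gating and are not used anywhere).

## Workflow

1. **Joint FBA.** Maximise Σ_k v_bio^k. Records community growth and the
   member growth rates θ^k. An infeasible status here is reported as an
   error: the zero flux vector is always feasible for a well-formed
   community, so infeasibility signals malformed inputs rather than "no
   growth".
2. **SCFA maximisation.** Maximise w_ac·v_ac + w_bu·v_bu + w_pr·v_pr over
   community exchange fluxes subject to v_bio^k ≥ gr_opt_frac·θ^k
   (inequality, not equality: growth above the floor remains allowed).
   Constraint ids 2–4 are implemented as the unit weight triples. Exactly
   three weighted exchanges are supported per run; the ids are configurable
   so any three metabolites can stand in for the SCFA triple. Individual
   fluxes in the objective may be negative (uptake); no nonnegativity is
   imposed on them, so a weighted optimum can consume one SCFA to produce
   another.
3. **Sequential reduction.** Tentatively delete species in sequence
   (user-supplied, else a seeded random permutation); a deletion sticks iff
   the remaining community still passes the growth and SCFA thresholds (one
   FBA LP + one FVA LP). Deletion zeroes all flux bounds of the member's
   reactions and is reversible (bounds are archived, and the matrix shape
   never changes, which keeps MILP assembly and restore trivial). The
   sequence is swept repeatedly until ≤ `milp_size` members remain or a
   full pass deletes nothing; in the latter case the MILP simply runs on
   whatever remains.
4. **Membership MILP.** Binary X^k per remaining member; minimise Σ X^k
   subject to mass balance, coupling, the thresholds, and gated bounds
   LB_j^k·X^k ≤ v_j^k ≤ UB_j^k·X^k for **all** reactions of member k. Gating
   only the biomass row and relying on coupling would leave an excluded
   member fluxes of magnitude up to u; the full gating makes exclusion
   exact. The literal coupling-only variant is retained behind
   `gate_mode="coupling_only"` for comparison.

### Growth threshold modes

The per-species growth threshold v_bio^k ≥ gr_frac·θ^k conflicts with
exclusion (X^k = 0 forces v_bio^k = 0), so two modes are provided.

* `community` (default): Σ_k v_bio^k ≥ gr_frac·Σ_k θ^k. This is the
  arithmetic that community-level reports of "80 % growth retention"
  correspond to, and it is well-defined for any membership vector.
* `per_species`: v_bio^k ≥ gr_frac·θ^k·X^k — membership-gated and still
  linear because gr_frac·θ^k is a constant. Stricter; communities whose
  optimum starves some member of substrate (θ^k = 0) are unaffected for
  those members.

### Degenerate thresholds

If both thresholds are ≤ 0 (e.g. gr_frac = scfa_frac = 0, or a community
that cannot produce any weighted SCFA so ϑ_SCFA = 0), the MILP optimum is
the empty community. The package reports the empty set with a warning
rather than inventing a singleton; the brute-force oracle follows the same
convention.

### Enumeration and iterations

Alternative optima are enumerated by integer cuts Σ_{k∈S} X^k ≤ |S|−1; by
default enumeration stops when the optimum's cardinality exceeds the first
optimum's (configurable), at infeasibility, or at `max_solutions`. This
does not exhaustively list all minimal communities of larger cardinalities.
`find_minimal_microbiomes` additionally reruns reduction + MILP with
deletion-sequence seeds `seed + i` for i = 0..iterations−1 and deduplicates
on membership, since the reduction can steer different runs to different
(mutually exclusive) optima. All randomness flows from these integer seeds;
identical inputs and seed replay identically.

## Numerical choices

* Default LP/MILP backend is HiGHS (via scipy); GLPK via optlang is the
  independent second backend used by the solver-agreement tests. MILP
  relative gap is set to 0; objectives are small integer cardinalities, so
  rounding |obj − round(obj)| < 1e-6 is asserted in tests.
* Feasibility/integrality tolerance 1e-6. Threshold comparisons subtract a
  slack of 1e-9 (`≥ threshold − 1e-9`) so solutions sitting exactly on a
  threshold do not flap between feasible and infeasible across solvers.
* Binary variables are rounded to the nearest integer on extraction.
* MILP cardinality ties are broken arbitrarily by the solver; any optimal
  support is a valid answer, with enumeration available for the rest.

## Synthetic communities and the oracle

The toy generator emulates the trophic structure of fibre fermentation: a
degrader (fibre → monomer + biomass), SCFA producers with separate growth
(monomer → biomass) and fermentation (monomer → SCFA + less biomass)
routes so growth and production compete for substrate, cross-feeders
(monomer → lactate + biomass) and freeloaders (monomer → biomass). Diets
supply fibre only. Yields and uptake bounds are small integers and halves,
so all LP optima are exact rationals and expected values can be derived by
hand (e.g. a 1 % growth concession at the default gr_opt_frac = 0.99 buys
fermentation flux 0.01·y_g·M/(y_g − y_f) for monomer supply M).

What the toys do **not** emulate: genome-scale network size and redundancy,
realistic biomass compositions, cofactor/ATP accounting, multiple
substrates per species, or curated diet tables. Passing tests therefore
certify the *algorithmic* properties (optimality versus enumeration,
constraint satisfaction, monotone parameter response, determinism) — not
quantitative agreement with any real community, which depends entirely on
the input reconstructions and diet.

The brute-force oracle enumerates all nonempty subsets of ≤ 12 active
members, testing each by a growth LP and a SCFA LP assembled **densely and
independently** (its own variable ordering, plain-loop matrix construction,
direct `scipy.optimize.linprog` calls) — it shares no constraint-assembly
code with the community/solve/workflow modules, so MILP–oracle agreement is
evidence, not tautology. The same dense assembly independently re-verifies
the residuals of every returned solution. For large parameter sweeps the
oracle can stop after fully enumerating the smallest feasible cardinality
(`min_cardinality_only`), which changes nothing about the mathematics.

The acceptance sweep uses 20 seeded random toys of 3–8 members crossed
with all four constraint ids and a 4×4 grid of retention fractions; the
demonstration runs use the fixed 9-member fixture. These sizes keep the
full suite comfortably within a few minutes while covering every role
combination and the degenerate corners (zero thresholds, infeasible
full-retention corners).

## Known limitations

* Cross-feeding is forced whenever it helps the summed-biomass objective;
  spatial separation or regulation is not modelled. Abundances are absent —
  the formulation weights every member's biomass equally.
* Step 2's growth floors use θ^k from one (possibly degenerate) joint-FBA
  optimum; alternate Step-1 optima could yield different floors.
* Enumeration with integer cuts guarantees completeness only at the minimal
  cardinality, and the reduction step can exclude some optima before the
  MILP ever sees them (mitigated by iterations with different seeds).
* Dynamic behaviour (dFBA), community stability and abundance estimation
  are out of scope.
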