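# Methods

## The screening problem

`actd` treats target discovery as a fuzzy multi-objective hierarchical
optimization over a pair of constraint-based metabolic models: a cancer
(CA) model and a healthy-counterpart (HT) model sharing most of their
reactions.  A candidate perturbation (enzyme knockout/modulation or
antimetabolite) is applied to both models; the treated CA cell and the
perturbed HT cell are each simulated, and four goals are scored on
[0, 1]: CA mortality, HT viability, dissimilarity of the perturbed HT
state from the CA template, and similarity to the HT template.  The
assumption throughout is the standard constraint-based one: cells are at
metabolic steady state, `N(v_f − v_b) = 0`, with fluxes bounded in
mmol·gDW⁻¹·h⁻¹.

## Inner problems

Reactions are flux-split into nonnegative forward/backward variables.
The split preserves the net-flux interval exactly, including positive
lower bounds (a forced net flux becomes a forced forward flux).
Exchange reactions are identified by single-species stoichiometry and
excluded from the UFD penalty set; whether exchanges belong in the
quadratic objective is not settled by the formulation we implement, and
we chose the internal-only reading — exchange fluxes remain constrained
by mass balance through the internal reactions they feed.

* **FBA (LP)**: maximize the biomass net flux (CA) or the ATP-demand net
  flux (HT), solved with HiGHS at 1e-9 feasibility tolerances.  An
  infeasible *perturbed* problem is a valid outcome — the perturbation is
  lethal/incoherent — and is mapped to a zero flux state (the mortality
  interpretation) with its status recorded; an infeasible *unperturbed*
  model is a configuration error.
* **UFD (QP)**: minimize `Σ_{k∈internal} c_k (v_f,k² + v_b,k²)` subject
  to steady state, bounds, and the objective floor at the full FBA
  optimum (fraction 1.0 by default, configurable).  Weights come from
  reaction confidence classes: high ¼, medium ½, negative ¾,
  other/non-gene 1.  The QP is convex; the penalty suppresses futile
  bidirectional flux, so no complementarity constraint is needed.

Numerically, the QP is solved with SLSQP (active-set SQP, analytic
gradient) started from the FBA vertex; a solution is accepted only if the
steady-state residual is ≤ 1e-8 and the floor and bounds hold.  A polish
round pins variables below 1e-4 to their zero bound and re-solves,
keeping the result only when it stays feasible and no worse — interior
dust at the 1e-5 level otherwise contaminates the template standard
levels and turns membership ramps into cliffs.  trust-constr is the
fallback when SLSQP's answer fails validation, and the (feasible) FBA
start is the fallback of last resort.  All solvers are deterministic, so
templates are bit-stable across runs.

## GPR logic

Rules are Boolean trees (AND = complex, OR = isozymes) parsed from
SBML-FBC-style strings.  Each OR-branch across all reactions becomes a
candidate enzyme; enzymes with *identical reaction sets* are merged into
one feasible representative, because regulating any member is
equivalent — this is also why two single-reaction isozymes with the same
reaction set do not make that reaction isozyme-buffered, while a
promiscuous isozyme (distinct reaction set) does.  Buffering is
evaluated against the *whole* target set of a candidate: all genes of
the targeted enzymes (including merged partners) are switched off and
the rule re-evaluated, so a double knockout of an isozyme pair is
correctly lethal rather than doubly buffered.  Buffered reactions are
held within ±ε of basal (ε = 0.03 by default) under both knockout and
down-regulation.

Gene expression classification uses quantile thresholds (default 25/50/
75%) over the *positive* expression values; zeros and sub-threshold
values are `not_detected`.  Confidence propagation is monotone: OR takes
the most-confident branch, AND the least-confident gene; gene groups map
to reaction classes as high→high, medium→medium, low→negative,
not_detected→other.  The exact mapping is a design choice of this
package (the narrative description it formalizes names no cutoffs).

## Membership grades and the hierarchy

One-sided minimization/maximization grades are linear ramps between a
user-settable LB and UB; two-sided similarity grades ramp to 0 at LB/UB
with value 1 at the standard level ST, clamped to [0, 1]; dissimilarity
is the complement.  Degenerate ramps (ST = LB or UB = LB) collapse to
indicators, which matters because healthy templates legitimately have
zero biomass flux.  Auto-built one-sided specs floor the UB at 1e-6 for
the same reason.

Default bounds: mortality grades use LB = 0, UB = the CA template's
biomass and ATP values; viability uses fuzzy minimization of perturbed
HT biomass (UB = HT template biomass) and fuzzy maximization of
perturbed HT ATP (UB = the HT ATP optimum).  Per-element two-sided specs
use ST = template value and half-width `max(α·|ST|, w_min)` with α = 1.0
and `w_min = 0.1 ×` the median nonzero template magnitude, making bands
scale-aware and giving zero-valued elements a nonzero tolerance.
Narrower bands (α ≈ 0.3) sharpen the discrimination between low- and
high-side-effect targets; α is a config parameter.

The comparison universe for deviation grades is the set of internal
reaction directions and base metabolites shared by both models with a
nonzero value (> 1e-6) in at least one template; all-zero elements carry
no signal and would make the ramps degenerate.  Per-element grades are
aggregated by arithmetic mean (bounded and symmetric), the four
resulting grades by mean–min, and the decision objective is
`η_D = (η_TR + min{η_TR, η_CV, η_MD})/2` — never exceeding the mortality
grade and equal to it whenever mortality is the binding goal.

Metabolite flow rates follow the compartment-pooled production sum: for
each species copy, positive-coefficient forward fluxes plus
`−N_ij·v_b,j` over negative coefficients — i.e. reverse flux through a
consumer counts as production, taken literally from the defining
algebra — then pooled over compartments by base id.

## Outer search (NHDE)

The mixed-integer outer problem (choose target ids and δ) is searched by
a nested hybrid differential evolution: DE/rand/1 mutation on a
continuous encoding (slot indices decoded by flooring, δ in [0, 1]),
binomial crossover with one forced component, greedy one-to-one
selection on the lexicographic key (η_D, η_TR), and migration — when
population diversity around the best individual falls below a tolerance,
80% of the others are re-randomized.  Defaults (population 20, F = 0.5,
CR = 0.8, 200 generations, δ quantized to 1e-3 for memoization) follow
common hybrid-DE practice and are config-overridable; they are this
package's choices, not values from any publication.  Fitness
evaluations are memoized on the sorted (kind, id, mode, quantized δ)
tuple, and the memo of a run is returned as a ranked archive —
screening reports top-k tables, not a single winner.  Ranking keys
round grades to 1e-9 and break ties by target id, since distinct
targets can produce bit-identical perturbed states; for the same reason
"recovering the optimum" in the solver-validation battery is judged on
the achieved (η_D, η_MD) value.

Two-target screens use the two-group strategy: one slot per group,
searching |G1|·|G2| cross pairs.  Spaces of ≤ 2000 pairs are enumerated
exhaustively instead (the exhaustive path and NHDE agree on such spaces
by construction and by test).

## Synthetic fixtures

The toy generator builds a shared core — glucose/glutamine uptake,
glycolysis, a pentose branch, a TCA-like ATP module, a pyrimidine-like
nucleotide branch feeding biomass, an ATP maintenance demand with lower
bound 1 — plus inert filler units to reach the requested size.  The CA
model adds a glutaminolysis branch and higher glucose uptake (10 vs 6,
with small seeded jitter); expression is log-normal with
pathway-specific emphasis per model, so confidence weights differ
between CA and HT.  Planted ground truth: `Gcad` (nucleotide synthesis)
is CA-essential but HT-dispensable — the ideal low-side-effect target;
`Gglyc1` (upper glycolysis) is shared-essential; `Gglyc2a`/`Gglyc2b` are
isozymes, individually buffered and jointly synergistic; `Gcadb` is a
redundant enzyme removed by GPR reduction; `orot[c]` knockout is the
antimetabolite mirror of the `Gcad` knockout.

What the fixtures do *not* emulate: realistic human network scale
(thousands of reactions), compartmentalized energy metabolism, cofactor
stoichiometry, growth-associated maintenance, or expression noise
structure of real RNA-seq.  Passing the fixture batteries therefore
shows the machinery is correct and the planted orderings are recovered;
it does not certify predictions on real tissue models, whose grades also
depend on user-supplied membership bounds.  Problem sizes throughout
(tens of reactions, populations of 8–20, 10–30 generations, 10-seed
batteries) were chosen so that exhaustive enumeration and dense-grid
oracles remain exact references for every stochastic component.

## Known limitations

* Mortality's ATP component is near-binary on the toys: the ATP demand
  is pinned at its maintenance bound by the UFD in both template and
  treated states, so η_ATP^TR only distinguishes "maintenance still
  achievable" from "not".  Richer energy metabolism would grade this
  continuously.
* The ε-window on buffered reactions *forces* flux near basal; combined
  with other knockouts this can make the perturbed model infeasible,
  which the pipeline interprets as lethality.  This is a consequence of
  the bracketed bound formulation, not a solver artifact.
* Up-regulation of the backward direction of reversible consumers
  (metabolite-centric mode) follows the bound algebra literally;
  thermodynamic plausibility of the induced state is not checked.
* Tables of per-target grades for real tissue models are not
  reproducible from this repository alone: they require the deposited
  tissue-specific models and the membership bounds used with them.
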