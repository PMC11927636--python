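# Methods

## Scope and model

`midflux` implements steady-state ¹³C metabolic flux analysis at the level
of whole-molecule mass isotopomer distributions (MIDs). The user supplies a
reaction network in which every reaction is unidirectional (`0 ≤ lb ≤ ub`;
reversible steps are written as two opposed reactions), carries an atom map
assigning each product carbon to a substrate carbon (or to an unlabeled
source), and each metabolite is declared *balanced* (intracellular, steady
state enforced), *substrate* (network input with fixed labeling) or *sink*
(excreted/accumulated, no balance row). Symmetric intermediates such as
succinate or fumarate can be modeled as two atom-map variants of the same
step, each carrying half the flux.

From the reaction list the package assembles the equality system
`A·v = b`: one row per balanced metabolite (production − consumption = 0)
plus one row per user equality (typically fixed, experimentally measured
exchange rates). Rows and columns are ordered by sorted id, so the system
is independent of input order.

## Forward model

The predicted MID of metabolite *i* is the flux-weighted average of the
MIDs produced by each generating reaction, `M̃ᵢ = Σⱼ vⱼᵢMⱼᵢ / Σⱼ vⱼᵢ`.
Whole-molecule MIDs are not sufficient statistics for this recursion:
a cleavage or condensation reaction needs to know *which* carbons are
labeled, not just how many. The package therefore tracks, for every
metabolite with *n* carbons, the full positional-isotopomer distribution —
a vector over all 2ⁿ labeling patterns — and marginalizes to MIDs (by
popcount) only for output and for the fitting loss. Substrate pools of one
reaction are treated as statistically independent, the standard assumption
of steady-state MFA; substrate-kind metabolites with partial labeling are
assigned the exchangeable (symmetric) positional distribution consistent
with their declared MID. Per (reaction, product) pair the implementation
precompiles index arrays that extract each contributing substrate fragment
(a bincount marginalization) and fold fragments together (an outer product
scattered onto product bit positions), so repeated evaluation inside the
optimizer is a handful of vectorized operations.

Positional tracking is exact and feasible for the intended network sizes
(the fixture's largest metabolite has 6 carbons, i.e. 64 states); the
implementation refuses metabolites beyond 16 carbons rather than
approximate.

Evaluation order: the metabolite dependency graph is condensed into
strongly connected components and processed in topological order. Acyclic
components are evaluated directly (the precursor recursion); cyclic
components (e.g. a TCA cycle) are solved by damped fixed-point iteration
from the all-unlabeled state (damping 0.5, convergence tolerance 1e-9 on
the positional vectors, at most 10,000 sweeps). The fixed point of this
flux-weighted averaging map is unique for positive-flux irreducible
systems, and the damped iteration is a contraction in practice; the
iteration count and final residual are reported in the `MIDSet`. A
metabolite with zero total inflow under the current flux vector is pruned
to 100% M+0 and flagged rather than raising, so optimizer iterates at the
boundary of the feasible box remain evaluable.

Natural-isotope abundance is not modeled; tracer impurity can be expressed
through the per-substrate `purity` parameter (effective MID =
`purity · MID + (1 − purity) · M+0`), default 1.0.

## Loss and fitting

Replicate MIDs are averaged per metabolite (arithmetic mean, renormalized)
before fitting. The per-metabolite loss is the observed-weighted
Kullback–Leibler divergence

    Lᵢ = Σⱼ Mᵢⱼ · ln(Mᵢⱼ / M̃ᵢⱼ)   (nats),

summed over measured metabolites to `L_total`. Both distributions are
floored at ε = 1e-9 and renormalized before the logarithm, which keeps the
loss finite when a boundary flux predicts an exactly-zero isotopologue that
was observed. This form is nonnegative and vanishes exactly when predicted
and observed MIDs agree (up to ε), which makes the minimization well posed.

The constrained problem `min L_total(v) s.t. A·v = b, lb ≤ v ≤ ub` is
solved by eliminating the equalities exactly: `v = v₀ + N·z`, where `N` is
an orthonormal null-space basis of `A` and `v₀` a feasible anchor chosen to
maximize its smallest distance to any bound (a max-slack LP), so every
iterate satisfies the balance equations to machine precision and only the
box bounds remain, as linear inequalities in `z`. Each local solve uses
SLSQP with finite-difference gradients (tolerance 1e-9, at most 500
iterations). Multi-start: starting points are drawn uniformly in the
bounding box and projected onto the feasible affine space by up to 50
rounds of alternating projection and clipping; if the residual has not
closed, a ray is cast inside the feasible affine space from the interior
anchor toward the draw and stopped just inside the box — always feasible
and seed-deterministic. Starts that fail to converge, violate a bound by
more than 1e-7, or end with an equality residual above 1e-6 are dropped and
counted in the diagnostics. The retained solutions are the `n_keep` lowest
losses, tie-broken by start index, so a run is bit-reproducible from
`(model, data, seed, n_starts)`.

The study-scale defaults are 10,000 starts keeping the best 50. The test
suite and the acceptance script use desk-scale analogues (typically 10–200
starts, keeping 3–50) that exercise the same code path on the shipped
fixture; with only four free degrees of freedom after the fixed exchange
rates, a few dozen starts already locate the global basin reliably.

## Flux indices

With a role map assigning reactions to the roles `glucose_uptake`,
`lactate_excretion`, `pyruvate_to_tca` and `citrate_efflux_route`:

* cancer index = lactate excretion / glucose uptake (Warburg-style lactate
  ratio),
* TCA index = pyruvate entry into the TCA cycle / glucose uptake,
* noncanonical TCA index = citrate efflux / pyruvate entry into the cycle.

A zero denominator yields an explicitly flagged undefined value, never a
silent zero. Since published descriptions of such indices rarely pin down
the exact numerator and denominator, the formulas are deliberately
user-overridable through the role map and are recorded verbatim in every
output.

## Fixture network and synthetic data

The shipped fixture (19 reactions, 11 balanced metabolites) covers: glucose
uptake; lumped upper glycolysis cleaving hexose into two trioses (with the
DHAP half entering in inverted carbon order); oxidative PPP releasing C1 as
CO₂ with a lumped non-oxidative return of pentose carbons; lower glycolysis
to 3-phosphoglycerate; the de novo serine branch and competing unlabeled
medium-serine uptake; serine cleavage to glycine plus the CH₂-THF one-carbon
unit; a lumped methionine cycle carrying the methyl carbon into SAM;
pyruvate fed by glycolysis and unlabeled alanine, drained by lactate
excretion and PDH decarboxylation; acetyl-CoA fed additionally by unlabeled
β-oxidation-derived acetyl units; and citrate synthesis (acetyl-CoA +
unlabeled OAA) split between oxidation and efflux. Eight metabolites are
"measured" (P5P, 3PG, serine, glycine, pyruvate, citrate, lactate, SAM).

Four exchange rates (glucose, serine, alanine, acetyl-unit inflows) are
fixed by constraint, emulating measured uptake rates. This leaves four free
degrees of freedom: the PPP split, the serine-branch split, the
lactate/PDH split and the citrate oxidation/efflux split. The first three
are identifiable from the measured MIDs (serine labeling dilution pins the
serine branch, pyruvate/lactate dilution pins lower glycolysis and hence
the PPP split through the 3PG balance, citrate M+2 pins PDH); the citrate
split is structurally unidentifiable — both routes drain the same pool —
and is excluded from recovery checks. Keeping one deliberately
unidentifiable flux in the fixture makes the solution-set machinery
(interquartile ranges, rank-overlap) demonstrably meaningful.

Ground-truth regimes are published constants, not random draws: `vehicle`
(serine branch 1.0, PPP 1.5, lactate share 0.69 of the pyruvate node) and
`shift` (serine branch 2.5, PPP 0.8, lactate share 0.75), both on a fixed
glucose uptake of 10 rate units. The shift regime forward-simulates to a
higher SAM M+1 fraction (0.556 vs 0.333) and a higher cancer index (1.40 vs
1.35). Measurement noise is i.i.d. Gaussian per MID entry (default
sd 0.01), clipped at zero and renormalized, with triplicate replicates by
default. The clipping introduces a small positive bias at entries near
zero (at most sd/√(2π) per entry before renormalization); the replicate-
averaging test accounts for exactly this bound.

What the generator does *not* emulate: natural-abundance contamination,
metabolite-specific error magnitudes, correlated (peak-integration) errors,
missing isotopologues, or isotopically non-stationary labeling. Passing the
recovery tests therefore demonstrates correctness of the inference
machinery under the stated error model, not robustness to every artifact of
real LC-MS data.

## Numerical choices

* Feasibility tolerance for retained solutions: ‖A·v − b‖∞ ≤ 1e-6 (null-space
  parametrization typically achieves ~1e-14).
* MID construction renormalizes and rejects negative entries; predicted
  MIDs sum to 1 within 1e-8 by construction (weighted averages of
  normalized distributions).
* ε-floor in the loss: 1e-9 on both distributions, then renormalization.
* Fixed-point damping 0.5; tolerance 1e-9; maximum 10,000 sweeps; raises on
  non-convergence rather than returning a stale state.
* Ties in the solution ranking are broken by start index, making reports
  byte-identical across reruns of the same configuration.

## Problem sizes used in the shipped checks

The randomized forward-model validation uses 50 random acyclic networks of
at most 6 reactions and 4 carbons per metabolite, compared against an
exhaustive dictionary-based enumeration; the cycle check compares the
damped fixed point against a direct linear solve over all positional
states. Recovery checks run 200 starts on noise-free data (expecting ≤ 2%
relative error on identifiable fluxes and best loss < 1e-6) and 12 starts
on each of 20 noisy datasets (expecting ≤ 10% median relative error).
These sizes are the package's desk-scale defaults and complete in about a
minute; they scale linearly in the number of starts for larger studies.

## Known limitations

* MID-level fitting with positional tracking internal to the forward model;
  tandem-MS fragment measurements are not supported.
* No confidence intervals beyond the multi-start solution-set spread
  (no profile likelihood or posterior sampling).
* No natural-abundance correction of measured spectra; inputs are assumed
  already corrected.
* Conditions are fitted independently; there is no joint multi-condition
  regularization.
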