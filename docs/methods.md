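# Methods

## Model

The package minimizes the "inconvenience" of dietary change: the sum of
SD-standardized squared deviations from an observed diet, at the food
category *and* food group level, under linear nutritional and environmental
constraints.  The two-level objective reflects that substitution among
closely related products (poultry for beef, mycoprotein for poultry) is
easier than substitution across groups (porridge for beef): category
deviations are penalized individually, and the group total's deviation is
penalized again with weight `z` (default 2 for every group).

Deviations are split into non-negative increase and decrease parts so the
two directions can carry different penalties.  The directional weights are
a popularity proxy: within each group, baseline intake is min–max
normalized to `s ∈ [0, 1]`, and `w⁺ = 2 − s`, `w⁻ = 1 + s`.  Both weights
lie in [1, 2] and sum to 3.  A novel food enters the survey with baseline
0 — the group minimum — and therefore `w⁺ = 2, w⁻ = 1`: the model treats it
as the least popular member of its host group, which is the mechanism that
keeps its inclusion conservative.  Because the novel food has no observed
intake variance, its SD is imputed as the mean SD of reference categories
(by default the five largest-intake members of the host group).

Assumptions worth stating explicitly:

* quadratic penalties mean many small changes are preferred to few large
  ones — the population-level reading of acceptability;
* SD standardization means foods with large natural intake variation are
  allowed to move more;
* popularity (baseline intake rank within the group) is a proxy for
  preference; it is not estimated from stated or revealed preferences.

## Constraints

All constraints are linear in the quantity vector (g/day).  Families:
nutrient bounds (absolute per day, or percent of dietary energy linearized
against the fixed energy target — valid because energy is an equality);
energy pinned at its observed level; per-category boxes at the 5th/95th
percentiles of observed intake, with a zero 95th percentile replaced by the
mean observed intake; a group-level cap at the host group's observed 95th
percentile for the novel food (it gets no individual box beyond
non-negativity); fixed categories (water) pinned at baseline; total food
mass within ±20% of baseline (fixed categories included); an optional GHGE
cap; optional group-total equalities.  The g/day ↔ per-100 g conversion
factor 0.01 is applied only in constraint/objective assembly, never in the
data layer.  Percent-of-energy conversion uses Atwater-style kJ/g factors
(protein/carbohydrate 17, fat 37, fiber 8, alcohol 29), overridable per
bound.

## Solving

The QP is assembled directly in the split variables (2n + 2m of them) with
equality rows linking group splits to member category splits.  Strictly
positive weights make the program strictly convex, so the optimum is unique
in the quantities and the optimal deviation of every category and group is
one-sided (complementarity) — the audit asserts this instead of assuming
it.  The solve has three stages:

1. an LP feasibility phase (HiGHS); an infeasible system is diagnosed with
   an elastic relaxation that minimizes total constraint violation and
   reports the families needing slack;
2. a trust-region interior solve (`scipy.optimize.minimize`,
   `trust-constr`, analytic gradient and constant diagonal Hessian,
   `gtol 1e-10`); the solution is then re-expressed with one-sided splits,
   which never worsens the objective;
3. an exact KKT polish on the detected active set, accepted only if it is
   feasible (1e-8) and not worse than the interior solution.

If the baseline diet is feasible it is returned immediately — it is the
unconstrained minimizer.  The LP comparator solves to a HiGHS vertex;
possible alternative optima are flagged from zero reduced costs at bounds.

Audit tolerances: constraint rows 1e-6 absolute scaled by row norm;
complementarity 1e-6 scaled by the category SD; objective recomputation
1e-6 relative.  On random small instances the QP objective agrees with an
independent reduced-space SLSQP minimizer to better than 1e-4 relative, and
the LP with exhaustive vertex enumeration to 1e-6 (both in the test suite).

## Linear comparator

The piecewise-linear model measures relative deviation `|q − q⁰| / q⁰`.
This is undefined for a zero-baseline category, so the novel food's
denominator defaults to its imputed SD — dimensionless and on the same
scale as the SD-standardized quadratic terms — and is configurable.  Group
terms (weight `z`, denominator `Q⁰`) mirror the quadratic model's two-level
structure and are on by default, as are the directional category weights;
both are toggleable.  These choices make the "no penalty weights" variant
meaningful for both engines.  Vertex solutions concentrate change in few
categories, the characteristic contrast with the quadratic model; the
packaged fixture regression asserts this direction, not a magnitude.

## Scenarios and sensitivity

NUTR optimizes under everything except the GHGE cap.  The ladder then caps
GHGE at `(1 − x)·GHGE(NUTR)` for strictly increasing `x` (default grid 5%
to 60% in 5% steps, configurable) while fixing the host-group *total* at
its NUTR value — composition inside the group stays free, which is exactly
what enables the within-meat substitution analysis.  The ladder truncates
at the first infeasible step; `max_feasible_reduction` bisects the
feasibility frontier using the cheap LP phase.  Stratum-specific runs
(male/female) are pure data changes.

Sensitivity variants change exactly one declared input (asserted in tests
by diffing the assembled model arrays): novel-food nutrient profile
replacement, category-weight removal (`w± = 1`, `z` unchanged — only
category weights are removed), ±50% scaling of the novel food's GHGE
coefficient, and engine swap.  The variant grid is declarative JSON.

## Synthetic surveys

The generator emulates the *structure* of a national dietary survey
aggregated to categories: default 79 categories in 13 groups; per-group
lognormal (right-skewed) baselines; SDs at 80% of baseline with a 1 g
floor; boxes at 0.2–0.6× (p5) and 1.6–3.0× (p95) baseline; positive
nutrient/GHGE/price coefficients; one fixed water category; one
zero-baseline novel food in the meat group with a mycoprotein-like profile
(355.6 kJ/100 g, protein-rich, GHGE below the host-group mean, price near
the group maximum).  One integer seed controls all draws.  It does **not**
emulate any country's actual magnitudes, correlations between nutrients
within a food, or realistic nutrient co-occurrence — so passing tests
demonstrate the machinery and the qualitative substitution economics, not
quantitative agreement with any real population.

`make_feasible_spec` brackets every nutrient at (1 ± slack)×baseline so the
observed diet is always feasible; `make_binding_spec` raises one nutrient's
lower bound to (1 + push)×baseline to force substitution.  Tests and the
acceptance script use a protein push of 0.1 on the default survey size and
a four-step ladder (10–40%), sizes chosen to exercise every constraint
family while keeping a full run in minutes.

## Design choices on genuinely open points

* Zero total intake in profile aggregation raises an error instead of
  falling back to an unweighted mean — silent fallbacks hide data problems.
* Degenerate weight groups (all baselines equal) get `s = 0.5`, i.e. the
  neutral `w⁺ = w⁻ = 1.5`; ties at the group min/max all receive the
  extreme weight.
* Popularity is normalized over the full group; no sub-grouping by intake
  magnitude is attempted.
* Equalities are exact rows, not inequality pairs; non-negativity is always
  imposed; the mass band includes fixed categories on both sides.
* Group SDs and the group 95th percentile are treated as observed survey
  inputs (the generator produces them; files supply them); they are never
  derived from category-level values.
* Item-to-category aggregation (intake-weighted nutrient averaging, yield
  factors, electricity-mix GHGE rescaling, price derivation) is provided as
  data-preparation operations for users with item-level data; the optimizer
  itself consumes pre-aggregated category tables.

## Known limitations

* No preference elicitation: weights come from intake ranks only.
* Absolute nutrient bounds and %-of-energy bounds only; no per-protein
  amino-acid bases.
* No integer or cardinality constraints; no multi-objective scalarization.
* The interior QP solve carries ~1e-3 g/day noise on near-degenerate
  coordinates; the audit and the KKT polish bound, but do not eliminate,
  this.
* Scenarios freeing the host-group total under GHGE caps are not provided.
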