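# dietopt

Acceptability-weighted diet optimization for introducing a novel food (e.g.
a mycoprotein meat alternative) into an observed diet, under nutritional,
feasibility, total-mass and greenhouse-gas constraints.

## Who this is for

Researchers in nutrition and sustainable-diet modelling who want to simulate
*culturally acceptable* dietary change: instead of asking what the optimal
diet is, the model asks for the smallest acceptable perturbation of the diet
a population actually eats that satisfies nutrient recommendations and a
greenhouse-gas (GHGE) target — with a novel food available as an imperfect
substitute inside its host food group.

## The model

The diet is described by daily quantities `q_i` (g/day) of `n` food
categories partitioned into `m` food groups with totals
`Q_j = Σ_{i∈S_j} q_i`.  Starting from the observed diet `q⁰` the model
solves the strictly convex quadratic program

```
min  Σ_i [ w_i⁺ ((q_i⁺ − q_i⁰)/σ_i)² + w_i⁻ ((q_i⁻ − q_i⁰)/σ_i)² ]
   + Σ_j z_j [ ((Q_j⁺ − Q_j⁰)/σ_j)² + ((Q_j⁻ − Q_j⁰)/σ_j)² ]
```

in split deviation variables `q_i = q_i⁺ + q_i⁻ − q_i⁰` with
`q_i⁺ ≥ q_i⁰` (increases) and `q_i⁻ ≤ q_i⁰` (decreases), and analogously at
the group level.  Deviations are standardized by the population SD of
observed intake (`σ_i`, `σ_j`), so changes are measured against each food's
natural variation.  The directional penalty weights encode within-group
popularity via min–max normalization of baseline intake `s_i`:

```
w_i⁺ = 2 − s_i ,   w_i⁻ = 1 + s_i ,   s_i = (q_i⁰ − min_{S_j} q⁰) / (max_{S_j} q⁰ − min_{S_j} q⁰)
```

so every weight lies in [1, 2] and `w⁺ + w⁻ = 3`: popular foods are cheap to
increase and expensive to decrease; a novel food (baseline 0, the group
minimum) gets `w⁺ = 2, w⁻ = 1` — maximally penalized to grow, free to stay
absent.  Group weights default to `z_j = 2`, making between-group
substitution harder than within-group substitution.

Constraints: nutrient bounds (absolute per day or % of energy), dietary
energy fixed at its observed level, per-category feasible ranges
[5th, 95th percentile of observed intake] (a zero 95th percentile is
replaced by the mean intake), a group-level 95th-percentile cap for the
novel food's host group, fixed categories (drinking water), total food mass
within ±20% of baseline, and an optional cap on diet GHGE.

The scenario engine first solves the nutritionally adequate **NUTR** diet
(no GHGE cap), then a **NUTR+GHGE-X%** ladder capping GHGE at
`(1 − x)·GHGE(NUTR)` for increasing `x` while holding the host-group total
at its NUTR value, so decarbonization happens by substitution *within* the
meat group.  A relative piecewise-linear comparator model (same constraint
system, deviations `|q_i − q_i⁰| / q_i⁰`) and four sensitivity variants
(market-product nutrient profile, weight removal, ±50% GHGE coefficient of
the novel food, engine swap) complete the toolkit, together with an
independent solution audit (feasibility, split complementarity, objective
recomputation) and a synthetic survey generator for fully reproducible
experiments.

## Worked example

```python
from dietopt import (generate_survey, make_binding_spec, run_nutr,
                     run_ghge_ladder, category_breakdown)

survey = generate_survey(seed=7)                    # 79 categories, 13 groups
spec = make_binding_spec(survey, "protein", push=0.1)

nutr = run_nutr(survey, spec)
print(f"NUTR: {nutr.status}, objective {nutr.objective:.3f}, "
      f"GHGE {nutr.totals['ghge']:.2f} kg CO2e/day")

ladder = run_ghge_ladder(survey, spec, nutr, reductions=(0.2, 0.4))
for step in ladder:
    myco = step.diet.quantities["new_food"]
    print(f"{step.label}: GHGE {step.totals['ghge']:.2f}, "
          f"mycoprotein {myco:.1f} g/day")

bd = category_breakdown(ladder[-1], survey, "meat")
print(f"new-food share of meat-group mass: {bd.new_food_mass_share:.0%}")
```

prints

```
NUTR: optimal, objective 2.383, GHGE 25.23 kg CO2e/day
NUTR+GHGE-20%: GHGE 20.19, mycoprotein 51.7 g/day
NUTR+GHGE-40%: GHGE 15.14, mycoprotein 145.1 g/day
new-food share of meat-group mass: 66%
```

The NUTR diet raises protein 10% above baseline at minimal acceptability
cost (objective 2.383 standardized units²).  As the GHGE cap tightens from
20% to 40% below the NUTR level, the zero-baseline mycoprotein category is
drawn into the diet (51.7 → 145.1 g/day) because it decarbonizes the meat
group while the group's total mass is held constant — at −40% it already
supplies two thirds of meat-group mass.

The same pipeline is available from the shell:

```
dietopt fixtures generate --seed 7 --out fx/
dietopt optimize ladder --survey fx/survey.csv --groups fx/groups.csv \
    --constraints fx/constraints.csv --steps 5:60:5 --engine qp --out run/
dietopt report --survey fx/survey.csv --groups fx/groups.csv \
    --quantities run/quantities.csv --metric energy --out report/
```

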