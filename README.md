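# synpid

Partial information decomposition (PID) of intersectional identity
effects on income and health.

Social identities such as race and sex do not act on life outcomes as a
simple sum of separate effects: some of their influence is *redundant*
(either identity alone would tell you the same thing), some is *unique*
to one identity, and some is *synergistic* — visible only when the
identities are considered jointly. The synergistic component is the
statistical signature of intersectionality: a cost (or privilege)
specific to a conjunction of identities, irreducible to any of them
alone. `synpid` is a library for social scientists and epidemiologists
who want to measure these components in person-level survey data, and
for methodologists who want to see exactly where interaction-term
regression falls short of that goal.

## The decomposition

For two categorical predictors $X_1, X_2$ (e.g. race and sex) and an
outcome $Y$ (e.g. an income bracket), the joint mutual information
splits into four non-negative atoms:

$$I(X_1,X_2;Y) = \mathrm{Red}(X_1,X_2;Y) + \mathrm{Unq}(X_1;Y|X_2) + \mathrm{Unq}(X_2;Y|X_1) + \mathrm{Syn}(X_1,X_2;Y),$$

with $I(X_i;Y) = \mathrm{Red} + \mathrm{Unq}(X_i)$. Two redundancy
functions are implemented:

* **I_min** (Williams–Beer): the expected minimum, over sources, of the
  target-state-specific information
  $\sum_y P(y)\min_i I(X_i; Y{=}y)$, Möbius-inverted over the antichain
  lattice of source collections (4 nodes for two sources, 18 for
  three).
* **Optimization-based unique information**: $\mathrm{Unq}(X_1;Y|X_2) =
  \min_{Q\in\Delta} I_Q(X_1;Y\mid X_2)$ over all joint distributions
  $Q$ preserving both pairwise $(X_i, Y)$ marginals; redundancy and
  synergy follow algebraically. The convex program is solved by exact
  cyclic line search along the elementary circuits of the constraint
  polytope, which handles the boundary optima that defeat generic
  solvers.

Before decomposing survey data, the pipeline computes an *effective*
information: many balanced subsamples (equal counts from every joint
identity cell) are pooled into a mixture distribution whose identity
marginal is exactly uniform — an intervention that removes the survey's
unequal cell occupancy. The same whole-versus-parts logic is also run in
outcome units: the expected income under the *disjunction* of two
identities (the shared, redundant shift) versus the *conjunction* (the
further, synergistic shift).

## Worked example

No data download is needed: the package ships a seeded census-like
population generator with independently controllable unique, redundant
(latent common cause) and synergistic (conjunction penalty) components.

```python
from synpid import (GeneratorConfig, generate_population, CohortConfig,
                    balanced_resample_mixture, effective_pid, classify_atoms,
                    IdentityPredicate, intersection_decomposition)

table = generate_population(GeneratorConfig(n=60_000, seed=0))
eff = balanced_resample_mixture(table, ("race", "sex"), "income",
                                CohortConfig(n_resamples=200, seed=0))
shares = classify_atoms(effective_pid(eff)).fractions
print({k: round(v, 3) for k, v in shares.items()})

dec = intersection_decomposition(
    table, "income",
    IdentityPredicate("race", "Black"), IdentityPredicate("sex", "Female"),
    predictors=("race", "sex"), balanced=True)
print(f"baseline ${dec.baseline:,.0f} | or ${dec.disjunctive:,.0f} "
      f"| and ${dec.conjunctive:,.0f} | synergistic ${dec.synergistic_shift:+,.0f}")
```

prints

```
{'redundant': 0.387, 'unique': 0.192, 'synergistic': 0.421, 'exotic': 0.0}
baseline $36,318 | or $33,927 | and $27,971 | synergistic $-5,956
```

Of all the information race and sex jointly disclose about the income
bracket, 42% is synergistic and 39% redundant; in dollars, holding
either marginalized identity costs about $2,400 in expected income and
the conjunction costs a further $6,000 that neither identity explains
alone.

The `examples/` directory holds five short narrative scripts: the
canonical logic-gate decompositions, a ten-year synthetic cohort
analysis, the dollar-unit outcome decomposition, the
regression-versus-PID comparison, and the robustness sweeps. A thin
`synpid` command-line tool exposes the same pipeline for delimited
person-level files (`synpid pid`, `decade`, `local`, `dummy`,
`robustness`, `simulate`); `configs/cps_asec_column_map.json` maps the
canonical field names to CPS ASEC person-file variable names for use
with `--column-map` (ASEC's numeric category codes still need recoding
to the canonical labels).

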