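# gemcuts

Genetic minimal cut sets in genome-scale metabolic models (GEMs), computed
with open-source MILP solvers.

## The problem

A GEM describes an organism's metabolism as a stoichiometric matrix **S**
over reactions with flux bounds *lb* ≤ *v* ≤ *ub*, a biomass objective, and
gene–protein–reaction (GPR) rules — boolean AND/OR expressions stating which
gene combinations keep each reaction catalysed. A **Minimal Cut Set (MCS)**
is an irreducible set of reactions whose removal makes biomass production
infeasible; a **genetic MCS (gMCS)** is the same concept at the gene level:
an irreducible set of gene knockouts that blocks growth. gMCSs predict
synthetic lethality and drug-target combinations, and — mixed with nutrient
deprivations (**ngMCS**) — interventions on the growth environment.

Computing them is hard for two reasons: GPR rules couple genes to reactions
nonlinearly (one knockout can silence many reactions; several genes may each
be needed for one reaction), and the interesting solutions are the *minimal*
ones, enumerated exhaustively up to a length bound.

## The method

1. **GPR analysis.** Each rule is parsed into an AND/OR tree (stack-safe for
   rules with thousands of literals). For every reaction the *minimal
   disabling sets* — inclusion-minimal gene sets falsifying the rule — are
   enumerated exactly: by subset brute force for small rules, or through an
   *artificial reaction network* (one pseudo-metabolite per expression node,
   one input reaction per gene) where disabling sets become reaction-level
   cut sets of a sink flux, for arbitrarily complex rules.
2. **G matrix.** Rows are the distinct minimal disabling sets across all
   reactions; entry (i, j) = 1 iff knocking out row i's genes falsifies
   reaction j's rule. Strict-inclusion relations between rows are recorded.
3. **Dual MILP.** A knockout is lethal iff the LP
   max { c᷆ᵀv : S v = 0, lb ≤ v ≤ ub } restricted by the knockout stays below a
   growth threshold *b*; that infeasibility has a Farkas certificate in the
   dual variables (u, μ⁺, μ⁻ and a free multiplier η per knocked reaction).
   The MILP searches over knockouts with one binary selector per gene,
   activation variables per G row, and big-M links |η| ≤ M·z; minimizing the
   selector sum makes optimal supports minimal cut sets.
4. **Length-ordered enumeration.** For k = 1, 2, …, L the MILP is solved
   with the selector sum fixed to k; every incumbent is re-verified by an
   independent FBA call, checked for irreducibility, and excluded with a
   support cut. Layering guarantees no shorter solution is ever shadowed by
   a longer one.

The MILP layer is solver-agnostic; backends for HiGHS (via SciPy) and GLPK
(via swiglpk) are included, and results are required to agree across them.

## Worked example

A toy network whose one essential pathway carries the rule
`(g1 and g2) or (g1 and g3)` — g1 is shared between both isoforms:

```python
from gemcuts import FixtureSpec, make_fixture, calculate_gene_mcs, RunOptions, results_to_tsv, fba

fx = make_fixture(FixtureSpec("shared_gene"))
print("wild-type biomass:", fba(fx.model).objective_value)
res = calculate_gene_mcs(fx.model, RunOptions(max_length=3, solver="highs"))
print(results_to_tsv(res))
```

prints

```
wild-type biomass: 10.0
order	members	kind	verified
1	g1	gene	true
2	g2,g3	gene	true
```

Knocking out g1 alone kills both isoforms (a 1-gene cut set); otherwise g2
and g3 must both go. `{g1, g2}` is lethal too but not reported — it is not
minimal. The same pipeline runs from the shell:

```bash
gemcuts calculate-gene-mcs --model model.xml --max-length 3 --solver glpk --out run1
gemcuts calculate-mcs      --model model.xml --out run2        # reaction level
gemcuts gpr-stats          --model model.xml --out stats
```

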