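# Methods

## Model and assumptions

Metabolism is modelled at steady state: fluxes *v* satisfy S v = 0 with
bounds lb ≤ v ≤ ub, and "growth" means the biomass flux reaches a threshold
*b*. Gene dependence enters only through GPR rules: a reaction whose rule
evaluates false under a knockout gets both bounds set to 0; a reaction with
no rule (spontaneous, orphan) can never be disabled through genes. Exactly
one biomass reaction is assumed (models with multi-term objectives are
rejected at read time), and exchange reactions are recognised purely
structurally as columns with a single nonzero stoichiometric entry, with the
convention that positive flux exports the metabolite (uptake is negative
flux, controlled by the lower bound).

## The dual formulation

For a fixed knockout K the lethality question "is
max { c᷆ᵀv : S v = 0, lb ≤ v ≤ ub, v_j = 0 for knocked j } < b ?" is decided
in the dual: a certificate (u free per metabolite, μ⁺, μ⁻ ≥ 0 per reaction,
η free per knocked reaction) satisfying

    Sᵀu + μ⁺ − μ⁻ + η-terms = c            (one row per reaction)
    ubᵀμ⁺ − lbᵀμ⁻ ≤ b − ε                  (dual objective cap)

exists iff the post-knockout optimum is at most b − ε. The search over
knockouts uses:

- a **binary selector y_g** per knockable unit — gene, nutrient pseudo-gene
  `uptake:<exchange>`, or reaction, depending on the analysis level;
- a **continuous activation z_p ∈ [0, 1]** per G-matrix row, constrained
  z_p ≤ y_g for every gene g of the row, so a row can only switch on when
  *all* its genes are selected (z needs no integrality: its ceiling is a
  minimum over binaries);
- a **certificate variable η_{p,j} per nonzero G entry**, linked by
  −M z_p ≤ η_{p,j} ≤ M z_p.

Minimizing Σ y makes optimal supports minimal cut sets; fixing Σ y = k gives
the cardinality-k layer. Giving each *nonzero entry* its own η (rather than
one η per row) keeps the certificate space exactly the dual of "v_j = 0 for
every disabled reaction", which is what makes the formulation complete, and
selectors over *genes* (rather than over G rows) make the layer index equal
gene cardinality even when rows overlap in genes — rows {g1,g2} and {g1,g3}
jointly describe the 3-gene knockout {g1,g2,g3}, which a row-counting layer
would misplace. With gene selectors every subset row activates through its
own z, so the recorded strict-inclusion relations between rows are a data
product for inspection and testing rather than a MILP ingredient.

Completeness also relies on the G matrix containing *all* minimal disabling
sets up to the requested length: any reaction a k-gene knockout disables has
a minimal disabling subset of size ≤ k, which is then a row.

### Knockout encodings and a known one-sided approximation

Gene and reaction knockouts add v_j = 0, whose dual multiplier is free
(η two-sided). Nutrient deprivation closes only the uptake direction,
adding v_j ≥ 0, whose multiplier is sign-constrained — nutrient-row η are
capped at 0. One approximation is deliberate: the certificate encodes
v_j = 0 *on top of the original bounds*. For a reaction with a forced
positive lower bound (e.g. a maintenance flux) this is stricter than
zeroing the bounds, so the MILP can over-claim lethality there — never the
reverse. Every incumbent is therefore re-verified by an independent FBA
call before being reported; a failed incumbent is removed with a *no-good*
cut that bans exactly that assignment (a support cut would also ban genuine
larger cut sets containing it), and verified solutions are excluded with
support cuts, which correctly ban their never-minimal supersets.

## Enumeration

Layers run k = 1..max_length; within a layer the MILP is re-solved until
infeasible, carrying all cuts forward. Verification and an explicit
irreducibility check (all (k−1)-subsets re-tested by FBA; smaller subsets
are covered by induction over earlier layers) guard every result, and the
final list is sorted by (length, lexicographic members), so backend
nondeterminism cannot reach the output. A per-solve time limit returns the
partial list flagged incomplete rather than raising.

## Parameters

| parameter | default | meaning |
|---|---|---|
| b | 10⁻³ × wild-type optimum | biomass flux counted as growth (flux units); relative default is scale-free across unit conventions |
| ε | 10⁻⁶ | strictness margin of the dual cap (flux units) |
| M | 10³ | big-M on η; logged at build time because a too-small M silently loses solutions |
| flux tolerance | 10⁻⁷ | zero-flux threshold in FVA-based blocked-reaction pruning |
| integer tolerance | 10⁻⁹ | forwarded to backends; binaries are rounded at 0.5 and re-verified regardless |
| time limit | 300 s | per MILP solve |
| brute-force gene limit | 12 | rules with more distinct genes route through the artificial network |

Blocked-reaction pruning (two LPs per reaction) is sound for cut-set
analysis because knockouts only tighten bounds: a reaction blocked in the
wild type stays blocked in every knockout, so deleting it changes no
verdict.

## Solver backends

HiGHS (SciPy) and GLPK (swiglpk) are registered; neither offers native
indicator constraints, so the big-M translation is the single encoding in
practice. Constraint addition is a transparent rebuild: handles keep the
spec plus added rows and re-translate per solve, which at fixture scale
costs less than solver startup. Both backends are deterministic; the `seed`
parameter is accepted, recorded in solve metadata, and reserved for
backends that expose an RNG. Cross-backend identity of the verified sorted
result lists is asserted in the acceptance suite.

## Synthetic fixtures: what they do and do not show

The generator emits small growing networks (≤ 30 reactions, ≤ 25 genes)
covering the structural motifs that drive the method: chains (every gene
essential), isoenzyme branches (a planted n-gene cut set whose proper
subsets are viable — the 3-branch instance is the length-order test case),
enzyme complexes (AND rules), a shared-gene motif producing the
{g1} ⊊ {g1,g2}-type row relations, and randomized layered networks with
bounded-depth AND/OR rules and gene-reuse probability 0.2 so shared-gene
structure occurs frequently. Ground truth is established by exhaustive FBA
screening at generation time and re-verified on load. Random models draw
6–14 genes so the brute-force oracle over all triples stays fast; the
motif bank plus twenty-model default keeps the full acceptance run within
a few minutes on one CPU.

These fixtures exercise the logic of the method — GPR combinatorics, row
relations, layering, verification — not the scale of published GEMs: real
models add thousands of reactions, compartments, reversible loops, and
maintenance constraints with forced fluxes. Passing the bank therefore
demonstrates correctness of the algorithmics, not wall-clock performance on
genome-scale inputs. As one anchor against public data, the *E. coli* core
model bundled with cobrapy is read offline and its dimensions (95 reactions,
72 metabolites, 137 genes) and largest GPR rule (13 distinct genes) are
checked in the acceptance suite; larger published GEMs would require
downloads and are not asserted.

## Numerical and design choices

- GPR parsing is an iterative shunting-yard (explicit stacks); evaluation
  and serialization are likewise iterative, so pathological rule depth
  cannot overflow recursion.
- Same-operator children are flattened but duplicate gene occurrences are
  preserved in the tree; operator counts are reported as binary connectives
  of the flattened tree (an n-child node contributes n − 1), which is the
  convention used for published "number of disjunctions" statistics.
- Rules that cannot be falsified contribute no G rows; a model whose G
  matrix is empty at the requested length yields an empty result from the
  pipeline (the MILP constructor itself rejects zero-row matrices).
- Ties everywhere break lexicographically on sorted member identifiers.
- `infeasible` is an explicit status in FBA and MILP solves, never an
  exception; an infeasible post-knockout model counts as lethal.

## Limitations

- One biomass target; no coupling of product yields to growth, no
  regulatory constraints, no thermodynamics.
- The forced-lower-bound approximation above can cost extra MILP
  iterations (spurious incumbents are verified away), though never wrong
  output.
- GLPK's MIP struggles on large dual MILPs; at genome scale the HiGHS
  backend is the practical default, and commercial backends would slot in
  behind the same bridge.
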