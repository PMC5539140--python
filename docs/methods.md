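# Methods

## Model representation

A `StoichiometricModel` is an ordered list of metabolites and reactions.
Reactions carry signed stoichiometries (negative = consumed), flux bounds
in mmol·gDCW⁻¹·h⁻¹, an optional gene–protein–reaction (GPR) boolean rule,
and an objective coefficient; the designated objective reaction is the
biomass drain, whose flux is the specific growth rate μ (h⁻¹). Boundary
(exchange/demand/sink) reactions are exactly the single-metabolite
reactions; by convention negative flux is uptake and uptake limits are
encoded as negative lower bounds. Reactions without stated bounds are
capped at `default_bound` (1000 flux units), the conventional magnitude
that keeps all LPs bounded without affecting any optimum in the networks
considered.

GPR rules use `and`/`or` with parentheses, `and` binding tighter, matching
the convention of model exchange formats; `or` joins isozymes, `and`
complex subunits. Rules must be written with explicit operators — bare
adjacency is a parse error rather than an implicit `or`, so malformed
files fail loudly at validation (loaders degrade an unparseable rule to
"no association" with a warning, since GPR is not needed for FBA itself).

## FBA core

FBA maximizes (or minimizes) one flux subject to steady state `S v = 0`
and bounds, solved with HiGHS through `scipy.optimize.linprog`. Solver
feasibility tolerances are set to 1e-9; every externally visible
comparison uses 1e-6. Optimal solutions can be re-checked independently of
the solver (`check_solution`: row-wise `|S v|`, bound violations, and
objective consistency). Degenerate alternate optima are deliberately not
resolved — any optimal vertex is acceptable; every operation whose meaning
depends on a *specific* optimum goes through the lexicographic solve
below. Metabolite duals (shadow prices) are reported for the maximization
problem.

`maximize_product_at_growth` is the two-step lexicographic LP: maximize
biomass to get μ\*, then maximize the product flux subject to
`v_biomass ≥ f·μ*` (the growth floor is relaxed by the 1e-9 feasibility
tolerance to avoid empty interiors at f = 1). This implements the
*optimistic* convention: among growth-optimal flux states the one most
favorable to the product is credited.

Flux variability analysis solves the 2n min/max LPs at a fixed fraction of
the optimum and is the tool for exposing the alternate optima that the
optimistic convention exploits.

Chemostat validation replaces the bounds of each measured exchange by the
measured interval, maximizes biomass, and reports
`relative_error = |μ_pred − D| / D` — the steady-state identity μ = D
makes this the natural consistency score for a model against continuous
culture data.

## TAG augmentation

`augment_tag_synthesis` adds, per acyl-CoA species, the irreversible DGAT
esterification `DAG + acyl-CoA → TAG + CoA` with bounds
`[0, default_bound]`, and (optionally, when no TAG sink exists) a demand
`DM_tag: TAG → ∅`. One reaction per acyl-CoA species rather than a lumped
reaction keeps chain-length bookkeeping in the species; the 1:1:1:1
stoichiometry reflects the univalent esterification chemistry. The biomass
reaction is untouched by construction, and because the additions are
irreversible drains that may carry zero flux, the growth optimum is
provably unchanged. The four species roles must be distinct — otherwise
the stoichiometry dictionary would silently merge coefficients. Which
acyl-CoA chain lengths to wire in, and whether to add the demand, are
genuinely open modeling choices, so both are explicit arguments rather
than defaults guessed by the package. The edit is recorded as a
`ModelDelta`; reverting it restores a byte-identical serialization, which
is what makes the augmentation auditable.

Knockouts are applied at reaction level (both bounds set to zero). A
gene-level mode (`reactions_disabled_by_genes`) maps deleted genes through
the GPR rules to the disabled reaction set first.

## Knockout design

The bilevel program (outer: pick ≤ K deletions maximizing the target flux;
inner: the cell maximizes growth under the surviving reactions) is
reformulated to one MILP via LP strong duality: inner primal feasibility
(`S v = 0`, `y_j lb_j ≤ v_j ≤ y_j ub_j`), inner dual feasibility
(`Sᵀλ + μ − γ = c_inner`, `μ, γ ≥ 0`), and the strong-duality equality
between the inner primal and dual objectives. Dual×binary products are
linearized with per-reaction big-M constants `M_j = max(|lb_j|, |ub_j|,
default_bound)` — the smallest safe choice without bound tightening; dual
variables are capped at the same constant, which is far above any dual
magnitude arising in networks with O(1) stoichiometric coefficients and
O(10–1000) bounds. A viability floor `v_biomass ≥ 0.1·μ_wt` (fraction
configurable) excludes lethal designs. The joint optimization makes inner
ties optimistic by construction, so MILP scores and lexicographic-LP
scores coincide.

Enumeration solves the MILP, records the candidate, adds the integer cut
`Σ_{j∈deleted} y_j ≥ 1` (excluding that set and all supersets, so each
returned strategy is mechanistically distinct), and repeats until the
requested count, infeasibility, or an outer objective ≤ 1e-6. Every
candidate's objectives are re-simulated through the lexicographic LP and
flagged `verified`; the stored duality gap is recomputed from the MILP
point, not taken from the solver.

Ranking is outer objective descending, then fewer deletions, then
lexicographic sorted reaction ids. Pure lexicographic tuple comparison
would rank `{A, B}` ahead of `{B}` at equal value, which contradicts both
parsimony and the superset-exclusion cuts, so the cardinality tie-break
comes first. The MILP reproduces this order deterministically through a
tiny objective perturbation (1e-4 per kept reaction, minus a binary-weight
term of at most 5e-5): it is two orders of magnitude below the smallest
meaningful objective difference in any fixture (≥ 1/60 flux units), and
candidate objectives are re-simulated anyway, so the perturbation can
never leak into reported values.

The brute-force oracle enumerates every deletion set of size ≤ K (guarded
at 20 000 sets), scores each with the same lexicographic LP and viability
floor, drops sets with outer objective ≤ 1e-6 (mirroring the MILP's stop
rule), ranks identically, and prunes supersets of better-ranked sets. The
oracle-equivalence property — identical ranked lists from both engines on
every fixture — is the package's core correctness test, because the two
paths share no optimization code beyond the LP solver itself (and the LP
core is in turn cross-checked against COBRApy/GLPK on a fixture).

## Synthetic fixtures

The generators produce the study conditions for every test: small networks
with the structural features genome-scale TAG analysis depends on.

* **Linear chain** — uptake → conversion → biomass; the optimum equals the
  uptake bound, exactly.
* **Redox-coupled toy** (9 reactions, fixed) — glucose (≤ 10) yields
  precursor and NADH; NADH is re-oxidized by O₂-limited respiration
  (uptake ≤ 5), an ethanol sink (2 NADH per precursor) or a TAG branch
  (1 NADH per precursor). Hand-derived, unique ground truth: μ = 7.5 with
  fermentation at 5 and TAG at 0; best single knockout {FERM_E} with TAG
  flux 10.0 at growth 5.0. The derivations are recorded in the fixture's
  notes and frozen in the tests.
* **Randomized TAG toy** — an acetyl-CoA/CoA/NADH economy in which
  reductive fatty-acid synthesis (2 acetyl-CoA + 2 NADH → acyl-CoA + CoA)
  plus a β-oxidation-like recycle (acyl-CoA + CoA → 2 acetyl-CoA, NADH not
  returned) form a carbon-neutral redox sink that the growth optimum
  prefers; DGAT and the TAG demand are installed by the augmentation
  operation itself. Deleting the recycle forces surplus NADH through TAG,
  making it the rank-1 single knockout *by construction* — the synthetic
  analogue of blocking fatty-acid β-oxidation to trap storage lipid.
  Seeded byproduct branches (0.5 acetyl-CoA + NADH per unit, distinct
  secretion caps drawn without replacement from a 0.1-step grid) supply
  additional, never-tying competing sinks and the partners of the best
  K = 2 designs. Ground truth is computed at generation time by plain FBA
  and the brute-force oracle — never by the MILP — so the fixture is
  self-certifying and the MILP is always graded against an independent
  path.
* **Chemostat chain** — a yield-calibrated chain plus a condition clamping
  uptake; `make_chemostat_fixture(D, Y, uptake)` predicts μ = Y·uptake
  with exactly computable relative error against D. The signature takes
  the measured uptake as an explicit third argument (defaulting to D/Y,
  the perfectly consistent measurement) because the interesting validation
  case is precisely a measured uptake that does not match D.

What the fixtures do *not* emulate: genome-scale size (thousands of
reactions), elemental/charge balance, thermodynamic feasibility, kinetics,
or measurement noise (FBA inputs are bounds, not noisy observations).
Passing tests therefore demonstrate correctness of the algorithms and
their agreement with independent oracles under realistic network *motifs*,
not predictive accuracy on any particular genome-scale reconstruction;
applying the workflow to a real reconstruction additionally requires that
model's own curation quality.

## Serialization

`json-v1` mirrors the in-memory types one-to-one and is the canonical
fixture format; output ordering follows model order and numeric values are
written verbatim, so serialization is deterministic to the byte. The SBML
dialect targets Level 3 Version 1 with the FBC v2 package: flux bounds as
constant parameters, a maximization objective with flux-objective entries,
gene products with labels carrying the raw gene ids, and COBRA-style
`M_`/`R_`/`G_` SId prefixes (added on write, stripped on read). Subsystems
ride in reaction notes; the designated objective reaction id is stored on
the objective so that models whose objective coefficient set is ambiguous
still round-trip. Model equality compares floats at relative tolerance
1e-12 and GPR rules by canonical form, making the round-trip law
(`read(write(m)) == m`, including a cross-dialect trip) testable without
bit-level float fragility.

## Problem sizes and determinism

Default verification scales: oracle-equivalence runs 20 seeded randomized
fixtures (10 knockable reactions each) at K ∈ {1, 2}; the enumeration-depth
check uses the 10-branch fixture (16 knockable, ~136 deletion sets at
K = 2). These sizes give dense coverage of the combinatorics while keeping
a full verification run in tens of seconds. All randomness flows through
explicit integer seeds; identical seeds give byte-identical serialized
fixtures, and every CLI command logs a hash of its effective
configuration.

## Known limitations

* The MILP relies on finite bounds; models with unbounded reactions must
  be capped (the formulation refuses non-finite bounds explicitly).
* Enumeration stops at outer objective ≤ 1e-6; strategies that merely tie
  the wild type are not reported, and if the wild type itself is optimal
  the candidate list is empty rather than padded.
* Gene-sharing between reactions is reported (per-candidate gene lists)
  but not enforced as a coupling constraint in the MILP — deletions are
  reaction-level, as in reaction-level candidate tables.
* Big-M linearization is exact only while true inner dual magnitudes stay
  below the cap; grossly rescaled models (coefficients ≫ 10³) would need a
  larger `big_m`, which the configuration exposes.
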