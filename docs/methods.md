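# Methods

## Balanced-growth community models

A community model is built from single-species stoichiometric models by
(i) suffixing every internal metabolite and reaction with the species id
(collision-proof and reversible), (ii) merging the metabolites named in the
exchange policy into a shared pool compartment (`<met>_pool`), (iii) adding
a biomass compound BM_i produced 1:1 by each species' biomass reaction, and
(iv) adding the community growth reaction Σ F_i·BM_i → BM_C. BM_C is a
boundary metabolite and accumulates freely; the BM_i are balanced, which is
what enforces r_BMi = F_i·µ_C (balanced growth) as a linear identity rather
than an extra constraint.

Exchange policy per pool metabolite:

* **closed** — no environment exchange; the metabolite must be fully
  consumed within the community. This encodes the syntrophic constraint
  that H₂ and formate cannot accumulate (their production is only
  thermodynamically feasible at low concentrations).
* **medium** — an environment supply reaction (unbounded; the species-level
  uptake caps, not medium availability, limit specific rates).
* **accumulating** — an environment export reaction (acetate, CO₂, methane
  analogs).

Every species transport touching a pool metabolite is split into two
irreversible halves (uptake ≥ 0, export ≥ 0). This makes substrate uptake
fluxes nonnegative by construction, so the yield-weighted secondary
objective is sign-safe, and lets the model track uptake and export of the
same metabolite separately.

**F-scaling.** All community fluxes are per gDW of community. Only bounds
declared as species-specific capacities — rate caps and the ATP-maintenance
lower bound — are multiplied by F_i on instantiation; generic "unbounded"
bounds (±1000 or ∞) are left alone, since they encode the absence of a
constraint, not a capacity. Species with F_i = 0 have all reactions closed.

## Hierarchical optimization and OptDeg

At a fixed composition the primary LP maximizes µ_C. The secondary LP fixes
µ_C and minimizes z = Σ_(i,s) r_{i,s}·Y^max_{i,s}(µ_C), one summand per
(species, substrate) pair the species is configured to use. The weight
Y^max_{i,s}(µ_C) is computed in the *single-species* model: all other
configured substrates blocked, ATP maintenance active, growth fixed to µ_C,
substrate uptake minimized; Y = µ_C / min-uptake. If the substrate cannot
support µ_C, the yield is marked unavailable and its summand omitted. z is
the smallest total biomass synthesis rate consistent with the observed
uptakes if every species operated at maximum yield, so OptDeg = µ_C/z ≤ 1
for single-substrate species, with equality exactly at yield-optimal
operation; multi-substrate synergies are the only way above 1.

Yield tables are recomputed whenever µ_C changes (maintenance makes yields
growth-dependent) and cached keyed by (species, substrate, µ_C rounded to
1e-9). OptDeg values within 1e-4 of 1 are reported as exactly 1; that
tolerance is grid/LP noise below reporting precision.

Degenerate optima: FBA returns one optimal vertex, unspecified which. No
downstream quantity is read off a single FBA solution; extremal product
rates and yields are always re-derived by dedicated LPs.

## Scans and product extrema

Compositions are enumerated on a step lattice of the simplex (default step
0.01: 101 points for two species, 5151 for three). Each cell is evaluated
either at its maximum community growth rate or at user-fixed rates;
infeasible cells are flagged and keep NaN metrics rather than being
dropped, because "no solution exists" regions are themselves results. Scan
rows are independent, so shuffling the grid cannot change any row.

The minimum product rate at (F, µ_C) is a plain LP over the feasible set
with µ_C fixed — feasibility-only, not restricted to z-optimal flux
distributions. This choice (the two are not equivalent) is what produces
the observed anti-correlation between OptDeg and minimal product formation:
suboptimal-yield compositions are *forced* to over-produce. A z-constrained
variant can be obtained by fixing the secondary objective value first if
needed.

The minimum product *yield* (product export / reference-substrate uptake)
is a linear-fractional program solved exactly by the Charnes–Cooper
transformation (variables y = t·r, t ≥ 0, denominator normalized to 1;
finite bounds become lb·t ≤ y ≤ ub·t). Zero-uptake denominators are
reported as undefined. A bisection solver over plain feasibility LPs is
kept as an independent cross-check.

When no lattice point reaches OptDeg = 1 (knife-edged toy systems at fixed
µ_C), the predicted operation point is the maximum-OptDeg lattice cell; all
ties within 1e-6 are reported, since competition scenarios legitimately
produce segments or regions of equivalent optima rather than single points.

## Physiological estimators

* **Pirt fit**: ordinary least squares of q_S = µ/Y_true + m_S. Negative
  intercepts are clipped to zero with a warning. Weighted variants are out
  of scope.
* **ATP maintenance**: ATPmaint = m_S × Y^max_ATP, with the maximum ATP
  yield computed as a fractional LP (ATP-hydrolysis flux per substrate
  uptake) at zero growth. Species-level coefficients are unweighted means
  over the per-substrate estimates; for the three reference organisms the
  per-substrate literature values give 4.3, 0.9, and 2.5 mmol ATP/gDW/h.
* **Cell geometry**: sphere V = πd³/6; rod = cylinder with hemispherical
  caps, total length L including caps (cylinder section L − d). For a rod
  of L = 2 µm, d = 0.5 µm this gives 0.36 µm³; the literature value of
  0.3 µm³ sometimes quoted for these dimensions is not reproduced by any
  standard capped-cylinder convention, so the formula used here is stated
  explicitly. Dry weight m = 435·V^0.85 (fg, V in µm³). Cell-count ratios
  convert to biomass fractions via F_i ∝ count_i × dry weight_i.

## The synthetic community generator

The toy generator builds a producer→consumer chain with explicit ATP:
substrate catabolism yields the cross-fed metabolite (x per mmol) plus
1 ATP, biomass costs 1/Y₀ ATP per gram, and maintenance is an ATP-hydrolysis
reaction with lower bound m — so F-scaling of maintenance is exercised
end-to-end, and the apparent yield obeys Y(µ) = µY₀/(µ + mY₀) in closed
form. Default parameters (Y₀ = 0.05/0.02 gDW/mmol, caps 10/15 mmol/gDW/h,
x = 1) give the analytically derived optimum F_A* = 5/7, µ_C* = 0.30 h⁻¹.
Random specs draw log-uniformly over one decade around these defaults with
a fixed seed.

The "waste" flag lifts the upper bound on ATP hydrolysis, letting a species
run a futile cycle; with 1 ATP per substrate this is stoichiometrically
identical to a dedicated substrate→product waste pathway and is what makes
off-balance compositions feasible (OptDeg < 1). Without waste the exact ATP
balance pins the feasible composition uniquely at each growth rate, which
the exactness tests exploit.

What the toys do *not* emulate: redundant internal pathways with different
ATP stoichiometries, co-substrate coupling (CO₂ alongside H₂),
multi-substrate species whose combined yield beats the single-substrate
optima (the only route to OptDeg > 1), and realistic network degeneracy.
Tests passing on the toys therefore validate the optimization machinery and
the balanced-growth bookkeeping, not the biology of any particular genome-
scale reconstruction; with real SBML species models, predictions inherit
those models' assumptions.

For multi-substrate organisms growing on H₂ + CO₂, the substrate summand in
the secondary objective should reference the electron-carrying species
(H₂), with the per-CO₂ yield convention reserved for reporting; CO₂ as a
co-substrate never contributes its own summand.

## Numerical choices and problem sizes

All LPs use HiGHS (scipy.optimize.linprog); solution feasibility is
asserted at 1e-9 on bounds and 1e-6 on N·r. Optimality comparisons are at
1e-6 relative, matching 3-significant-digit reporting. SBML reading accepts
fbc bounds and kinetic-law LOWER_BOUND/UPPER_BOUND parameters; missing
bounds default to the COBRA convention (±1000 reversible, 0–1000
irreversible) with one warning per reaction. Boundary metabolites are
recognized by boundaryCondition or membership in an environment
compartment.

The test and acceptance runs use two-species scans on the 0.01 lattice
(101 points), three-species scans at step 0.1 (66 points), and
property sweeps of 100 random toy communities probed at sampled
compositions with a 0.05-step scan — sizes chosen so the full analysis
remains an interactive, sub-minute computation while still covering every
code path at the default lattice resolution.

## Known limitations

No thermodynamic/loopless constraints, no gene–protein–reaction rules, no
dynamic FBA, no adaptive mesh refinement of the simplex, no plotting. The
composition prediction assumes a stable, quasi-continuous environment
(balanced growth); batch dynamics and lag phenomena are outside the model
class.
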