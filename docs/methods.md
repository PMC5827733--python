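# Methods

This document states the model formulation, parameter choices, numerical
methods, the scope of the fixture generator and the known limitations of
`dynamoma`.

## 1. Problem structure

The workflow has three phases:

1. **Network preparation.** An organ metabolic network is extended with
   *xenobiotic reactions*: cofactor-only templates (the drug and its
   metabolites are balanced by the PK scale, so only endogenous cofactor
   turnover appears in the stoichiometry). A physiological scenario is
   imposed through a metabolite-utilization table on the exchange
   reactions, and an expression-constrained *reference flux distribution*
   v_ref is computed.
2. **PK simulation.** A PBPK model (or any external platform exporting a
   rate table) provides the time-resolved rates of the xenobiotic
   reactions in the organ, in µmol·organ⁻¹·min⁻¹.
3. **Dynamic coupling + metrics.** One MOMA quadratic program per
   timepoint yields a flux trajectory; integrated deviations from v_ref
   quantify the metabolic response.

## 2. Reference state

* **Expression scores.** Gene intensities are normalized to a maximum of
  1 and mapped to reactions through GPR rules (AND → min, OR → max;
  genes missing from the profile drop out of their min/max). Reactions
  without a GPR receive no score.
* **Thresholds.** Reactions scoring at or above the 75th percentile of
  the non-zero score distribution form the *active* set; at or below the
  25th percentile (plus all zero-scored reactions), the *inactive* set.
  Percentiles use linear interpolation.
* **Fasted-state bounds.** Exchange reactions listed in the utilization
  table get the given (lb, ub); all other exchanges are closed. Bounds
  follow the secretion-positive convention.
* **iMAT.** A MILP maximizes the number of satisfied activity
  indicators: binary y⁺ (and y⁻ for reversible reactions) force
  |v| ≥ ε through active reactions, binary z forces |v| ≤ ε through
  inactive ones, subject to S·v = 0, bounds, and a biomass minimum
  (default 1e-4 µmol·organ⁻¹·min⁻¹). A small index-weighted penalty on
  the binaries (total < 0.5, below the integrality gap) makes the chosen
  optimum deterministic.
* **Pruning.** A reaction is removed from the context network only when
  it is idle in the MILP solution (|v| < ε) *and* flux variability
  analysis proves it can never reach |v| ≥ ε. Xenobiotic reactions are
  exempt: they ship with closed bounds ([0, 0]) until the coupling loop
  pins them, so FVA necessarily reports them blocked.
* **Flux-sum minimization.** With exchange fluxes fixed to their iMAT
  values, flux directions of all reactions carrying |v| ≥ ε held, and
  the biomass minimum kept, the L1 norm of the non-exchange fluxes is
  minimized (LP with auxiliary variables). The result is v_ref.
  Important: the direction-fixing bounds are local to this LP — the
  stored reference network keeps the fasted-state bounds, because the
  coupling loop leaves endogenous reactions unconstrained.

Defaults are study conditions, not tuning knobs: activity threshold
ε = 1e-5 µmol·organ⁻¹·min⁻¹, biomass minimum 1e-4, 72 h horizon
(4320 min), 1-min coupling step.

## 3. Xenobiotic templates

Phase I (oxidation, NADPH-dependent oxidation, hydrolysis, reduction),
phase II (glutathione/sulfo/acetyl/sugar/methyl/amino-acid conjugation)
and phase III (metabolite integration, ATP-dependent and symport/antiport
transport) templates define cofactor roles, signed stoichiometry and
allowed subcellular locations (e.g. NAT-type acetylation is cytosolic,
amino-acid conjugation mitochondrial). Instantiated reactions carry
`role="xenobiotic"`, cluster `"xenobiotic metabolism"` and closed bounds,
so extension never changes the feasible space until coupling.

The isoniazid preset wires eight reactions — NAT2 acetylation of
isoniazid/hydrazine/acetylhydrazine, amidase hydrolysis of
isoniazid/acetylisoniazid, CYP2E1 oxidation of acetylhydrazine, glycine
conjugation of isonicotinic acid, NOS-mediated hydrazine oxidation — to
auto-detected cofactor metabolites. The stoichiometry table is shipped as
a JSON resource so a curated table can be substituted.

## 4. The toy PBPK simulator

The driver only needs hepatic xenobiotic reaction rates plus a closed
mass balance, so the simulator is deliberately small: gut → liver (portal
absorption, ka = 0.05 min⁻¹), flow-limited plasma↔liver exchange
(Q = 1.5 L·min⁻¹, V_plasma = 40 L, V_liver = 1.7 L), Michaelis–Menten
hepatic reactions matching the preset reaction ids, first-order renal
clearances, and one lumped extrahepatic (plasma) hydrolysis of the parent
drug (0.05 L·min⁻¹) standing in for all non-hepatic metabolism. Fast and
slow NAT2 acetylator phenotypes differ *only* in a Vmax scale applied to
the NAT2 reactions (1.0 vs 0.083).

Mass balance is checked on moieties, not molecules: hydrolysis splits one
isoniazid into isonicotinic acid + hydrazine, but every species carries
exactly one isonicotinyl and/or one hydrazine moiety and the cascade
conserves both (oxidation sinks hold the oxidized hydrazine moiety).
Both balances close to ~1e-15 relative error (LSODA, atol 1e-10).

Calibration targets are qualitative dose-fraction patterns, not exact
literature values: fast acetylators metabolize 55–75 % of the dose
hepatically, slow 10–25 %; slow acetylators excrete 45–60 % unchanged;
urinary isonicotinyl recovery is 100 %.

## 5. Dynamic MOMA

At each timepoint t the QP

```
min ‖v − v_ref‖²  s.t.  S·v = 0,  lb ≤ v ≤ ub,  v_xen = v_PBPK(t)
```

is solved. Every timepoint references the *same* v_ref (metabolic
homeostasis pulls toward the pre-dose state); a chained mode referencing
the previous column exists but is opt-in. The objective is strictly
convex, so columns are unique — the trajectory is deterministic.

**Solver.** A dense primal active-set method: the equality-constrained
subproblem is solved through its KKT normal equations
((S_f S_fᵀ)·µ = d − S_f·r_f, least squares), blocking bounds are added on
the line search and bounds with wrong-signed multipliers are released.
Because the pinned set is the same at every timepoint, the pseudo-inverse
of S_f S_fᵀ is factorized once per run; a timepoint falls back to the
full active-set solve only when a network bound becomes active. The
fallback path and the fast path agree to ≤1e-7 (tested).

**Infeasibility.** If a pinned rate vector admits no steady state, the
run aborts with the timepoint, a partial flux matrix, and the conflicting
metabolite balances (from a slack LP). With `relax=True` the rate vector
is instead scaled by the largest feasible α ∈ [0, 1] (bisection) and the
α log is attached to the results.

## 6. Perturbation metrics

With Δv_it = v_it − v_ref,i and left-rectangle weights w (consistent with
the piecewise-constant QP trajectory; trapezoid is available):

* P_rxn,i = ∫|Δv_i| dt; significance: P_rxn > ε·t (strict).
* P_PBPK = ∫ Σ_xen |Δv| dt — the driver perturbation.
* P_MP = Σ P_rxn over a cluster's significant members.
* AT_MP(t) = cumulative per-step cluster perturbation / P_MP —
  non-decreasing, ends at exactly 1; empty for unperturbed clusters.
* PS = P_MP / P_PBPK. PS = 0 means independence from the perturbation;
  a zero driver with nonzero P_MP raises (upstream inconsistency).
* Altered fraction per timepoint: share of reactions with |Δv| > ε.
* Exometabolome pools: signed and absolute ∫Δv dt per exchange; pools
  changing by more than 50 µmol are flagged. Positive signed change =
  extracellular gain (secretion-positive convention); an
  uptake-positive column is also emitted.

## 7. Fixture generator scope

`generate_toy_fixture` emulates all four input kinds at desk scale:
a 23-metabolite / 26-reaction liver-like network (lactate-fed
gluconeogenesis, PPP-style NADPH supply, acetyl-CoA and glutathione
synthesis, biomass drain), expression with a high-scored main route and
low-scored alternative/dead-end branches, a fasted utilization table, and
pathway-cluster labels. It deliberately contains a stoichiometrically
disconnected two-reaction subnetwork with its own exchanges and cluster
("isolated pathway") — the negative control no xenobiotic perturbation
can reach. The "medium" size adds seed-randomized amino-acid degradation
chains; the small network is fixed and fully deterministic.

## 8. Numerical choices

* LP / FVA / L1 / feasibility: `scipy.optimize.linprog` (HiGHS).
* iMAT MILP: `scipy.optimize.milp` (HiGHS), deterministic tie-break.
* MOMA QP: custom dense active-set solver (no QP library is assumed);
  verified against the analytic KKT solution, nullspace projection, and
  SLSQP cross-checks in the test suite.
* ODEs: LSODA with rtol 1e-9 / atol 1e-10, integrated piecewise between
  dosing events (boluses enter the gut state discontinuously).
* Rate-table resampling averages within coarse intervals, which
  preserves left-rectangle integrals exactly.

## 9. Limitations

* The PBPK simulator is a minimal driver (single well-stirred liver,
  lumped extrahepatic clearance, no enterohepatic recirculation, no
  protein binding); for real studies, import rate tables from a full
  PBPK platform instead.
* The xenobiotic templates carry cofactor stoichiometry only; shared
  enzyme capacity between drug and endogenous substrates is not modeled.
* MOMA assumes the organ returns toward a fixed reference; slow
  adaptation (enzyme regulation over days) is out of scope.
* Metrics assume a uniform time grid.
* The dense QP targets networks up to a few thousand reactions; very
  large reconstructions would need sparse factorizations.
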