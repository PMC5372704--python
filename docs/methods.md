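# Methods

## The constraint-based model

All analyses assume pseudo-steady state: internal metabolite
concentrations are constant, so the flux vector `v` satisfies `S·v = 0`
with `S` the stoichiometric matrix (rows = metabolites, columns =
reactions; the conventional orientation).  Exchange reactions are
written `1 M_ext →`, so uptake is negative flux and secretion positive.
Growth is the flux through a biomass reaction, maximized by linear
programming.  The LP is solved with the HiGHS dual simplex
(primal/dual feasibility tolerances 10⁻⁹) rather than an interior-point
method so that the returned solution is a vertex with well-defined
reduced costs.  The reduced cost reported for reaction *i* is
dμ/db — the marginal change of the objective per unit shift of the
binding bound value b.  Growth below 10⁻⁶ h⁻¹ is treated as zero
everywhere.

Reduced costs of degenerate optima are basis-dependent; the sensitivity
module can flag exchanges whose flux is non-unique at the optimum
(FVA span at fixed μ*) so that reported values are read with care.

## Screens and validation

Two growth criteria are used deliberately:

* omission screens call *no growth* when the perturbed optimum falls
  below 20% of the wild type — a relative criterion, because a wild
  type exists;
* sole-carbon-source screens call *growth* when μ exceeds the absolute
  10⁻⁶ h⁻¹ floor, because no wild type is defined there.

Deletions knock a reaction out by pinning both bounds to zero (and a
gene knockout disables every reaction whose GPR evaluates false);
essential means growth reduced by at least 80%.  Media may flag
components (water, phosphate) as *always open*; such components are
exempt from omission screening — closing them would only probe the
bookkeeping of the proton/phosphate economy, not nutrition.

The packaged validation table lists 62 nutrients (18 carbon sources,
20 amino acids, 6 nucleotides, 7 minerals, 11 vitamins) with observed
and predicted growth calls transcribed from published experimental
validation work on the organism.  Tallying it gives TP=31, TN=27, FP=1,
FN=3 and the six metrics printed in `examples/02_nutrient_screens.py`.

## Variability, blocked reactions, dead ends

"Unconstrained" means every exchange opened to (−1000, 1000) — 1000
being the conventional unbounded proxy — with no objective floor.  A
reaction is blocked when its FVA minimum and maximum are both below
10⁻⁹ in magnitude under those conditions; the tolerance sits at solver
scale, not at the 10⁻⁶ growth scale, so tiny feasible loops are not
misclassified.  A maintenance reaction whose bounds are still (0, 0)
is reported blocked, which is literally true; set its value first if
that is not intended.

Dead ends are found two ways.  The structural scan expands reversible
reactions into both directions and flags metabolites that only ever
appear as product or only as substrate.  The functional probe attaches
a temporary drain `M →` (maximized: producibility) and a temporary
source `→ M` (maximized: consumability); a metabolite missing *either*
capability is a dead end.  The either/or reading is what makes the two
scans consistent — a structurally orphaned product is producible but
not consumable, and every reaction touching such a metabolite is
necessarily blocked — and matches the purpose of the scan, which is to
explain blocked reactions.  FVA ranges are reported raw; no
thermodynamic loop correction is applied.

## Maintenance (NGAM) fitting

The maintenance reaction is the literal ATP hydrolysis
`ATP + H₂O → ADP + Pi + H⁺` with bounds (0, 0) until a value is set.
Fitting fixes the measured exchange rates as equality bounds
(lo = hi = signed rate), sweeps the maintenance flux over
[0, 5] mmol gDW⁻¹ h⁻¹ at 0.1 resolution, maximizes growth at each grid
value, and refines at 0.01 around the coarse argmin.  The error metric
is the relative absolute growth error |μ_pred − μ_obs| / μ_obs.
Grid points where the constrained model is infeasible (expected at high
maintenance, where the fixed substrate influx cannot cover the ATP
demand) are recorded and excluded; ties resolve to the smallest
maintenance value.

## ATP accounting

The network method sums the substrate-level phosphorylation fluxes
(acetate kinase + pyruvate kinase + phosphoglycerate kinase) and
subtracts the kinase investments (hexokinase, fructokinase); the
classical fermentation shortcut adds the D-lactate and acetate export
fluxes.  The shortcut systematically overstates ATP whenever lactate or
acetate arise from routes that bypass substrate-level phosphorylation
(malate, citrate, amino-acid catabolism) — the mean relative shortfall
over condition pairs quantifies that bias.  The synthase fraction is
ATP-synthase flux over total production (kinase sum + synthase).

## Hit-and-run sampling

Directions are drawn uniformly on the unit sphere of the null space of
`S` restricted to non-fixed fluxes; the chord through the current point
is intersected exactly with the bounds and the next point is uniform on
the chord.  The warm-up start is the centroid of FVA extreme-point
solutions (feasible by convexity).  Thinning keeps every *k*-th point.
Defaults follow common practice at scale (100,000 points, 500 steps);
the test suite and examples use desk-scale settings (hundreds to
thousands of points, 10–50 steps) so the whole suite runs in minutes on
one core — convergence is checked only at the box-calibration level the
tests state, not asserted beyond it.  Rankings of sample flux ranges
round to 9 decimals before sorting so that float jitter cannot reorder
exact ties, which then fall back to reaction-id order.

## The synthetic toy network

The generator emulates the physiology that matters for a wine LAB:

* hexoses enter by permease + kinase and ferment through the oxidative
  6-phosphogluconate branch and phosphoketolase to glyceraldehyde-3-P
  and acetyl-P, yielding D-lactate, acetate or ethanol, and CO₂;
* fructose → mannitol and fructose-6-P → erythritol branches regenerate
  the NAD⁺ that the heterolactic route consumes — with both valves
  removed and no oxygen, fructose-only growth drops strictly, because
  redox balance must fall back on the ATP-costly ethanol branch;
* malolactic fermentation: malate import, proton-consuming
  decarboxylation to L-lactate, lactic-acid efflux that carries a
  proton out.  Proton export happens only through lactate and
  CO₂/carbonic-acid efflux; the resulting gradient drives an ATP
  synthase translocating a configurable number of protons per ATP
  (default 3 — the stoichiometry is uncertain in the literature, so
  conclusions should be checked over 2–4);
* a lumped citrate lyase to oxaloacetate, with malate dehydrogenase and
  oxaloacetate decarboxylase closing the loop to pyruvate;
* essential amino acids (uptake only, with an ATP-yielding oxidative
  catabolism of the arginine-deiminase kind) and synthesizable amino
  acids (a transamination shunt from pyruvate) — omitting an essential
  amino acid stops growth, omitting a synthesizable one does not;
* slack routes a heterofermenter plausibly owns: water-forming NADH
  oxidase with microaerophilic O₂ uptake, acetoin overflow from
  pyruvate, spontaneous acyl-phosphatase, a mannitol-1-P route, and
  cofactor salvage (phosphate exchange, nicotinamide- and
  adenylate-precursor uptake with small biomass demands).  These keep
  the flux polytope full-dimensional around the optimum — without them
  a toy-sized network is so rigid that equality-fixing measured rates
  with any noise yields an empty polytope — and they unblock the
  cofactor pools in the dead-end probes, as cofactor biosynthesis does
  in genome-scale reconstructions;
* planted orphan metabolites (products with no consumer) as recorded
  structural dead ends.

The biomass reaction demands amino acids (0.05 per essential, 0.5 per
synthesizable amino acid per unit growth), 10 mmol gDW⁻¹ ATP (a
growth-associated-maintenance surrogate), water, and small phosphate /
adenylate / NAD increments; it deliberately contains no central-carbon
intermediate.  That composition is what makes maintenance identifiable
in the closed loop: with measured rates fixed, the ATP budget — not a
pinned carbon precursor — limits growth, so predicted growth falls
strictly as maintenance rises and the error curve has a unique V-shaped
minimum.  Literature-derived biomass coefficients of the real organism
are deliberately **not** reproduced.

Default uptake bounds are a few mmol gDW⁻¹ h⁻¹ (glucose and fructose
1.0, malate 1.0, citrate and oxygen 0.5, amino acids 0.5–2.0), chosen
once to sit on the scale of measured exchange rates for slow-growing
wine bacteria; they put the optimum near 0.6 h⁻¹ and keep the whole
0–5 maintenance grid meaningful.

Synthetic rate datasets fix the maintenance flux at a known value,
solve, and record the measured species (sugars, malate, citrate,
essential amino acids; D-/L-lactate, acetate, ethanol, mannitol,
erythritol).  Noise is applied multiplicatively to the substrate rates
and the product rates are then re-extracted from a re-solve under the
noised substrates, keeping the dataset mass-consistent; independent
jitter on all thirteen rates of an 80-reaction network almost surely
violates its stoichiometric couplings and produces an empty polytope,
which no fitting procedure could rescue.  The observed growth rate is
the noiseless optimum.

### What the toy network does and does not show

Passing the closed-loop tests shows the *procedures* are correct:
screens recover planted essentialities exactly, the maintenance sweep
recovers its generating value to grid resolution (and within three
coarse steps under 2% rate noise in ≥ 90% of replicates), dead-end
scans recover planted orphans, samples satisfy the constraints.  It
does not show that real measured rates are noise-free or
mass-consistent, that a real reconstruction's biomass composition is
right, or that condition-specific published flux values are
reproducible — those depend on unpublished experimental rates and on a
660-reaction reconstruction distributed separately (the loader accepts
it; see `tests/test_acceptance.py::test_published_reconstruction_statistics`).

## Numerical choices

* LP tolerances 10⁻⁹; blocked tolerance 10⁻⁹; growth epsilon 10⁻⁶ h⁻¹;
  sampler feasibility tolerance 10⁻⁶.
* TSV model serialization uses `repr(float)` so write→read→write is
  byte-identical.
* Bounds omitted by a Level 2 SBML file default from the `reversible`
  flag — reversible (−1000, 1000), irreversible (0, 1000) — with a
  logged warning; a Level 3 fbc file missing bounds is rejected, since
  there the omission indicates a malformed file rather than a dialect.
* Across-condition sensitivity summaries report mean ± sample standard
  deviation (n−1); the spread definition is stated because reports in
  the field often leave it ambiguous.
* The aggregate across always-open medium components uses the most
  permissive bound when a medium lists an exchange twice.

## Known limitations

Single-compartment cytosol + exterior only; no thermodynamic loop
removal, so futile cycles (cofactor salvage, isomer interconversion)
legitimately dominate sampled flux ranges; no parallel sampling chains
or formal convergence diagnostics; no growth-associated-maintenance
estimation from multi-dilution data; double deletions and dynamic FBA
are out of scope.
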