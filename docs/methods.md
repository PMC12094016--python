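# Methods

## Model representation and units

Models are `cobra.Model` objects; `pyroflux.model` adds the I/O dialects
(SBML L3/FBC via cobrapy, plus a minimal documented YAML schema), carbon
validation and editing helpers. Flux sign convention: positive = forward as
written; reversibility is expressed only through bounds, which are
authoritative. Bounds absent from a YAML file default to (0, 1000), or
(−1000, 1000) for entries flagged `reversible`; 1000 model units is larger
than any calibrated bound used here.

All analyses default to a **batch-yield flux basis**: one flux unit is one
mM of the compound over the whole batch, so model outputs compare directly
to measured endpoint concentrations. A specific-rate basis (divide by
culture duration) is available through `CalibrationPolicy`; the gram-dry-
weight normalisation is then the model's own affair.

Validation is **carbon-only** by design: each metabolite carries a carbon
count through its formula (carbon-only pseudo-formulas such as `C23` for
acetyl-CoA are sufficient), and every non-exchange reaction must have zero
net carbon. Protons and elemental balance beyond carbon are not audited —
the downstream accounting is per carbon atom, and tracking protons in a
lumped desk-scale network would suggest a precision the model does not
have.

Feasibility tolerance is 10⁻⁶ model units everywhere (steady-state
residual and bound violation), a standard double-precision LP tolerance.

## The 1-propanol pathway

`build_propanol_pathway` emits twelve reactions: E1–E6 of the 3-HP/4-HB
route (acetyl-CoA → propionyl-CoA, fixing one HCO₃⁻), the ADP-forming
acetyl-CoA synthetase step to propionate (regenerating ATP), the
AOR/AdhA couple to 1-propanol, passive export, carbonic anhydrase and
inorganic pyrophosphatase. Design choices:

* **Cofactors are a policy, not a constant.** The reductive steps (E2, E3,
  E6, AdhA) default to NADPH — the anabolic couple this host family runs
  on, and the couple whose perturbation experiment the package implements —
  but each can be switched to NADH independently; AOR is always
  ferredoxin-driven. Carbon balance is carrier-independent.
* **E4 is AMP-forming** (CoA ligase releasing PPi) and PPase is bundled:
  this is the only stoichiometry under which pyrophosphate turnover is
  coupled to the route, which is exactly why PPase shows up in bottleneck
  scans.
* The composed route from acetyl-CoA costs 2 ATP-equivalents (1 ATP → AMP
  at E4 counts double; ACS gives one back) and 4 NADPH + 1 Fd_red per
  1-propanol, and the E1 carboxylation makes the pyruvate → 1-propanol
  route CO₂-neutral. Both facts are asserted symbolically in the tests.
* `augment` also adds a **propionate exchange**: propionate is a measured
  extracellular product, and calibration requires an exchange for every
  measured compound.

## Calibration

`calibrate_exchanges` only ever tightens bounds. Substrate uptake is
upper-bounded in magnitude by measured consumption; measured products are
fixed at their endpoints (configurable to lower bounds); biomass is fixed
at `protein_yield × protein_to_dryweight / biomass_formula_weight`.

* `protein_to_dryweight` defaults to 2.0 (protein ≈ half of dry weight).
* `biomass_formula_weight` defaults to 50 µg/µmol: the synthetic core's
  biomass unit is one acetyl-equivalent (2 C), and 50 µg/µmol commits
  ≈ 9% of substrate carbon to biomass under the reference calibration —
  a realistic share for a stationary-phase batch. Both factors are plain
  policy fields for real models with their own biomass composition.
* **The maximisation target is excluded from clamping** wherever a maximum
  is the question: fixing every measured product *including* the target
  would pin the target at its measured endpoint and make "maximum
  attainable production" meaningless. The pipeline therefore builds two
  calibrated models — one fully clamped (for sampling "physiological"
  flux distributions) and one with the target's exchange left free (for
  FBA, the scan, sweeps and perturbations).
* Open culture mode zeroes the cytoplasmic soluble hydrogenases SHI and
  SHII (H₂ escapes an open vessel and cannot be recaptured); closed mode
  changes nothing.

## Sampling and the bottleneck scan

Sampling uses cobrapy's OptGP sampler. Defaults: n = 5000, thinning = 100,
4 chains; chains run sequentially in one process with per-chain seeds
derived from the user seed through `numpy.random.SeedSequence`, so a seed
reproduces the matrix bit-for-bit on any CPU count. Rows violating the
tolerance are rejected and redrawn, never projected. Tests and pipeline
demos use n = 200–1000 with thinning 10–25 — the desk-scale core mixes in
a few hundred steps, and the scan consumes only per-reaction medians.

The scan caps one reaction at a time at its sampled median and re-maximises
the target. The cap is **sign-aware**: a non-negative median becomes the
upper bound (lower kept), a negative median the lower bound — capping
activity at its typical level on whichever side of zero it operates. A
symmetric |v| ≤ |median| variant would also cap the *reverse* direction,
which the sampled distribution says the reaction does not use. Caps that
make the model infeasible record a constrained maximum of 0 with a note.
Flagging is a strict inequality against the threshold (default 2 mM, the
package-wide unit being mM per batch); the histogram uses right-open bins
of width 0.25 over [0, baseline], last bin closed.

The yield sweep fixes the target at n (default 40) evenly spaced values
from 0 to the model's **own** computed maximum — never a hard-coded
endpoint — and runs FVA for a reaction roster at each step. Scaled ranges
divide each reaction by its largest absolute range endpoint across all
steps (zero-range reactions scale to 0), landing in [−1, 1].

LP degeneracy: only optima are contractual. Optimal vertices are
solver-dependent and are reported but never asserted.

## Carbon closure

The ledger sets consumed cellobiose carbon (12 C per molecule) to 100%.
Measured entries are endpoint mM × carbon atoms. CO₂ is calculated as
`acetate + ethanol + 2 × acetoin` (one decarboxylation per acetyl unit,
two for acetoin; the 1-propanol route contributes nothing because its
carboxylation re-fixes the CO₂ released upstream). Acetoin and isoamyl
alcohol default to 0 when unmeasured. Estimated sinks (compatible solutes,
alanine, EPS, biomass) appear only when the user supplies non-zero
`EstimationCoefficients`; the conversion factors are literature-derived
and none are shipped as defaults, so a default ledger's "total recovered"
covers measured products + CO₂ only. Ledgers are computed in full
precision; only display rounds to one decimal.

## The synthetic core

`build_core_model` emits a 25-reaction, 23-metabolite caricature of
saccharolytic *Thermococcales* fermentation: cellobiose hydrolysis;
glycolysis lumped into a single ATP-neutral, ferredoxin-reducing step
(labelled GAPOR; a GAPN variant reduces NADP⁺ instead); POR; the
ADP-forming ACS to acetate (the host's ATP-yielding step); AOR/AdhF to
ethanol; ALS lumped to acetoin + CO₂; the Fd_red → MBH (H₂ + pumped ion) →
ATPS energy backbone with small-integer ion stoichiometries; Nfn (forward
only, to exclude thermodynamically impossible H₂-to-gradient cycles) and
SHI as NADPH supplies; adenylate kinase plus an AMP-yielding maintenance
drain (so pathway AMP from E4 is recyclable and adenylate turnover has a
physiological, non-pathway flux); an acetyl- and ATP-consuming biomass
drain; and a free compatible-solute/EPS carbon sink. The solute sink and
maintenance drain are what give sampled glycolytic and adenylate fluxes
physiological slack above the bare minimum the fixed products require —
without them every carbon-chain reaction would be artificially pinned and
the bottleneck scan would flag the entire network.

SHII exists but ships closed (bounds (0,0)): it is NADH-specific in vivo
and the core tracks a single NADPH pool; it is present so the open/closed
culture convention has its named targets.

Three **regimes** are enforced by parameter choice and verified by LP at
build time (`GenerationError` otherwise):

* *substrate-limited*: maximum acetate equals the hand-derivable
  4 per cellobiose (2 glucose → 4 pyruvate → 4 acetate);
* *ATP-limited*: headspace H₂ may be recaptured (H₂ uptake open, SHI on),
  so reductant is free; a free-ATP generator strictly raises the
  1-propanol maximum at the origin while free NADPH leaves it flat;
* *redox-limited*: SHI off, H₂ export-only, so every NADPH costs reduced
  ferredoxin; free NADPH strictly raises the maximum.

The measurement generator's default yields per mM cellobiose are the
bottled reference culture's endpoint ratios (0.40/6.8 1-propanol,
0.63/6.8 propionate, 9.36/6.8 ethanol, 6.26/6.8 acetate, acetoin 0), with
protein at 93.65/6.87 µg/mL per mM — the conditions the analyses are
meant to operate under. Noise is independent Gaussian per endpoint with a
5% coefficient of variation (the magnitude of the reported standard
errors), truncated at zero — the simplest model consistent with what is
reported; three replicates.

**What the core does not emulate** — and hence what passing tests do not
show about real data: genome-scale redundancy and alternative routes
(its bottleneck scan is cleanly bimodal where a real network is merely
multimodal), gene–protein–reaction logic, yeast-extract co-substrates,
temperature-shift kinetics and expression levels, thermodynamic
constraints, and any kinetic rate information. Quantitative full-scale
results require the released genome-scale host model as input.

## Verification strategy

Two independent LP oracles live in the test suite: scipy's HiGHS solver,
and an exhaustive vertex enumerator that eliminates fixed variables,
parameterises the null space of S, and enumerates every choice of active
bounds (tractable because generated cores keep the polytope dimension ≤ 5).
`maximize()` must agree with enumeration to 10⁻⁸ relative on 25 randomly
parameterised cores. Sampling feasibility is asserted on 100% of rows;
scan restoration is asserted bit-for-bit; and the calibrate → sample →
scan chain must recover a throttled pathway entry (E1) in ≥ 19 of 20
seeded runs.

## Known limitations

* The biomass/protein conversion is a two-factor policy, not a validated
  composition; absolute biomass-coupled numbers on real models depend on
  the model's own biomass equation.
* Pathway cofactor assignments per reductive step are configurable
  defaults, not measured specificities.
* The sampler inherits OptGP's approximate-uniformity; no convergence
  diagnostics beyond the two-seed median comparison are performed.
* The bottleneck scan caps one reaction at a time; correlated multi-
  reaction limitations are out of scope.
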