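# Methods

## Model scope and structure

`cannakin` describes one engineered *S. cerevisiae* cell and its medium as
a deterministic ODE system in concentration units (mM) on a time axis in
hours. A single cytosolic volume is the reference frame; medium-to-cell
fluxes are pre-scaled into mM·h⁻¹ of cytosol, so no explicit volumes
appear. Compartments are bookkeeping labels: `medium` (glucose batch,
clamped hexanoic-acid feed), `cytosol` (everything from pyruvate to THCA),
`mitochondrion` (a separate acetyl-CoA pool reached via pyruvate
dehydrogenase and drained by a lumped TCA cycle and the ATP-citrate-lyase
shuttle), and `ledger`.

Ledger species — ATP, NADH (FADH₂ counted as NADH), NADPH, CO₂, H₂O₂ —
appear in stoichiometries with integer or simple rational deltas and are
integrated into cumulative totals (`LedgerTotals`: ATP split into consumed
and produced streams, NAD(P)H net, CO₂ released, H₂O₂ produced), but they
never occur in a rate-law denominator. Energy and redox demand are
outputs; the model deliberately imposes no cofactor limitation and no
toxicity feedback. The toxicity numbers carried in `model.constants`
(THC EC₅₀ 360 mg/L, hexanoic-acid EC₅₀ ≈ 1.2 mM, 280 mg/L experimental
titer ceiling) are reporting context only, and the model is not expected
to stay accurate in regimes where they would matter.

Biomass growth, pH, pO₂, temperature effects on enzyme folding,
glycosylation/detoxification, and downstream processing are out of scope.
The 40-h default horizon reflects that the kinetics describe
exponential-phase physiology; beyond the point where a real culture goes
stationary the "ideal cell" assumption loses meaning.

## Rate laws

* **Michaelis–Menten**, irreversible, for every single-substrate step.
* **Ordered bi-bi**, irreversible with product terms omitted,
  `v = vmax·a·b/(ki_a·km_b + km_b·a + km_a·b + a·b)`, reserved for the two
  steps where neither substrate is in excess: the fused OLS/OAC reaction
  (hexanoyl-CoA + malonyl-CoA) and NphB (GPP + olivetolic acid).
* **Mass action** for the ERG20 couplings; the IPP ⇌ DMAPP isomerization is
  the one reversible reaction (`k`, `k_rev`), so the DMAPP pool can
  equilibrate in either direction.
* **Diffusion** `k·(out − in)` for hexanoic-acid uptake; the sign reverses
  with the gradient.
* **Hill regulation** as a multiplicative factor on vmax with shared
  half-point `K_rep` and `n = 2`: ADH1 is glucose-activated
  (`glc²/(K² + glc²)`), ADH2 glucose-repressed (`K²/(K² + glc²)`). This
  realizes Crabtree overflow and the diauxic shift with one free parameter
  and no explicit respiratory-capacity threshold: ethanol accumulates
  while glucose is high and is reconsumed after depletion.

Branched reactions (OLS/OAC: olivetol 0.95, olivetolic acid 0.05, the
lactone by-products HTAL/PDAL at 0 by default; NphB: CBGA 1.0, the
O-prenylated 2-O-geranyl side product 0 for the CBGA-specific variant)
carry their product sets as fractions applied to a shared consumption
stoichiometry, so the molar product ratio is exact by construction at
every instant, not an emergent outcome.

Two numerical guards keep starved scenarios well-posed: rate-law inputs
are clipped at zero inside the right-hand side, and any reaction that
consumes a species *not* appearing in its rate law (e.g. the second
acetyl-CoA of the HMG-CoA synthase step) is multiplied by a smooth
depletion switch `s/(s + 10⁻⁴ mM)` for that species. At the pool sizes of
the default run the switch is a ≤0.01% perturbation; its role is to make
rates vanish as any consumed pool reaches zero.

## Integration and observables

`scipy.integrate.solve_ivp` with LSODA (stiff-capable, adaptive), relative
tolerance 1e-8 and absolute tolerance 1e-10 mM by default, output grid
0.05 h. Concentrations are clipped into [0, ∞) for reporting; an excursion
below −1e-6 mM aborts with a stability error. Observables interpolate
linearly on the output grid, so halving the grid does not move them:

* `depletion_time`: first crossing below a threshold (default 0.1 mM,
  ≈0.1% of the 111 mM glucose charge — "completely metabolized" needs an
  operational cutoff); +∞ sentinel if never reached.
* `steady_state_time`: earliest time after which |d[s]/dt|/max([s], 1e-6)
  stays below 1%/h through the end of the run.
* `yield_per_substrate`: grams of product formed per gram of substrate
  consumed, via the molecular weights shipped in the species table
  (THCA 358.48, glucose 180.16, olivetolic acid 224.25, CBGA 360.49,
  hexanoic acid 116.16 g/mol).

## Parameters and calibration

No rate constant here is a measured literature value; the primary sources
for this pathway report endpoints, not kinetics. The shipped parameter
file is therefore a calibration output and says so in its header. Km
values are fixed at literature-plausible magnitudes (single-digit mM for
transport and central carbon, sub-mM for dedicated biosynthetic enzymes)
and are not fitted. Free parameters are vmax-type scale factors for the
pacing enzymes, the hexanoic-acid diffusion constant, the glucose
regulation half-point `K_rep` (5 mM), and the PPP fraction `f_ppp`
(default 0.1 of glucose catabolism; the black box fixes only NADPH yield,
2 per glucose routed).

Calibration anchors are the model endpoints the default parameterization
reproduces: glucose (111 mM) depleted at 20.8 h; THCA 0.837 mM
(≈300 mg/L) at 40 h; accumulated GPP ≈0.65 mM at 40 h; intracellular
hexanoic acid steady below 0.3 mM under a 1 mM clamped feed; olivetolic
acid steady within 10 h; which together imply the 0.015 g/g mass yield on
a 20 g/L glucose charge. The objective is a weighted sum of squared
relative residuals (one-sided hinge for upper bounds), minimized by
Nelder–Mead in log-parameter space with an explicit ±20% initial simplex
(the scipy default simplex degenerates for log-values near zero),
multi-started from a seeded Latin-hypercube design; the search is
deterministic given the seed. Parameters whose objective profile varies by
less than 1% across their bounds can be flagged as flat (non-identifiable)
in the calibration report rather than reported as recovered. The
glucose-uptake vmax has a closed form — for Michaelis–Menten consumption,
t(S₀→S_f) = (ΔS + K_m·ln(S₀/S_f))/V_max, giving 5.669 mM/h for
111 → 0.1 mM in 20.8 h at K_m = 1 mM.

Two engineered steps are represented directly by their variant forms
rather than multipliers: ERG20 F96W-N127W (the GPP-forming reaction *is*
the double mutant, with a small calibrated residual FPP-forming fraction
retained so FPP accumulates alongside GPP) and NphB Y288A/G286S (the
CBGA-specific variant; the promiscuous O-prenylating wild type is
available by configuring the 2-O-GOA branch fraction). The other default
interventions are multiplicative variants from the registry: tHMGR ×11,
IDI1 overexpression ×2, ACC1 phosphosite mutant ×3, OAC Y27F ×1.62, and
the THCAS pair ×2 and ×1.7. The AAE1 activation cost is counted as 2
ATP-equivalents (ATP → AMP via the adenylate intermediate).

## Sensitivity analysis

Pathway intermediates all start at 0 mM, so a relative perturbation is
undefined; the perturbation is a t = 0 concentration bolus (default
0.05 mM) and the score is the THCA endpoint gain divided by the bolus — a
dimensionless transfer coefficient. An optional time-integrated variant
averages the normalized gain over the whole grid. An independent
finite-difference oracle recomputes single scores by central difference of
half-width bolus/2 on a freshly rebuilt model; where the base initial
concentration is below bolus/2 the stencil center shifts to bolus/2 so
both evaluations stay non-negative.

On the calibrated default, CBGA scores ≈1 (its only sink is THCA
synthase), olivetolic acid just below it, and everything upstream of the
polyketide bottleneck scores near zero. One finding worth recording: a
10× faster NphB raises the olivetolic-acid score toward CBGA's, but
*lowers* the GPP score. Once olivetolic-acid supply is the binding
constraint, prenylation flux is pinned to it in quasi-steady state, and a
GPP bolus can only add THCA by drawing down the standing olivetolic-acid
pool — which a faster NphB holds ~10× smaller. The intuition that a faster
prenyltransferase would make extra GPP more valuable does not survive this
model structure; extra GPP stays inert (or drains to FPP) unless the
polyketide side moves with it.

## Synthetic data and what the tests show

The generators exist so every stage is testable without external data:
lognormal multiplicative parameter perturbations (concentrations and rate
constants are positive, so multiplicative noise is the natural error
model), pointwise lognormal observation noise with a specified coefficient
of variation, and equal-rate first-order chains whose Erlang/Bateman
closed form is the integrator's independent oracle. All generators are
pure functions of (inputs, seed).

Parameter-recovery tests (anchors generated from a known truth, search
started from a perturbed point) demonstrate that the calibration machinery
finds identifiable parameters to well within 10% noise-free and 15% at 5%
observation noise. What passing these tests does *not* show: the noise
model is idealized (independent, multiplicative, unbiased), the default
run is a deterministic ideal-case cell, and none of the trajectories
emulate real fermentation artifacts (sampling cadence, biomass drift,
instrument bias). Agreement with the anchors shows internal consistency
of the calibrated model, not validation against independent measurements.

## SBML exchange

Export writes SBML Level 3 core with compartments, species (clamped feeds
as boundary species), reactions with explicit kinetic-law math, local
parameters, and modifier references for regulators. Because SBML core
cannot express this package's structured law kinds (ordered substrate
lists, branch fractions, Hill factors), every element also carries a
namespaced annotation holding a JSON payload of its exact definition;
import prefers the payload (making round trips bit-stable and
hash-identical) and falls back to recognizing kinetic-law parameter
signatures for foreign documents, rejecting unknown forms with a named
error.

## Problem sizes

The default run integrates 27 dynamic species plus six ledger counters
over 40 h (801 output points) in well under a second on one core; the
full sensitivity analysis is eight such runs, and the shipped calibration
(six free parameters, single start from the hand-balanced point) took a
few hundred simulations. Test-suite recovery experiments use two free
parameters and three endpoint anchors, chosen to keep each experiment
around a hundred simulations while still exercising the full
multi-start/simplex path.

## Known limitations

* Absolute pool sizes of unanchored intermediates (cytosolic acetyl-CoA,
  ethanol, olivetol) are only weakly constrained by the endpoint anchors;
  treat them as qualitative.
* Branch fractions are composition-independent constants; real OLS/OAC
  product ratios shift with malonyl-CoA availability.
* The Hill form and `K_rep` for glucose switching are modeling choices, not
  measured regulation curves.
* Irreversibility everywhere except IDI1 means the model cannot represent
  product inhibition or thermodynamic back-pressure; no Haldane
  consistency is attempted.
* The eighth sensitivity input mentioned alongside the canonical seven is
  left as a caller-supplied slot rather than guessed.
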