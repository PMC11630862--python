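# Methods

## The measurement being modelled

A split-chamber zero-resistance ammetry (SC-ZRA) cell holds two nominally
identical carbon-steel coupons (WE1, WE2) in separate chambers of synthetic
brine connected by a salt bridge; the coupons are shorted through a
zero-resistance ammeter and current is logged every 15 min.  Positive
current denotes electron transfer from WE1 to WE2.  When fermentative
bacteria in one chamber acidify the fluid, proton reduction concentrates on
the coupon they touch and the *remote* coupon supplies the electrons by
anodic dissolution (Fe⁰ → Fe²⁺ + 2e⁻) — corrosion at a distance.  The
package implements both quantification routes (coupon weight loss and
charge integration) and a generator that emulates the experiment.

## Weight-loss route

Mass loss per coupon is the difference between the initial mass and the
first cleaning-cycle mass whose change from the previous weighing falls
below a tolerance (default 0.001 g, read as "no mass lost between wash
cycles" at typical balance resolution; configurable).  If no cycle
converges the last one is used and the result flagged.  The rate is
`CR = K·W/(D·A·t)` with `K = 8.76×10⁴` giving mm/yr from g, cm², h and
g/cm³.  `K` is sometimes quoted as "dimensionless"; it is in fact a unit
conversion, so the package computes in mm/yr and converts to mpy by the
exact factor 39.3701 on request.  Density of UNS G10180 defaults to the
handbook 7.87 g/cm³ (overridable).  CRR is WE1/WE2; the biotic rate is the
absolute rate difference with the faster electrode kept as a "net anode"
annotation (reported magnitudes are always non-negative; the sign lives in
the annotation).

## Faradaic route

Charge is the trapezoidal integral of the signed current over the trace
(time converted h → s), exact for piecewise-linear current and tolerant of
irregular sampling; positive and negative components are accumulated
separately with linear zero-crossing splitting so they sum to the total
exactly.  Faraday's law `Δm = |Q|·a/(nF)` uses a = 55.845 g/mol and n = 2
(ferrous dissolution).  The predicted biotic rate pushes Δm through the
weight-loss formula using the anodic coupon's geometry (areas are equal in
this design; the code would flag a mismatch).  The net-anode call is the
sign of Q, with |Q| < 1 C per 30 days (scaled to the window, configurable)
called "balanced" — far below any treatment-scale signal.  Prediction
accuracy is `100·(1 − |pred − actual|/actual)`, floored at 0 and undefined
(reported n/a) when the actual biotic rate is zero; this relative-agreement
definition reproduces the ~90 % headline agreement of the reference
predicted/actual pairs and is logged in reports as the package's own
convention, since no formula is standard.

## Brine speciation

Chamber pH is the unique root on (0, 14) of the charge balance

    Z + B_T/2 + [H⁺] = [OH⁻] + [HCO₃⁻] + 2[CO₃²⁻] + [Ac⁻] + [B⁻]

solved by Brent bracketing to machine precision (residuals < 10⁻¹⁰ M by a
wide margin).  Z is the strong-ion excess of the recipe
(350 NaCl / 30 NaHCO₃ / 25 CaCl₂ / 15 MgCl₂ / 2 KCl / 0.05 K₂HPO₄ mM):
the chloride salts close exactly, so Z = 30 mM with bicarbonate and 0
without.  K₂HPO₄'s potassium is balanced by its phosphate, which is lumped
— together with yeast extract and biomass — into a single monoprotic
background buffer B (default 14.4 mM total at pKa 6.8, added
half-neutralised, hence the B_T/2 counter-cation term).  Equilibrium
constants default to 25 °C values (acetic 4.756; carbonic 6.35 / 10.33;
pKw 14.00) and are configurable; activity corrections are deliberately
omitted despite ~0.4 M ionic strength because the analysis is sign- and
shape-driven, and the constants being configurable leaves room to layer a
Davies-type correction later.

Carbonate handling follows the headspace: the buffered treatments (80:20
N₂:CO₂) use an open system with fixed CO₂(aq) = 6.8 mM (Henry's law at
0.2 atm); the bicarbonate-free treatments (N₂) use a closed system with
zero total carbonate.

**Calibration.** The background buffer was sized once, by closed-form
charge-balance arithmetic, so that full conversion of 20 mM glucose at an
acetate yield of 1.0 mol/mol (≈ 20 mM total acetate) brings the
bicarbonate-free chamber to pH ≈ 4.5 — the observed endpoint — while the
CO₂-buffered chamber moves < 0.5 units.  The resulting starting points are
pH ≈ 6.80 (unbuffered, slightly below the buffered ≈ 6.97, as observed)
and endpoints 4.50 / 6.59.  The calibration lives in configuration
defaults, not hard-coded truth.

## Fermentation kinetics

Monod growth after a lag: `dX/dt = μmax·S/(Ks+S)·X`,
`dS/dt = −(1/Y_X)·dX/dt` with S floored at 0, integrated by RK45
(rtol 10⁻⁹) on the 15-min grid; acetate is exactly `Y_ac·(S₀ − S)`.
Defaults: μmax = 0.05 h⁻¹, Ks = 2 mM, Y_X = 0.05 A600/mM (so 20 mM glucose
supports a maximum A600 of ≈ 1, the observed ceiling), Y_ac = 1.0 mol/mol
(acetate was the only detected product; the remaining carbon goes to
biomass and CO₂), lag 12 h, inoculum A600 = 1 (cells are concentrated into
the chamber at stationary-phase density).  In the Ks → 0 limit the glucose
depletion time reduces to the closed-form exponential-growth expression,
which the tests use as an oracle.

## Galvanic current model

The two-electrode current is a Tafel-like function of the pH asymmetry:

    I(t) = −k₀ · (10^(−β·pH_WE1) − 10^(−β·pH_WE2))

so a more acidic WE1 chamber yields negative current (electrons WE2 → WE1,
anode on WE2).  β defaults to 1 decade per pH unit (Nernstian proton
sensitivity); k₀ = 0.5 A is anchored so the default unbuffered-inoculated
run integrates to ≈ −39 C over 30 days, i.e. a predicted biotic rate of
≈ 1 mpy — the scale of the reference predicted rates — because published
current magnitudes are not machine-readable.  Noise is multiplicative
Gaussian on the current (default sd 5 %, explicit seed).  Ground-truth
coupon losses are a constant abiotic baseline (0.10 mm/yr ≈ 3.9 mpy, the
sterile-control scale, contributing zero current) plus the Faraday
equivalent of the noise-free charge added to the net anode, so by
construction the emitted noise-free trace integrates exactly to the imposed
differential mass loss.  Synthetic cleaning-cycle records converge exactly
to the imposed loss (final two cycles equal), mirroring the ASTM stopping
rule.  Chemistry is sampled every 24 h.

## Pathway screen

End-product completeness is a boolean AND/OR rule per product over a
controlled enzyme vocabulary (the inventory row labels; EC/KO mapping is a
user-supplied concern).  Rules live in versioned YAML.  The default
ethanol rule requires alcohol dehydrogenase alone — this reproduces the
published calls for all three MAGs, including ethanol for
*S. epidermidis*, whose acetaldehyde dehydrogenase was not detected (many
staphylococci route acetaldehyde through bifunctional enzymes).  A strict
two-enzyme alternative (`strict_ethanol`) ships alongside and flips only
that call.  Completeness is monotone in the presence set by construction
(rules contain no negation), which the property tests exercise.

## What the generator does and does not emulate

It reproduces: the four-treatment contrast (current sign and scale, pH
trajectories, glucose→acetate conversion), the daily-sampling cadence, the
charge/mass-loss bookkeeping, and realistic instrument noise.  It does not
reproduce: the slightly positive current and WE1-leaning CRR of the
*buffered* inoculated cell (a direct-exposure effect on the colonised
coupon, not a pH-difference effect — the model yields a small negative
charge there instead); suppression of overall rates by inoculation in the
unbuffered cell; electrode potentials beyond a nominal drift; biofilm
structure, H₂ feedback or sulfide chemistry.  Passing tests therefore
demonstrate the correctness of the analysis chain and the pH-driven
mechanism's signatures, not a quantitative match to any one incubation.

## Numerical choices and problem sizes

Traces are 15-min grids over 720 h (2 881 points); pH solves are < 0.1 ms
each, so a full four-treatment suite runs in well under a second.
Stochastic recovery checks use 20 seeds at 5 % noise (median relative
error ≈ 0.1 %, comfortably within the 5 % requirement; the noise averages
out over ~2 900 samples).  The slow-sine integration oracle uses a
half-period 1 440-h sine: trapezoidal error scales as (ωΔt)²/12, so the
10⁻⁶ relative target is only meaningful in this slow-drift regime — which
is also the regime real ZRA signals occupy.  Report tables round rates,
biotic rates and CRR to one decimal, matching the precision of the
reference table.

## Known limitations

Concentration-based equilibria (no activity model) bias absolute pH by a
few tenths at this ionic strength; the background buffer is a lumped proxy
rather than a speciated phosphate/amino-acid model; the galvanic law is a
single driving-force term with no electrode kinetics, mass transport or
film formation; and the reference study's absolute mpy values cannot be
recomputed from first principles because the underlying masses and
currents are unpublished — they enter only as inputs to the
ratio/difference/accuracy arithmetic.
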