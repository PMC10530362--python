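# Methods

## Steady-state block models

The package models inhibition of agonist-evoked currents by cationic
open-channel blockers as binding within the transmembrane electric field.
With thermal voltage V_t = RT/F (25.507 mV at the 296 K default; CODATA
values of R and F), membrane potential V in mV (inside minus outside,
negative at rest) and concentration C in µM:

* `ratio_eq1` — one impermeant pore site. K_d(V) = K_b·e^{z δ_b V/V_t};
  the exponential acts on K_b, so for a cation (z ≥ 1, δ_b > 0)
  hyperpolarization shrinks K_d and deepens block. This sign convention is
  the only reading under which the permeant model reduces to the
  single-site model at K_p = 0 while block deepens with hyperpolarization.
* `ratio_eq2` — permeant blocker. K_d,eff(V) adds
  K_p·e^{−z δ_p V/V_t}: at strongly negative V the field pushes the
  blocker through the channel and block is relieved. K_d,eff is convex in
  V with minimum at the relief voltage
  V* = V_t/(z(δ_b+δ_p))·ln(K_p δ_p/(K_b δ_b)) (`relief_voltage`;
  a distinct `NoReliefError` signals K_p = 0 or δ_p = 0).
* `ratio_eq3` — adds an independent voltage-insensitive site of affinity
  K_vin. Independence means the ratio factorizes exactly as
  `ratio_eq2 × 1/(1 + C/K_vin)`; the C² cross-term of the expanded form is
  what double occupancy of two independent sites implies. No cooperativity
  is modelled.

δ_b and δ_p are treated as independent empirical quantities; their sum may
exceed 1 (the AAQ parameter set has δ_b = 0.9 with δ_p = 0.15), so no
joint constraint is imposed. The blocker charge z is fixed from chemistry
(QAQ +2, AAQ +1), never fitted; the AMPA-receptor QAQ parameters use z = 2
throughout. Units are µM and mV everywhere; converters belong at the I/O
boundary. Illumination is a discrete state selecting a parameter set —
photochemistry (spectra, photostationary states) is out of scope, and
switching is treated as instantaneous.

## Parameter presets

`azoblock.presets()` transcribes the published values: Hill IC50s for both
compounds on NMDA and calcium-permeable AMPA receptors in the dark and
under 380 nm light (Hill slopes ≈ 1); the consensus depths δ_b = 0.18
(NMDA), δ_b = 0.70 (QAQ) / 0.90 (AAQ) with δ_p = 0.15 (CP-AMPA); and the
single-condition reference ratios, including the weak block of
calcium-impermeable AMPA receptors. Each preset carries a `source` note
distinguishing *reported* values from *derived* and *calibrated* ones.

Two derivations fill gaps the publications leave open:

* NMDA K_b values are obtained exactly from the −120 mV anchors
  (0.26 for QAQ, 0.31 for AAQ at 30 µM) with δ_b = 0.18, giving 57.3 and
  31.4 µM. Illuminated-state K_b scales by the IC50 ratio — the
  parallel-shift interpretation that light changes affinity, not depth.
* CP-AMPA K_b/K_p/K_vin are not published. They were calibrated once
  against the published constraints: K_vin = 150 µM puts the depolarized
  residual inhibition at 30 µM inside the reported 15–20% band; QAQ
  K_b = 310, K_p = 7 µM place the relief voltage at −80 mV (relief
  visible negative to −70 mV) with −70 mV potency matching the dark IC50
  of 17 µM; AAQ K_b = 280, K_p = 12 µM put relief at −120 mV (no clear
  relief within the scanned range, as observed) with potency matching
  IC50 28.5 µM. Whether K_vin differs between illumination states is not
  known; presets keep it fixed, but the fitting layer estimates it per
  state when asked.

## Kinetic schemes

Gating is two-state (Closed ↔ Open, opening proportional to agonist
concentration, desensitization omitted — the experiments this emulates
use steady kainate/NMDA responses). Block rates map from the steady-state
parameters with the voltage dependence placed entirely on unbinding and
permeation: k_on is voltage-independent (default 0.7 /µM/s),
k_off = k_on·K_b·e^{z δ_b V/V_t}, k_perm = k_on·K_p·e^{−z δ_p V/V_t}.
This is the minimal assignment whose open-state balance reproduces
K_d,eff exactly; other assignments are expressible through `RateLaw`.
Permeated blocker returns to the clamped extracellular pool
(concentration clamp), keeping the chain irreducible; cytoplasmic
accumulation is not tracked. Permeation edges are excluded from the
detailed-balance bookkeeping — their stationary flux is exactly the
microscopic-reversibility violation the permeation cycle creates, and it
vanishes when K_p = 0.

No rate constants are published (block relaxations were faster than the
solution-exchange limit of ~200 ms); defaults — opening 0.5 /µM/s of
agonist, closing 25 /s, k_on 0.7 /µM/s — complete block relaxation at
30 µM within ~100 ms. The slow trapping reference blocker
(`slow_trapping_reference`, IEM-1925-like) uses K_d(−70 mV) = 0.5 µM and
k_on = 0.25 /µM/s, giving washout time constants of ~10 s.

`simulate` propagates the master equation per piecewise-constant protocol
segment with the matrix exponential, so trajectories are exact for the
scheme up to roundoff (probability conserved to 1e−9, checked).
`steady_state` solves the null space after verifying strong connectivity;
reducible conditions (e.g. agonist absent in a trapping scheme) raise an
error naming the closed communicating classes.

### Equivalence with the closed forms

The oracle identity is stated on the *unblocked open fraction*
P(Open)/(P(Open)+P(OpenBlocked)), times the allosteric conductance factor
where present. Because the schemes are chains, the stationary balance
across the Open–OpenBlocked cut gives this fraction as 1/(1 + C/K_d,eff)
exactly, independent of gating rates; the full current ratio converges to
the same quantity as agonist saturates. The allosteric site is an
instantaneous-equilibrium factor 1/(1 + C/K_vin) on open-state
conductance (fast-kinetics limit), which makes the two-site equivalence
and the allosteric-partner competition control exact.

### What the tail-current index can and cannot distinguish

`tail_current_index` is peak |I| after washout over |I| just before it.
Immediately after washout the open-state balance is
dP(Open)/dt = k_off·P(OB) − α·P(Open), and since the pre-washout ratio
P(OB)/P(Open) = C/K_d in *both* the trapping and foot-in-the-door
topologies, an overshoot occurs if and only if k_on·C > α — in either
scheme. The index therefore discriminates the modes only through
kinetics: the fast foot-in-the-door compounds (k_on·C ≫ α at the 300 µM
tail-protocol concentration) overshoot strongly (index ≈ 4), while the
slow trapping reference (k_on·C ≪ α) decays monotonically (index ≈ 0.98).
A scheme-topology-only distinction at identical rates is impossible in
this model class; a test records that a trapping scheme with fast rates
also overshoots. The topology-sensitive diagnostic is the double-pulse
residual: the trapped blocker survives an agonist-free wash inside the
closed channel (residual ≈ 0.6 under the defaults), while the
foot-in-the-door blocker must exit through the open state and washes out
completely (residual ≤ 1e−6).

Competition uses occupancy exclusion at a single shared pore site
(whether displacement is direct knock-off or occupancy competition is not
experimentally distinguishable; the scheme implements the latter). A
near-saturating fast pore blocker (500 µM) keeps the slow blocker out of
the channel during co-application and collapses its recovery time
constant from ~12 s to ~0.1 s; an independent allosteric antagonist
leaves it unchanged (<0.2%). Recovery time constants come from a
mono-exponential fit over the washout segment (8 s co-application, 30 s
recovery by default).

## Fitting

Weighted least squares (weights 1/sd² when per-condition SDs are present,
unit weights otherwise — the original analysis does not state its
weighting) via bounded trust-region optimization, with the best of 20
seeded multi-starts (K's drawn log-uniformly in [1e−2, 1e5] µM, depths
uniformly in [0, 1]). Model selection uses AICc — with n ≈ 8–10 voltage
points the small-sample correction matters — with ties broken toward
fewer parameters, and underdetermined candidates ranked last. The
joint dark/light fit shares the depth parameters and estimates per-state
affinities, mirroring the interpretation that photoisomerization changes
affinity, not site location; a Wald–Wolfowitz runs test on the shared-fit
residuals flags slices whose depths genuinely differ. `two_point_delta`
is the exact algebraic inverse of the single-site model from two
observations. Bootstrap intervals are case-resampling percentiles
(2.5/97.5), resampling whole cells when a cell column is present and rows
otherwise; replicates that become underdetermined are skipped and
counted. Fitting operates on mean-per-condition rows or per-cell rows;
mixed-effects (per-cell random effect) modelling is out of scope.

## Synthetic data

Generators emulate the measurement structure of the experiments: per-cell
inhibition ratios over the +20…−140 mV grid (20 mV steps) at 30 µM, or
over a half-log 1–500 µM concentration series at −70 mV (the exact
published concentration grids are not listed; half-log spacing is the
field default), with n = 6 cells per condition and additive Gaussian
ratio noise of SD 0.05 (mid-range of the reported 0.02–0.08), clipped to
(0.01, 1.2]. Per-cell ratios are i.i.d. across voltages — the summaries
being emulated are per-condition, and no cell random effect is reported —
so bootstrap resampling of rows and of cells are equally valid for these
data; the noise model is a choice, since only means ± SD are published.
Traces add Gaussian noise and optional linear drift to simulator output.
Not emulated: series-resistance artifacts, liquid-junction potentials,
solution-exchange kinetics, desensitization, Mg²⁺ block, monochromator
spectra. Passing recovery tests therefore show identifiability under
idealized i.i.d. noise, not robustness to correlated instrumental error.

## Numerical choices and problem sizes

Matrix exponentials make the simulator's accuracy dt-independent within a
segment; dt only sets the recording grid (default 1 ms; 5 ms for the slow
competition protocols). The steady-state solve uses least squares on the
transposed generator with a normalization row. Ratio-table CSVs embed
units in column names (voltage_mV, concentration_uM) and preserve unknown
columns. The recovery study in the acceptance suite uses 200 generated
datasets with 200 bootstrap replicates each, refitting bootstrap
replicates from a warm start; the model-recovery examples use 20
repetitions. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Known limitations

* The two-site model's K_b/K_p/K_vin for AMPA receptors are calibrated,
  not published; absolute affinities carry that uncertainty even though
  the depths and the qualitative shape are published.
* δ_b + δ_p > 1 for AAQ has no clean physical reading; parameters are
  empirical descriptors of the voltage dependence, not literal positions.
* The kinetic rate defaults are order-of-magnitude choices consistent
  with "faster than solution exchange"; quantities that depend on them
  (tail amplitudes, recovery taus) are qualitative signatures, not
  predictions.
* Single-channel (stochastic) simulation and use-dependence fitting are
  out of scope.
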