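# Methods

## Overview

`glottiflow` is a reduced-order model of phonatory airflow. The glottal
channel — contraction (subglottal), glottis (between the vocal-fold medial
surfaces) and expansion (supraglottal) — is discretized into `n + 1` planar
cross sections along the flow direction, and the quasi-steady pressure
balance from the prescribed subglottal pressure `Ps` to the supraglottal
pressure `Pc` is written as a Bernoulli equation with one dimensionless
viscous-loss coefficient `fr_i` per glottal segment:

    Ps + ρ/2 (Q/As)² = Pn + ρ/2 (Q/An)² + ρ/2 Q² Σᵢ fr_i / Aᵢ²

with sudden-expansion recovery `Pn − Pc = −ρ/2 (Q/An)² · 2 (An/Ac)(1 − An/Ac)`.
Solving for the flow rate gives a closed form; inverting the balance
segment-by-segment turns any reference per-section pressure table (for
example section-averaged Navier–Stokes output) into training targets for
`fr`. A small fully connected network maps eight dimensionless per-section
features to `fr`, closing the model: resistance depends on the flow-dependent
features (Reynolds number, pressure-drop coefficient) and the flow depends on
the resistance, so prediction uses a damped fixed-point iteration.

All units are CGS (cm, g, s, dyn/cm²); pressures are accepted in kPa at the
configuration interface (1 kPa = 10⁴ dyn/cm²). Default air properties are
ρ = 1.145×10⁻³ g/cm³ and ν = 1.655×10⁻¹ cm²/s; default boundary pressures
are Ps = 1.0 kPa, Pc = 0.

## Shape synthesis

The medial surface is a half-gap field g(y, z) on a uniform grid
(resolution 0.01 cm by default), with y the inferior–superior (flow)
coordinate over the medial thickness T = 0.3 cm and z the anterior–posterior
coordinate over the fold length L = 1.5 cm. The prephonatory surface is a
linear inferior–superior half-gap profile (convergent when the inferior
half-gap exceeds the superior) multiplied by a cosine taper to closure over
the 5 % of L nearest each fold end. Vibration modes (m, n) — m
half-wavelengths along the fold, n along the flow — contribute

    ξ = a · sin(mπz/L) · cos(nπy/T − φ − φ₀)

added antisymmetrically to the two surfaces; the sine factor anchors the
folds at their anterior/posterior ends. Where the surfaces interpenetrate
(closed phase) both are replaced by their pointwise mean, so the contact
patch has exactly zero gap. The contraction and expansion parts are then
extruded by per-column linear interpolation between duct half-widths and the
inferior/superior glottal gap.

The default training corpus is 2 prephonatory shapes (convergent
0.10 → 0.02 cm half-gap, divergent 0.02 → 0.10 cm) × 2 modes ((1,0) with
amplitude 0.05 cm, (1,1) with 0.02 cm) × 16 phases uniformly spaced on
[0, 2π), i.e. 64 shapes. The mode amplitudes and prephonatory half-gaps are
package defaults chosen to produce realistic normal-phonation gap widths
(maximum glottal half-gap of order 0.1 cm, full closure during part of the
(1,0) cycle); they are configurable.

## Discretization and features

"n = 128" is read as 129 stations / 128 segments spanning the contraction
entry through the glottal exit. With a station spacing of 0.012 cm this
fixes the default contraction length at 1.236 cm. Per station, the open
area is the z-integral of the gap width and the wetted perimeter is the
boundary length of all open intervals (two wall curves plus vertical
closures at abrupt interval ends), which supports multi-channel sections
produced by partial contact. Areas are clamped at a floor of 10⁻⁴ cm² so
closed stations stay usable by the solver; a station with no opening falls
back to a square slit of the floor area. D = 4A/Pe exactly.

The eight features per section follow the standard dimensionless set:
Y\* (position normalized to [0, 1]), A\* = A/A₀, D\* = D/D₀, upstream and
downstream diameter slopes α⁺ and α⁻, shape change rate ΔS\*, pressure-drop
coefficient ΔP\* = ΔP/(ρ/2 (Q/A)²), and Re = Q·D/(A·ν). Feature rows are
computed for sections 0…n−1 (so Y\* spans exactly [0, 1]); the inlet row
uses one-sided differences (α⁺ copied from its neighbour, ΔS\* set to 0).
Training record i pairs the feature row of section i — the upstream face of
segment i+1 — with the target fr_{i+1}, giving exactly n records per shape
(64 × 128 = 8192 at defaults).

## Surrogate ground truth

High-fidelity per-section reference data can be loaded from CSV tables.  For
self-contained operation the package ships a deterministic quasi-1D
surrogate: per segment,

    fr = 64 L/(D Re)  +  k_sep · max(0, α⁻ · D/L)²

(laminar Darcy friction plus a separation penalty active only where the
channel diverges downstream; k_sep = 0.5 by default, both terms
config-exposed). The segment is evaluated on its upstream section, whose
downstream slope is the segment's own divergence; this makes the surrogate
resistance an exact measurable function of the extracted features, which is
the property the regression stage is meant to exercise. The surrogate flow
rate is found by a bracketed Brent root-find on the closed-form balance
(resistance only reduces the flow, so the bracket is
(10⁻³, Q_Bernoulli]); the residual is monotone because the laminar term
scales as 1/Q and the separation term is Q-independent. The root is polished
to machine precision; the enforced contract is recovery of the prescribed
outlet pressure to 10⁻⁹ relative. The surrogate is a stand-in law with
plausible physics, not a calibrated viscous model: its purpose is a
deterministic, geometry-sensitive mapping the network must learn, so
resistance magnitudes on strongly divergent shapes are much larger than a
Navier–Stokes average would give, and flow-rate errors of the inviscid
model against this surrogate are correspondingly exaggerated.

## Resistance regressor

A fully connected network (hidden layers 256/64/16/4, ReLU, linear output;
20 % inverted dropout after each hidden layer, active only in training
passes) is trained with mini-batch Nadam (learning rate 10⁻³ with cosine
decay to 10⁻⁵ over the run, batch 256) on a mean-squared loss with L2
penalty λ‖w‖², λ = 10⁻⁴. The decay schedule was chosen by validation
performance — the stated purpose of the cross-validation stage — because it
averages out dropout gradient noise in the final epochs. Weights are
initialized from a normal distribution with σ = 0.05; one seed threads the
split, initialization and batch shuffling. The implementation is plain
numpy with explicit forward/backward passes. Inputs are standardized by
zero-mean normalization fitted on the training split only; the regression
target is standardized the same way internally (and mapped back at
prediction) so the optimizer's step size is matched to the output scale
whatever the corpus' resistance magnitude — reported MAEs are always in
physical units. The default epoch budget is 20 000; the fast profile used
by the test suite and the acceptance script trains for 2000 epochs (500 in
the reduced end-to-end pipeline runs), which is where the held-out error
plateaus on the surrogate corpus.

Train/test splitting is stratified by shape so sections of one shape never
straddle the split; k-fold cross validation (k = 5) records per-epoch MAE
curves for the training folds (with dropout, as during optimization) and
validation folds (deterministic evaluation) — the validation curve
typically sits below the training curve for exactly that reason.

Prediction inside the flow solver uses under-relaxed fixed-point iteration
(factor 0.5, relative tolerance 10⁻⁶ on Q, 50 iterations maximum) starting
from fr = 0.

## FSI loop

The paired-waveform demonstration couples the flow model to a deliberately
simple wall: lateral-only oscillators on the medial-surface grid (masses,
linear springs and dashpots per node from per-area parameters, plus
nearest-neighbour coupling springs that support a mucosal-wave-like phase
lag), anchored at the anterior/posterior columns, with symplectic-Euler
time stepping and contact enforcement against a 10⁻³ cm floor gap.
Coupling is staggered: rebuild channel → solve flow → load nodes with the
sectional pressures → advance the wall. Defaults (mass 0.15 g/cm²,
stiffness 10⁵ dyn/cm³, damping 8 dyn·s/cm³, coupling 50 dyn/cm, 9 × 15
nodes, dt = 10⁻⁵ s) self-oscillate near 130–140 Hz at Ps = 1 kPa, settling
to a steady limit cycle within ~0.15 s; runs default to 0.2 s so the last
cycles are converged (the fast profile keeps the full duration — shortening
it would sample the transient). A run is classified as
sustained when the last four flow-rate peaks agree within 5 % and the
cyclic swing exceeds 20 % of the mean flow (the latter rejects a decayed
equilibrium with numerical ripple). Cycle extraction samples the interval
between the last two flow-rate peaks uniformly (92 instants by default)
and feeds the same training-set builder as the synthetic corpus.

The three-layer viscoelastic tissue description of continuum vocal-fold
models (cover/ligament/body moduli) is shipped as documented metadata
(`glottiflow.fsi.VOCAL_FOLD_LAYERS`) for reference only; the simplified
wall does not resolve layers.

## Numerical choices and problem sizes

- Contact-averaged gaps may be exactly zero; the discretization's area
  floor (10⁻⁴ cm²), not the shape module, guards the solver.
- Boundary feature rows use one-sided differences; ΔS\* at the inlet is 0.
- The flow-rate expression requires a positive bracketed denominator;
  profiles violating it raise a no-real-solution error, and an FSI step
  whose self-consistent loop fails is carried with the previous resistance.
- Inside the self-consistent loop, predicted profiles whose *total* loss is
  negative (out-of-distribution extrapolation of the regressor) have their
  negative entries rescaled so the total is zero: a dissipative channel
  cannot net-outflow the inviscid one, and the bound keeps the iteration's
  flow rate at or below the inviscid value.
- Training runs in float32 with flush-to-zero guards on the optimizer
  moments and parameters: dead ReLU units otherwise decay weights into the
  subnormal range, which silently degrades CPU throughput several-fold.
- The test suite and acceptance script use the full 64-shape corpus at
  n = 128 with 2000-epoch trainings, and 0.16 s fast-profile FSI runs at
  n = 32 with a 0.03 cm solid grid; these sizes keep a complete run on one
  CPU in the tens of minutes while leaving every contract at full strength.

## Limitations

- The flow model is quasi-steady: no inertive (unsteady) term, no acoustic
  loading, and planar sections normal to the flow axis (no curved
  centerline).
- The surrogate ground truth is not CFD; passing tests demonstrate that the
  architecture recovers a deterministic geometry-to-resistance mapping and
  that the learned resistance strictly improves flow/pressure predictions
  over the inviscid model on held-out shapes — not that the specific MAE
  values transfer to Navier–Stokes corpora.
- The surrogate's separation term divides the diameter slope by the station
  spacing, so on strongly divergent shapes the resistance targets span
  roughly 10⁻⁴–10³ at n = 128. Heavy dropout on the small hidden layers
  biases the deterministic-inference network toward an ensemble mean that
  underfits the sharp separation peaks: with the default 20 % dropout the
  held-out relative MAE on this corpus plateaus well above what the same
  architecture reaches with dropout disabled. The dropout rate is
  config-exposed; users retargeting the model at reference data with
  mild-ranged resistance values (where dropout's regularization is actually
  useful) should keep the default, while users fitting wide-range surrogate
  laws may prefer to reduce it.
- The wall model is lateral-only with uniform per-area properties; it
  produces self-sustained oscillation and a mucosal-wave-like phase lag but
  no layered tissue stresses and no left–right asymmetry (the
  architecture allows per-side parameters later).
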