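# Methods

## Respiratory-system model

Each virtual patient is a linear single-compartment respiratory system:
compliance C<sub>rs</sub> (ml/cmH₂O), separate inspiratory and
expiratory resistances R<sub>insp</sub>, R<sub>exp</sub> (cmH₂O·s/l),
giving an inspiratory time constant τ<sub>i</sub> = R<sub>insp</sub>·C<sub>rs</sub>
and the expiratory time constant RC<sub>e</sub> = R<sub>exp</sub>·C<sub>rs</sub>.
Pressure-controlled breaths apply an ideal square airway-pressure wave
(PEEP → PEEP + ΔP; an optional linear rise is available for robustness
checks but defaults to 0). Inflation and passive exhalation follow the
exponential solutions of the linear ODE; the per-breath end-expiratory
volume map is affine, so the cyclic steady state is computed in closed
form, and gas trapped by short expiratory times (auto-PEEP) is captured
exactly. Waveforms are emitted on a fixed 0.01-s grid (the 100-Hz
resolution of ventilator recordings); metrics must not assume anything
finer. The simulator is fully deterministic — randomness exists only in
the cohort generator and the trial randomization.

Nonlinear compliance, recruitment/derecruitment, oxygenation, and
spontaneous (triggered) breaths are out of scope.

## Rate selection

Both adaptive rules are solved in coherent units (breaths/s, ml/s, s);
a damped fixed-point iteration (λ = 0.5, start 15 /min, tolerance 1e-9
breaths/s, ≤ 500 iterations) with a bracketed root-finding fallback
returns the rate, which is clamped to [4, 60] breaths/min and flagged
if the clamp engages (device safety envelopes beyond this are not
modelled). The printed form of the power-minimisation equation is
typographically ambiguous in its exponent grouping; the implemented
form, RR = V̇E/(2·VDA)·(1 − x/expm1(x)) with x = 1/(2·RR·RCe), is the
one derived from the square-wave power objective (work per breath =
ΔP·V<sub>T</sub>, ΔP = V<sub>T</sub>/(C·(1 − e^(−Ti/RCe))),
Ti = half cycle, alveolar ventilation held fixed), and the brute-force
power-curve argmin agrees with its fixed point to within 0.01 /min
across V̇<sub>E</sub> ∈ [5, 15] l/min × RC<sub>e</sub> ∈ [0.3, 1.5] s ×
VD<sub>A</sub> ∈ [110, 220] ml — which is the strongest evidence that
this resolution is correct.

A note on the large-RC<sub>e</sub> asymptote: the leading-order
asymptote √(V̇E/(8·VDA·RCe)) is approached slowly; at RC<sub>e</sub> =
50 s (cohort-baseline V̇<sub>E</sub> and VD<sub>A</sub>) the fixed
point still sits ≈ 1.8% below it, the next-order term of the expansion
(x/12 ≈ 0.018). Agreement tightens only for far larger RC<sub>e</sub>.

## Measurement conventions

* Static driving pressure ΔP<sub>stat</sub>: plateau (mean airway
  pressure over the final 0.5 s of a ≥ 2-s zero-flow end-inspiratory
  occlusion) minus **set** PEEP. With trapped gas the value therefore
  contains the intrinsic PEEP — deliberately, because that is what the
  bedside convention measures; the trapped volume is available on the
  waveform as a diagnostic. The occlusion maneuver breath prolongs its
  own cycle so that the regular expiratory time is preserved (a 2.5-s
  hold cannot fit inside a high-rate cycle otherwise).
* Static compliance: expired V<sub>T</sub> / ΔP<sub>stat</sub>.
* Mechanical power: per breath, the trapezoidal integral of *absolute*
  airway pressure over inspired volume (PEEP included), averaged over
  breaths and multiplied by the measured rate. The above-PEEP product
  RR·ΔP·V<sub>T</sub> (the AVM2 objective) is kept distinct in the
  mechanics module.
* Expiratory time constant: least-squares slope of expired
  volume-remaining against flow over the 75% → 25% expired-volume
  window, with intercept (so trapped volume does not bias the slope);
  exact on the generating model.
* Dead space: the modified Bohr form VD = V<sub>T</sub>·(PaCO₂ −
  P<sub>E</sub>CO₂)/PaCO₂. In the trial engine the mixed-expired
  tension P<sub>E</sub>CO₂ is known exactly from CO₂ mass balance
  (P<sub>E</sub>CO₂ = 0.863·V̇CO₂/V̇<sub>E</sub>), which makes the
  alveolar-ventilation endpoint V̇<sub>A</sub> = 0.863·V̇CO₂/PaCO₂ — a
  quantity that equalises between phases whenever the etCO₂ protocol
  holds PaCO₂ at baseline, exactly as a capnography-based measurement
  would. An end-tidal surrogate (PaCO₂ − fixed gradient) is used for
  the *control* signal instead, because that is what a bedside
  capnometer displays; using it also for the V̇<sub>A</sub> endpoint
  would make V̇<sub>A</sub> proportional to V̇<sub>E</sub> and produce
  a spurious between-mode difference.
* Endpoints are averaged over complete breaths in the final 300-s
  window of each phase. Phases are simulated at cyclic steady state
  (≈ 80–110 breaths), which makes the final window representative of a
  full hour without simulating one.

## Closed-loop protocol

For each phase, the controller selects RR from the mode's equation
(using the compliance and time constant *measured* from a short
baseline recording with one occlusion, so estimator error propagates; a
perfect-measurement switch exists for unit tests), sets
V<sub>T</sub> = V̇<sub>E</sub>/RR, the inspiratory time from the mode's
timing rule, and the pressure that delivers the target volume; a
breath-by-breath pressure adaptation (exact in one step on a linear
system) then holds the delivered V<sub>T</sub> on target. Timing rules:
AVM2 splits the cycle 1:1 (the assumption under which its equation is
derived); AVM targets I:E = 1:2, shortening inspiration when three
expiratory time constants would not fit, with a floor at 20% of the
cycle. The published AVM behaviour is only characterised by its
observed I:E of 1:2.0 ± 0.5, so this rule is an explicit, configurable
stand-in calibrated to that observation.

The %MinVol loop starts at 100% of the baseline minute ventilation and
applies the protocol's multiplicative 10% steps whenever end-tidal CO₂
leaves the baseline ± 2 mmHg corridor. Because the etCO₂ response gain
((PaCO₂/etCO₂)·(V̇E/V̇A)) can exceed 2, a fixed 10% step can limit-cycle;
the loop therefore halves its step whenever the error changes sign, and
converges to within 0.5 mmHg (a quarter of the protocol band) so that
both of a patient's phases settle to near-identical alveolar
ventilation. Convergence takes ≤ 9 adjustments across all tested
cohorts. The %MinVol range is bounded to [25, 350]%.

## Synthetic cohort

Truncated-normal marginals calibrated to the study population
(compliance 55 ± 13 ml/cmH₂O, ARDS subgroup 47.3 ± 9.1; RC<sub>e</sub>
0.82 ± 0.22 s truncated at the 1.5-s eligibility bound, ARDS
0.73 ± 0.18; PBW 74 ± 10 kg; baseline V<sub>T</sub> 7.5 ± 0.8 ml/kg at
15.3 ± 1.8 /min; PaCO₂ 43 ± 6 mmHg; discrete PEEP with median 8, IQR
8–10 cmH₂O). Compliance and RC<sub>e</sub> are coupled through a
Gaussian copula with latent correlation 0.4; the arterial–end-tidal CO₂
difference is 5 ± 3 mmHg (truncated [0, 15]), a typical capnometric
gradient. V̇CO₂ is derived per patient so that the baseline ventilation
reproduces the sampled PaCO₂ under the steady-state alveolar
ventilation equation — every patient is self-consistent by
construction. Draws violating any invariant (eligibility, expiratory
resistance within [3, 45] cmH₂O·s/l, V̇CO₂ within [80, 500] ml/min) are
rejected and resampled.

What the generator does *not* emulate: within-patient physiological
drift between phases (the simulator is deterministic, so paired
differences carry no biological noise and p-values are far smaller
than clinical data would give), nonlinear mechanics, and any joint
distribution structure beyond the single compliance–time-constant
coupling. Passing trial-level tests therefore demonstrates the
mechanics of the mode contrast, not the sampling variability of a real
trial.

## Statistics

Per endpoint, the D'Agostino–Pearson K² omnibus test (n ≥ 8) on the
paired differences decides between the paired two-sided t test and the
Wilcoxon matched-pairs test (exact null for n ≤ 25 after dropping zero
differences, normal approximation with continuity correction above);
smaller samples default to Wilcoxon. No multiple-testing correction is
applied, matching the original analysis plan. The sample-size routine
inverts the exact noncentral-t power function of the paired t test
(smallest n with power ≥ target), which yields n = 20 for the published
design (Δ = 1 ml/kg, SD 1.5 ml/kg, 80% power, α = 0.05) where the
normal approximation would give 18. At extreme noncentrality, where
scipy's noncentral-t CDF loses precision, the routine falls back to the
normal approximation; note that with a huge effect the answer is n = 3,
not 2, because a t test with one degree of freedom has little power no
matter the effect.

## Known model–study divergences

The equations separate the two modes' rates more strongly than the
commercial devices do in practice (at cohort-typical inputs:
13.6 vs 18.1 /min here, against an observed separation closer to
13 vs 16 /min). Two consequences follow, both deliberate properties of
the faithful implementation rather than bugs:

1. **Total mechanical power.** The square-wave saving in the above-PEEP
   power term (≈ −0.4 J/min after the intrinsic-PEEP penalty of I:E 1:1
   at ≈ 2 expiratory time constants) is outweighed by the extra
   dead-space ventilation at PEEP (≈ +0.8 J/min at PEEP ≈ 8.5 and
   ≈ +6 /min of rate), so the *total* mechanical power under power
   minimisation comes out marginally higher, not lower. A smaller rate
   separation — as observed clinically — flips this balance.
2. **V<sub>T</sub>–compliance correlation.** The per-phase *measured*
   compliance under AVM2 is depressed by intrinsic PEEP in proportion
   to RC<sub>e</sub>, which suppresses (and at this rate separation
   reverses) the correlation contrast when computed against the
   measured value. Computed against the patient's true compliance, the
   tidal volume scales with lung size consistently more strongly under
   power minimisation, as expected from the larger RC<sub>e</sub>
   elasticity of its rate equation. Both correlations are reported on
   the trial result.

## Numerical choices

Fixed-point tolerance 1e-9 breaths/s; power-curve grid 0.01 /min;
cmH₂O·ml → J conversion 9.80665e-5 exactly; occlusion plateau read as
the mean of the final 0.5 s of the hold (default hold 2.5 s, the
midpoint of the 2–3-s convention); trapezoidal integration on the
100-Hz grid everywhere, no resampling; volume channels store the exact
analytic solution, so flow–volume consistency holds segment-wise
(trapezoid quadrature across the valve-switch discontinuity is a
property of the quadrature, not the signals). Degenerate inputs
(all-zero paired differences, zero-variance correlations, missing
occlusions, streams shorter than the averaging window) raise typed
errors or flagged degenerate results rather than NaNs.
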