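# Methods

This note documents the models, parameter choices and numerical decisions
behind `resuscloop`, and what the synthetic test conditions do and do not
show about live subjects.

## The control problem

A hemorrhaged subject has lost circulating volume; mean arterial pressure
(MAP) falls with it, and perfusion failure accumulates lactate. Fluid
resuscitation restores volume — autologous whole blood (WB) first, capped
at 1 L, then lactated Ringer's (LR) — and the controller's job is to bring
MAP to a target of min(pre-hemorrhage baseline, 65) mmHg and hold it for
60 minutes, receiving MAP only as one non-invasive reading per 60 s,
upsampled to the 15-s control cadence.

## Synthetic subject (plant)

The plant is a lumped model: MAP is a memoryless saturating function of
circulating volume V,

    MAP(V) = P_floor + (P_max − P_floor) · (1 − exp(−(V − V_floor)/V_s)),

calibrated so MAP(V₀) equals the drawn baseline and dMAP/dV at V₀ equals
the drawn volume-responsiveness slope. The curve steepens as volume falls,
so small boluses in deep shock recover pressure quickly — the qualitative
behavior seen in animals. A `linear` plant variant (exact constant dP/dV,
clipped) is provided for controller oracles.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| baseline MAP | U[55, 85] mmHg | the spread observed across study animals |
| slope at baseline | U[0.065, 0.095] mmHg/mL | chosen a priori so a 100-mL bolus from the 35-mmHg hold restores ≈ 14 mmHg and closed-loop rise times land at ≈ 2–3 min, the range reported in vivo |
| P_max | baseline + 20 mmHg | modest headroom above baseline; saturation bounds overshoot |
| P_floor | 20 mmHg | deep-shock pressure floor |
| blood volume | 2800 mL | ≈ 40-kg swine at 70 mL/kg |
| LR retention | 0.3 | MAP is far less responsive to crystalloid than to whole blood; exact fraction unreported, configurable |
| observation noise | 1.5 mmHg SD, Gaussian, seeded | visible wobble without drowning the signal |
| lactate | rate 0.0075 mmol/L/min per mmHg below 45 mmHg; clearance 0.02/min toward 0.8 | only the ≥ 4 mmol/L gate is prescribed; these kinetics make default subjects cross 4 mmol/L ≈ 40 min into the 35-mmHg hold, inside the 90-min cap |

One deliberate consequence of this calibration: withdrawal volumes to
reach 35 mmHg are ~300–400 mL rather than the ~1 L a 40-kg swine loses.
The subject is *scaled down* in volume so that pressure dynamics (rise
times, pace tracking) match the reported behavior at the prescribed
6 mmHg/min pace. Metrics defined on pressure and time are comparable;
absolute fluid volumes are not.

**Known artifact — no redistribution.** The plant conserves volume
exactly: there is no capillary leak, urine output or fluid redistribution.
Any overshoot past the target therefore persists for the rest of the hour
instead of washing out, and noisy estimates that spuriously re-trigger
infusion ratchet MAP upward a few mmHg over the hold. This inflates MDPE,
target overshoot and area-above-target, and deflates the ±5-mmHg
effectiveness metric relative to live subjects. Resuscitation
effectiveness (no penalty above target), rise time and wobble are
unaffected, which is why those carry the closed-loop claims here.

## AutoBleed

The published description of the hemorrhage software is behavioral (step
targets, holds, withdraw/reinfuse regulation, CPDA-1 mixing, termination
rules); its decision table is not public. The reimplementation is a
proportional controller (gain 40 mL/min per mmHg, pump cap 100 mL/min,
1-mmHg deadband) over the step ladder 75/65/55/45/35 mmHg, first step
strictly below baseline, 10-min holds entered once within ±2 mmHg of the
step target. It reproduces the observable input–output behavior, not the
original rules.

## Controllers

**ARC.** The regression window is the 5 most recent (V, P) points (the
original updates "each iteration" but does not state a window; 5 balances
adaptation against noise amplification). Safety values not printed in the
source material and therefore reconstructed: slope floor 0.01 mmHg/mL,
rate cap 250 mL/min (mirrors the DFL maximum), 1-mmHg re-engagement
hysteresis below target to avoid rate chatter. Only volume-advancing
observations enter the P–V history — zero-ΔV points carry no slope
information and would make the windowed fit singular. Cumulative volume is
the commanded volume (ideal pump).

**DFL.** Zero-order Sugeno, product t-norm, strength-weighted average.
The membership breakpoints and the 20-rule table are **reconstructions**
of the qualitative control surface (only the endpoints — Off = 0,
High = 250 mL/min, four PE sets, five dPE sets — are published):

* PE: VeryLow (−∞, −∞, 0.55, 0.70), Low (0.55, 0.75, 0.90) triangle,
  NearSet (0.82, 0.93, 1.0) triangle, Set (0.95, 1.0, +∞).
* dPE (ratio/min): breakpoints at ±0.05 and ±0.25, noChange triangular
  about 0, shoulders to ±∞.
* Rules: Set row all Off; consequents increase monotonically with deficit
  and with how fast pressure is dropping (VeryLow×dropFast = High, …,
  NearSet×riseFast = Off); intermediate levels 0.25/0.5/0.75.

Everything is configurable; tests that depend on these defaults assert
bands, orderings and structural properties (boundedness, continuity,
monotonicity in PE), not exact interior values. With intermittent input
the DFL starts with the same 100-mL/1-min bolus as the ARC (configurable
off, reproducing the one study subject resuscitated without it).

## Intermittent input and upsampling

NIBP emulation samples the arterial trace instantaneously once per 60 s
(no cuff inflation delay — the study likewise derived its intermittent
feed by downsampling the invasive line). The upsampler fits a line
through the two most recent **valid** readings and evaluates it at the
four future 15-s instants, re-anchoring at every new reading; with fewer
than two readings it passes the raw reading through (startup behavior).
Invalid (zero) readings are skipped, not extrapolated from. An optional
logistic dropout model (failure probability rising as MAP falls) exists
solely to exercise the reliability metric. Extrapolated estimates are not
clamped by default; an optional [0, 200] mmHg clamp is available.

A property worth stating precisely: against a sample-and-hold feed,
linear extrapolation is *better* on smooth monotone signals (first-order
vs zeroth-order accuracy) and *worse* wherever the slope reverses between
samples or the readings are noisy (the projected value 2r₂ − r₁ carries
5× a single reading's noise variance). The degradation suite and its
tests demonstrate the upsampled feed losing to the plain hold under
those two mechanisms, which is the regime the in-vivo comparison
reported.

## Metrics

Varvel-style: PE = (MAP − target)/target × 100; MDPE = median(PE);
wobble = median(|PE − MDPE|). Effectiveness = % of samples within
±5 mmHg of target; resuscitation effectiveness = % at or above
target − 5 mmHg. Areas use the rectangle rule at the trace's native
sampling; the metric window is the full 60-min resuscitation including
the rise, with the clock restarted at zero. Choices the source leaves
open, made here: target overshoot = max excursion above target;
infusion-rate variability = time-weighted SD of commanded rates; R² =
squared Pearson correlation; accuracy band boundary inclusive
(|diff| ≤ 10 mmHg, with 1e-9 slack for float round-off); agreement joins
pair nearest samples within half the coarser period; MDPE/wobble use the
trace's native sampling.

## PPG pipeline

Preprocessing follows the stated recipe — decimate to 100 Hz, 2nd-order
Butterworth band-pass 0.5–10 Hz, replace samples beyond 1.5×IQR by linear
interpolation — with two documented choices where the recipe is silent:
filtering is zero-phase (forward–backward) so derivative features carry
no phase lag, and derivatives are successive central differences
(`numpy.gradient`, one-sided at edges) computed after downsampling.
Segments are non-overlapping 20-s windows (2000 samples × 5 rows);
the label is the mean MAP over the window.

The regressor is a random-convolution-kernel model (ROCKET family): a
seeded bank of 150 random 1-D kernels (lengths 7/9/11, dilations 2⁰–2⁴
via strided input, random channel), pooled to max and
proportion-of-positive features, plus per-channel summary statistics,
feeding a standardized cross-validated ridge readout. It is a compact,
CPU-only sequence regressor with the same 5×2000 → one-MAP contract as a
deep sequence model, implemented as a scikit-learn estimator. LOSO folds
hold one subject out for test and one (rotating) for validation, leaving
≈ 2/3 of subjects for training.

The synthetic PPG couples heart rate (↓MAP ⇒ ↑HR), pulse amplitude
(↑MAP ⇒ ↑amplitude) and dicrotic-notch position monotonically to the
instantaneous MAP, with additive noise well below the amplitude contrast.
Passing LOSO tests on this data shows the pipeline is sound end to end —
leakage-free splitting, informative features, working regression. It does
**not** show that real swine PPG carries an equally strong MAP signal;
the in-vivo per-subject accuracies ranged from poor to excellent, and no
claim about them is reproduced here.

## Problem sizes and determinism

The inner simulation step is 1 s with zero-order-hold pump rates;
controller ticks every 15 s; a full protocol is ≈ 2.5 simulated hours and
runs in well under a second. The acceptance script uses 5 subjects per
controller; PPG evaluation uses 4–6 synthetic subjects at 120–240 s each
(6–12 segments per subject), which is ample for the margin being
demonstrated (LOSO RMSE ≈ 1–2 mmHg vs baseline ≈ 13–14 mmHg). Every
stochastic component (subject draws, noise, dropout, kernel banks, MAP
profiles) is seeded; identical seeds give byte-identical runs.

## Limitations

* The plant has no heart-rate/cardiac-output state, no baroreflex, no
  fluid redistribution (see the ratchet artifact above), and lactate
  kinetics are a construction around the single prescribed 4 mmol/L gate.
* DFL memberships/rules and ARC safety limits are reconstructions;
  conclusions that depend on their exact interior values should not be
  drawn from the defaults.
* The subject is volume-scaled; absolute fluid totals are not comparable
  to a 40-kg animal.
* CPDA-1 is bookkeeping only (volume and ratio); no coagulation or
  calcium chemistry is modeled.
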