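# Methods

## Model

A breath's PV loop is treated as a hysteresis cycle: the inspiratory and
expiratory limbs (split at the volume maximum, first sample on ties) are each
approximated by an *r*-segment piecewise linear regression of pressure on
volume. Segments are contiguous runs of samples in traversal order, so the
model remains well defined even when volume is locally non-monotone within a
limb (as in a double-triggered breath). Each segment's slope is a local
elastance (cmH₂O/L); the breakpoints are reported as the volume, fitted
pressure and sample index at the start of the following segment.

A normal half-cycle is modelled as two segments (the lower/upper inflection
of the quasi-static PV relationship); asynchronous distortions add segments
with characteristic sign patterns, which is what the typing rules key on.

## Breakpoint search

For fixed *r*, segment costs (per-segment OLS residuals) are computed for all
`O(N²)` index intervals from prefix sums, and the optimal breakpoints are
found by dynamic programming — exactly equivalent to enumerating every
breakpoint combination with at least `min_segment_points` samples per
segment (default 5, i.e. 50 ms at 100 Hz). There is no candidate decimation
by default: the search is exact at these problem sizes (N ≲ 600). DP
tie-breaks resolve to the earliest breakpoints in traversal order. The final
fit re-estimates each segment with centred arithmetic, so noise-free polyline
data yields RSSE at the level of float rounding rather than the cancellation
error of the fast prefix formulas.

## Model-order selection

The cascade starts at r = 2 and tests r against r+1 via
`F(r+1|r) = (RSSE_r − RSSE_{r+1}) / σ²`, stopping at the first acceptance or
at `r_max` (default 5, the segment count of the double-trigger signature).
Both RSSE values are global minima over the breakpoint grid.

Because the improvement is maximised over every breakpoint configuration, it
behaves as a sup-type statistic, not a fixed 2-parameter F increment: using a
plain F quantile at α would escalate far more than α of normal half-cycles.
The default critical value is therefore a Bonferroni-adjusted chi-square
quantile `χ²₂(1 − α/B)`, with `B` the number of breakpoint combinations
searched at the alternative. This is conservative (measured false-escalation
rate ≈ 0 at α = 0.01 versus the 3% design bound) while the archetype
signatures exceed it by orders of magnitude; the plain F quantile remains
available as `crit_method="f-quantile"`.

σ² is the mean over presumed-normal half-cycles of RSSE₂/(N−4) (two slopes
and two intercepts), floored at 1e-6 cmH₂O² so noise-free synthetic data
cannot zero the denominator. The end-to-end pipeline warm-starts σ² from the
first 20 breaths of a record using the **median** of the per-half values —
the warm-up window may contain asynchronous breaths whose inflated residuals
would contaminate a mean — and then maintains a rolling mean over the last 50
half-cycles whose selected model was two-segment on both limbs, the running
operational definition of "non-asynchronous".

## Typing rules

Phase assignment is fixed: fa, rt, dc, dt inspect the inspiratory fit; pc, ie
the expiratory fit; at the whole loop. Precedence for the primary label is
dt, dc, fa, rt, pc, ie, at; all matching rules are retained as evidence.
Details worth noting:

- **fa vs dc** share the +,−,+,+ pattern; dc additionally requires the
  end-inspiration spike k₄ > 2k₃ and fa explicitly excludes it, so the two
  are disjoint and each breath counts once.
- **pc vs ie** share phase and differ in where the notch sits: pc's first
  breakpoint lies within the first half of the exhaled volume
  (V_N0 − V_N1 < V_T/2), ie's second breakpoint beyond it
  (V_N0 − V_N2 > V_T/2), with V_N0 the start-of-expiration volume (= V_T).
- **dt** compares the fitted pressure at the third breakpoint (the trigger
  point of the stacked cycle) against PEEP, estimated per breath as the
  pressure at the breath's first sample — robust and available without
  look-back across breaths.
- **at**'s volume-gap threshold ε defaults to 0.1·V_T per breath (an absolute
  override is supported): no magnitude is dictated by the loop geometry
  itself, and a relative gap scales naturally across tidal volumes.
- A rule whose required half-cycle was unfittable is false with an
  "unfittable" evidence marker, never an exception; a 3-segment relaxed fa
  variant (clear early sag without the fourth segment) sits behind an
  off-by-default flag.

## Synthetic data generator

The generator emulates volume-controlled breaths of a single-compartment
respiratory system (equation of motion
`P = E(V)·V + R·Q + PEEP − P_mus`) with optional two-regime elastance (a
lower-inflection knee, default 30/18 cmH₂O/L with the knee at 35% of V_T),
square inspiratory flow, and an expiratory limb drawn as a relaxation
polyline from the end-inspiratory pressure down to PEEP over an exponential
volume decay. Defaults: V_T 0.5 L, PEEP 5 cmH₂O, R 10 cmH₂O·s/L, 15
breaths/min, I:E 1:2, 100 Hz, Gaussian measurement noise 0.2 cmH₂O and
0.01 L/s. A pressure-controlled preset exists for normal/leak breaths.

Design choices that matter:

- **Exact polyline loops.** Breaths are synthesized so the noise-free PV
  loop is an exact piecewise-linear curve. Effort distortions are piecewise
  linear in the volume coordinate (triangular or trapezoidal muscle-pressure
  bumps, polyline expiratory notches) rather than smooth raised-cosine
  bumps: a smooth bump lies outside the piecewise-linear model class, so the
  *selected* segment count would depend on the noise level instead of on the
  archetype, making ground-truth labels meaningless. Likewise the expiratory
  limb connects continuously to the end-inspiratory pressure: a strict
  exhalation-valve model inserts a near-vertical pressure drop at cycling
  whose samples would force extra segments on every breath, normal or not.
  These are deliberate departures from strict circuit dynamics; the
  generator's purpose is labelled archetypes with guaranteed signatures, not
  device-level realism.
- **Per-archetype mechanics presets.** Sag types (fa, dc), notch types
  (pc, ie) and the stacked breath (dt) use a single-regime elastance
  (25 cmH₂O/L) so the distortion, not the knee, owns the extra segments;
  normal, rt and at breaths keep the knee (rt needs the two positive
  segments before its late dip; for normal/at the knee pins the two-segment
  breakpoint, making the fitted slopes robust under noise).
- **dt realization.** One merged breath: full first insufflation, incomplete
  expiration to ~62% of V_T, a short sub-PEEP trigger dip, then a second
  insufflation to a stacked peak — the inspiratory half (up to the global
  volume maximum) carries exactly five segments.
- **at realization.** A circuit leak is expressed in the measured signals:
  the expiratory volume decays to `leak_rate × T_e` instead of zero, so the
  end-expiratory volume gap equals the injected leak volume.
- **Flow/volume consistency.** Emitted flow is constructed so its
  trapezoidal integral reproduces the constructed volume exactly; the
  departure from the analytic derivative is an alternating ripple of order
  1e-4 L/s, far below the flow noise and the onset-detection threshold. This
  keeps the integrate-from-flow pipeline path exact on noise-free data.
- **Sequences.** Label counts follow the requested mix within ±1
  (largest-remainder allocation) and are shuffled by the seed; identical
  configuration and seed reproduce records and labels bit-for-bit. The
  default cohort mix is 5% of each of the seven types (35% asynchronous
  overall, within clinically reported ranges); a reverse-triggering/flow-
  asynchrony dominated mix (36%/15%) is shipped as the demo mix.

What the generator does **not** emulate: heterogeneous or multi-compartment
lungs, mode-specific trigger dynamics, drifting baselines, coughs and
artefacts, or the smooth, variable-magnitude distortions of real patient
effort. Passing tests on this generator therefore demonstrate correctness of
the fitting, selection and typing machinery under the stated loop model —
not clinical performance on ICU recordings, which varies with effort
magnitude and is known to degrade for low-magnitude pc/dc/ie distortions.

## Breath segmentation

Breath onset is a crossing of flow from ≤ threshold (0.01 L/s) to above it
sustained for ≥ 50 ms, with a volume gate: a candidate onset is rejected
while the volume since the previous onset still exceeds 50% of that breath's
running peak. The gate is what keeps a double-trigger's second insufflation
merged into a single breath while real onsets (volume near baseline) pass.
Volume is re-baselined to zero at each breath start, so circuit-leak drift
does not accumulate across breaths.

## Numerical choices and degenerate inputs

- Segment OLS on a vertical run (all volumes equal) flags the slope as
  undefined and scores residuals against the mean pressure; typing rules
  treat undefined slopes as failing every sign test.
- RSSE monotonicity in r holds whenever a segment of the best r-fit can be
  split (guaranteed for N ≥ 2·r·min_segment_points); the F-ratio clamps at
  zero if rounding produces a marginally negative improvement.
- Percentages are displayed half-up at one decimal; machine output keeps raw
  fractions. Sensitivity/specificity are reported as not-available when the
  relevant denominator is empty.
- Problem sizes in the shipped tests and acceptance script — 500-breath
  cohorts, 1000 half-cycle null runs, 24 breaths per amplitude-grid point —
  were chosen as the smallest sizes at which the binomial noise of the
  measured rates is well inside the asserted bounds.

## Known limitations

- The typing rules are exact signature matches on the selected model; real
  loops with atypical segment counts (e.g. a 3-segment flow asynchrony) are
  missed unless the relaxed flag is enabled.
- σ² calibration assumes some normal breaths exist in the record; a record
  that is asynchronous from the first breath inflates the warm-up median and
  lowers sensitivity until the rolling window fills.
- One primary label per breath: simultaneous inspiratory and expiratory
  asynchronies resolve by precedence, with the runner-up visible only in
  `matched_rules`.
- Asynchrony magnitude is not graded, only incidence and type.
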