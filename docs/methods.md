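# Methods

## Measurement model

The recording chain couples the extracellular voltage of a cell layer
into a current amplifier through the electrode–electrolyte interface.
The interface is the standard equivalent circuit of a planar metal
electrode: charge-transfer resistance R_D in parallel with the
Helmholtz–Gouy–Chapman double-layer capacitance C_D, in series with the
spreading resistance R_c of the electrolyte; leakage between sensing and
counter electrode is a seal impedance Z_seal that is assumed very large
(the package warns when Z_seal < 10·max(R_D, R_c), where the model's
high-seal approximation degrades).  A cell-layer voltage v_s(t) drives
the displacement current

    i_s(t) = C_D · dv_s/dt · (1 − e^{−(t−t₀)/τ}),   τ = C_D · (R_c R_D)/(R_c + R_D),

which a transimpedance amplifier converts to v_o(t) = −R_F·i_s(t).  τ is
implemented as the charging time of the parallel R_c‖R_D pair through
C_D — the combination that is dimensionally a time and consistent with
the circuit topology — and the charging factor is anchored at the start
of the supplied trace, the only defined onset for sampled data.  The
derivative is a central difference in the interior and one-sided at the
ends (second-order interior accuracy, no phase lag).

Defaults (all overridable): R_D = 10 MΩ, C_D = 1 µF, R_c = 10 kΩ,
R_F = 1 GΩ, Z_seal = 1 TΩ — representative of a mm²-scale Au electrode
recording pA-scale currents.  No published component values exist for
this chain; these set plausible scales and every derived statistic in
the package is independent of them.

## Synthetic recordings

No raw MEA recordings of this preparation are publicly deposited, so the
package ships a seeded generator whose defaults encode the published
signal statistics; it is first-class, tested code, and every analysis
result in the test suite is measured on its output.

* **Units and sampling.** Current traces are held in pA end to end (file
  formats, thresholds and reports all use pA; the circuit module
  converts internally).  Default sampling 1 kHz: the signal band is
  0.1–10 Hz and the shortest spikes are 30 ms wide, so 1 kHz is
  comfortably above the 10-samples-per-width floor the generator
  enforces.
* **Baseline.** White Gaussian noise; "peak-to-peak" for an unbounded
  distribution is defined as the 0.01–99.99 percentile span, scaled so
  that span equals `baseline_noise_pp_pa` (default 1 pA).  A 60-s
  medium-only trace then stays below 1 pA in peak magnitude.
* **Spike shape.** Gaussian lobes.  The drawn "width" is the full width
  of the lobe at the ±50 pA detection level (falling back to full width
  at half maximum for lobes under 100 pA, which makes the convention
  continuous at the changeover), so the detector's threshold-crossing
  width measures the same quantity the generator draws.
* **Asynchronous regime.** Poisson event times; |Normal(100, 25)| pA
  amplitudes; negative polarity with probability 0.7; widths log-uniform
  on [20, 214] ms, which places ≈80% of draws in the 30–200 ms band.
  The event rate (default 0.05 /s) has no single published value; it is
  set so the default two-regime simulation reproduces the reported ~10×
  synchronous/asynchronous count disparity, and it is not revisited.
* **Synchronous regime.** Biphasic events: a positive and a negative
  Gaussian lobe of equal magnitude (default ±150 pA) and equal width
  (log-uniform 50–300 ms), hence exactly charge-balanced.  Lobe-peak
  separation defaults to 0.3 s, or to the wave transit time
  diameter/speed when wave kinematics are supplied.  Inter-spike
  intervals are truncated-normal with centre 2.15 s, sd 0.6 s, clipped
  to [1, 10] s.  This calibration was chosen once to satisfy the two
  published constraints simultaneously: a realized mean ISI of ≈2.19 s
  (rate ≈0.46 Hz, i.e. "around 0.5 Hz") *and* a modal 1-s ISI bin at
  2–3 s.  A centre of exactly 2 s puts the centre on a bin edge — equal
  mass in the 1–2 s and 2–3 s bins, so the modal bin becomes a coin
  flip — and a wider sd inflates the realized mean through the left
  clip, dragging the rate visibly below 0.5 Hz.  The trade-off: with
  sd 0.6 s the generated ISI spread does not fill the full reported
  1–10 s range; the clip bounds still enforce its limits.
* **Wave kinematics.** For a circular electrode the diameter is
  2·√(area/π) (1.128 mm for 1 mm²); per-pair wave speed is diameter
  divided by lobe separation.  Loose "1 mm" conventions are supported by
  passing the diameter directly.
* **Inhibition protocol.** Three phases: pre (600 s), block (1200 s),
  post (600 s).  Pre and post draw from identical distributions but
  independent random sub-streams, so their expected rates agree.  The
  block phase carries baseline noise plus sporadic residual lobes drawn
  uniformly in [0.2, 0.8]×`residual_amplitude_pa` (default cap 5 pA);
  residual lobes are re-drawn rather than superposed so their sum cannot
  break the cap.
* **Bookkeeping.** Events superpose linearly (population signals add);
  overlapping supports are counted in `GroundTruth.overlap_count`, never
  dropped.  Every insertion is logged with time, amplitude, width,
  polarity, kind and regime, enabling detection scoring.

What the generator does **not** emulate: spatially resolved wave
propagation (one channel only), electrode drift and thermal artifacts,
1/f noise, amplitude variability of the synchronous lobes, and
cross-channel structure.  Passing tests therefore demonstrate that the
analysis chain is correct and well-calibrated on signals with the
published statistics — not that it is robust to every artifact of real
recordings.

## Spike detection and pairing

An event is one excursion beyond +threshold or below −threshold
(default ±50 pA, the published histogram cut).  Peak time is the
extremum sample (earliest wins ties); amplitude is the signed extremum;
width is the time between the excursion's two threshold crossings with
linear interpolation between samples — the only signal level the data
description names, hence the width convention.  Same-polarity peaks
closer than the refractory gap (default 50 ms, below the shortest
published ISI by an order of magnitude) merge, keeping the larger.

Biphasic classification is a greedy left-to-right pass: two adjacent
opposite-polarity events whose peaks lie within the pairing window
(default 2 s, covering the published 0.3–2 s separations) form one
biphasic spike; every event joins at most one pair.  No pairing
algorithm is published; greedy adjacent pairing is the simplest rule
consistent with the described morphology and is exercised against
exhaustive small cases in the tests.

**Counting convention:** a biphasic pair counts as *one* spike for
rates, ISIs and regime counts (the published ISI analysis treats a
biphasic spike as one event), while amplitude and width histograms
remain per lobe, preserving the signed ± amplitude distribution.

## Regime segmentation

The recording span is tiled into 30-s windows; a window is synchronous
when its pair-collapsed spike rate is ≥ 0.2 /s **and** the coefficient
of variation of its ISIs is ≤ 0.6 (windows with fewer than 3 spikes
cannot establish regularity and default to asynchronous); adjacent
same-label windows merge.  The cutoffs sit in the wide margin between
the two published regimes: quasi-periodic firing at ≈0.46 Hz has an ISI
CV of ≈0.27 under the default jitter, while sporadic activity at
0.05 /s fails the rate cutoff outright.  Segmentation by eye is the
published procedure; this rule is the package's operationalization.

## Inhibition quantification

Per-phase spike counts assign each event to the half-open phase interval
containing its peak (boundary events belong to the earlier phase).  The
fluctuation magnitude of a phase is the 99.5th percentile of
|i − median(i)| — robust, so one stray sample cannot defeat a few-pA
criterion, and invariant to constant offsets.  Decision rules: a block
is called when the during-phase count is ≤ 10% of the before count
("almost zero", which is unquantified in the source description) and the
during magnitude is ≤ 5 pA; recovery is called when the after count is
within ±50% of the before count ("close", likewise unquantified).  A
zero before-count makes the assessment undecidable and is flagged.  An
optional diagnostic reports the first 60-s window of the block phase
quieter than 5 pA as the block onset.

## Growth and viability arithmetic

Growth: per-day mean over replicate electrodes and S.E.M (sample sd/√n,
n = 8 by convention for this assay), normalized by the final-day mean
and reported to 4 decimals — the final day is exactly 1.  The
"normalized S.E.M" here is S.E.M divided by the final-day mean; other
definitions exist and published tables do not always state theirs.
MTT viability: 100 × condition mean / negative-control mean with the
control treated as fixed, S.E.M propagated from the condition
replicates, scale-invariant in absorbance units; conditions below 90%
are flagged cytotoxic.  Dilution: c = stock·V_added/(V_added+V_medium),
in µM.

## Numerical choices and degenerate inputs

Tolerances used by the test suite mirror the statistical power of the
chosen problem sizes: 600-s simulations (≈270 synchronous spikes) for
rate/amplitude recovery at 10–20%, ten 60-s baselines for the noise
bound, and 2400-s three-phase runs for the block/recovery calls; all of
it executes in seconds.  Ties at the detection extremum go to the
earliest sample.  Empty event lists yield a single asynchronous segment,
zero-count reports and all-zero histograms rather than errors; a wave
speed estimate without any biphasic pair returns an empty, flagged
result.  Non-finite samples, sub-3-sample traces, overlapping phase
annotations, non-positive physical parameters and unknown config keys
are hard errors.

## Known limitations

The detector is a plain threshold device: spikes under ±50 pA are
invisible by design, and coincident opposite-polarity events closer than
the pairing window can be mis-paired if one lobe of a true pair is
missed.  The segmentation cutoffs are tuned to the two published
regimes, not learned.  The circuit model is quasi-static and
single-channel; no frequency-domain impedance or crosstalk is modelled.
Dose–response (IC50) fitting is deliberately out of scope — the source
viability data show no measurable cytotoxicity to fit.
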