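# Methods

`cavmon` implements the computational chain of an ex vivo study of
HIFU-induced vessel rupture: quantification of passively detected
cavitation emissions, flow-based rupture labeling, ROC-based rupture
prediction, and a closed-loop subharmonic-feedback intensity controller.
The raw detector recordings of the original experiments are not publicly
deposited, so the pipeline is exercised end-to-end against a synthetic
signal generator; the statistics that *are* derivable from the published
measurement tables are reproduced exactly from the shipped fixtures.

## Spectral quantification

Each 0.5-s PCD record (10 MHz sampling in the reference protocol) is split
into non-overlapping rectangular-window segments; the default segment
length keeps the bin width at 2 kHz (5,000 samples at 10 MHz). The DFT is
taken per segment and squared magnitudes are averaged. The stored one-sided
spectrum uses the normalization `P[k] = |X[k]|² / N` with **no** one-sided
doubling, so a unit-amplitude bin-center sinusoid appears with peak value
`N/4`; `PowerSpectrum.total_energy()` applies the two-sided weights
(interior bins ×2) and recovers the mean per-segment energy exactly
(Parseval, checked to 1 part in 10⁶).

Band powers are plain sums of in-band bins (the DC bin is always excluded;
the preamplifier high-passes at 10 kHz in any case). Bands: low-frequency
10–30 kHz (boiling), broadband 0.3–1.1 MHz (inertial cavitation), and the
single bin nearest 1.65 MHz (stable cavitation; ties resolved to the lower
bin). Each record's band power is divided by the same band's power in a
pre-exposure noise reference processed identically, giving a per-cycle
dB-scaled SNR at 1-s cadence. Because the SNR is a ratio on a shared bin
grid, it is invariant to common rescaling of signal and reference, and the
(undoubled) one-sided convention cancels.

A note on bin width: segmenting 5·10⁶ samples at 10 MHz into 5,000-sample
segments yields 2-kHz bins arithmetically; the reference protocol describes
its resolution as 10 kHz. The segment length is a parameter, so either
reading can be reproduced; all defaults here use the arithmetic 2-kHz
binning.

## Rupture labeling

The flow-meter current is sampled at 1 Hz; samples before sonication start
define the baseline (fallback: first sample). Detection is the first sample
below 97% of baseline; the rupture instant is 8 s earlier (the measured
transit delay of the flow circuit). Cycles within the last `W` seconds
before the rupture instant (default `W` = 10 s) are `pre_rupture`; earlier
cycles, and all cycles of non-rupture trials, are `intact_vessel`; cycles at
or after the rupture instant are excluded from analysis. Emission and flow
clocks are aligned at 1-s precision, so timestamps are integer seconds.

## ROC analysis

Scores are the dB-scaled band SNR values (AUROC is invariant under the
monotone dB transform; the choice fixes the units of reported thresholds).
The decision rule is `score ≥ θ → positive` over all unique scores. AUROC
is computed by the Mann–Whitney rank identity (ties credited ½), its
standard error by the Hanley–McNeil formula, and significance against 0.5
by a normal test with a 95% normal CI — the standard toolkit of clinical
ROC analysis; the original report does not name its SE method. The
operating point is the threshold minimizing the Euclidean distance to
(FPR, TPR) = (0, 1), ties resolved toward the lower threshold; PPV/NPV come
from the implied confusion matrix. A post-hoc sweep recomputes AUROC for
pre-rupture windows of 1–20 s.

## Analog monitoring chain and feedback controller

The suppression-mode electronics are modeled stage by stage: a 2nd-order
Butterworth bandpass at 1.65 MHz with 10% fractional bandwidth (applied
zero-phase), the preamplifier high-pass (10 kHz, 12 dB/octave) and gain
(20,000), half-wave rectification `max(x, 0)`, a 1st-order low-pass at
1,063 Hz (classic envelope detector; only the cutoff of the original
demodulator is documented, so the canonical topology is used), and linear
resampling onto the 68.6-kHz ADC clock. The RMS of the envelope over each
insonation is the controller input. For an in-band tone of amplitude `A`
the settled envelope mean is `A·gain/π` (half-wave-rectified sinusoid),
which the tests verify to 1%.

The drive calibration is the six measured (mVpp, W, W/cm², MPa) conditions,
linearly interpolated in voltage between rows and extrapolated below the
lowest row with the small-signal law `P ∝ V²` anchored at
(250 mVpp, 20.28 W, 15,690 W/cm²). Inverting that law places the 9,117
W/cm² starting condition at ≈190.6 mVpp.

Controller rules, one decision per 1-s cycle: envelope RMS above threshold
→ drive −10 mVpp, counter reset; ten consecutive below-threshold cycles →
drive +10 mVpp (the increase step is not documented; symmetric with the
decrease by default, configurable), clamped so the mapped intensity never
exceeds the cap. The cap defaults to 21,980 W/cm² (the protocol text);
24,430 W/cm² (the flow-diagram caption) is available by configuration.
Controller-inactive exposures use a monotone ramp with the same
one-step-per-10-s cadence, which makes an active controller with an
unreachable threshold exactly equivalent to the inactive schedule. The
deployed threshold, 0.06 V_RMS, was derived by pushing labeled records
through the chain model, taking the ROC corner threshold of the RMS scores,
and subtracting 1.5× the chain's RMS noise level; `derive_threshold`
implements exactly this rule (floored at zero), and the synthetic
derivation lands near the same value (≈0.05 V_RMS at default generator
scale).

## Synthetic data generator

Each record is the sum of a white Gaussian noise floor (RMS 10 µV), band-
limited Gaussian noise in the low-frequency and broadband bands (2nd-order
Butterworth-shaped, normalized to exact RMS), and a 1.65-MHz tone, with RMS
class amplitudes

    A_c(t, I) = (base_c + growth_c · t) · (I / I_ref)^κ  +  B·e^(−t/τ_b),

where `I_ref` = 20,570 W/cm², κ = 2, and the burst term (B = 2 µV,
τ_b = 4 s) mimics residual gas bubbles eliminated early in the exposure.
Base amplitudes (6.3, 24, 0.5 µV for low-frequency/broadband/subharmonic)
set band SNRs near 16, 12, and 2 dB at 2-kHz bins; growth rates (0.01,
0.12, 0.3 µV/s) make the subharmonic the steepest riser relative to its
base and the low-frequency band nearly flat, reflecting the observed
predictiveness ordering.

The latent vessel accumulates a cavitation dose — the sustained (non-burst)
subharmonic-plus-broadband amplitude integrated over on-time — and ruptures
when the dose first reaches a per-trial threshold drawn once from
LogNormal(ln 1.9·10⁻³, 0.4). A second per-trial log-normal factor (log-sd
0.6, median 1) scales every growth rate; because the same amplitudes drive
the dose, slow-growing vessels both emit less and survive longer. This
shared-cause structure is essential: without it, long-surviving trials
accumulate large late emissions labeled "intact" and the band ordering
cannot be recovered. No acoustic field or bubble-dynamics simulation is
attempted; the model is phenomenological.

The flow trace fluctuates uniformly within ±1% of a 10-mA baseline; after a
rupture the current declines deterministically, engineered so the first
sample below the 97% line falls exactly 8 s after the rupture instant for
every seed (the fluctuation bound, shoulder slope, and post-lag drop are
mutually arranged so neither false-early nor late detection can occur).

Determinism: one seeded generator per trial with a fixed draw order
(rupture threshold, growth factor, noise reference, per-cycle record draws,
flow trace). Identical seeds give bit-identical trials within one
installation; across implementations the seeds are portable only at the
statistical level.

### What the generator does and does not emulate

Calibrated against the qualitative behavior of the real experiments:
emission growth until rupture, initial bursts, rupture times of roughly
13–180 s (median ≈ 50 s) at 15,690–24,430 W/cm², recovered AUROCs near
0.84/0.73/0.59 (subharmonic/broadband/low-frequency) versus the reported
0.757/0.729/0.657, and a controller threshold near 0.06 V_RMS. It does not
emulate: tissue heterogeneity beyond one scalar growth factor, the
non-uniform PCD frequency response (band SNRs are therefore comparable here
though they were not in the real apparatus), ultraharmonics, or censoring
at prediction-scale intensities (the synthetic hazard almost always
ruptures within 300 s, whereas 3 of 18 real trials did not). Passing
recovery tests therefore demonstrate pipeline correctness under a plausible
emission model, not clinical performance.

## Problem sizes and numerical choices

Full protocol scale (0.5-s records at 10 MHz, 300 cycles) is supported but
not used by default in simulation studies. The desk scale is 4-MHz sampling
(still well above the 3.3-MHz Nyquist requirement for the subharmonic) with
0.05-s records for closed-loop runs and 0.01–0.02-s records for the
Monte-Carlo prediction studies; segment length scales to keep 2-kHz bins.
The shipped studies use 50 prediction replicates of the 18 measured
exposure conditions and 50 suppression pairs. Degenerate inputs raise
explicit errors (single-class ROC, zero noise-band energy, empty envelopes,
zero flow baseline); the exact Wilcoxon enumeration (Pratt zero handling:
zeros ranked jointly, then dropped — the only convention consistent with
the published T₋ = 8 on the paired rupture times, where one censored pair
has zero difference) is used up to 15 non-zero differences, with a
tie-corrected, continuity-corrected normal approximation above.
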