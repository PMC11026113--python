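# Methods

This note documents the models behind `dodsfx`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter.

## Apparent-cell scaling model

Indexing reports a unit cell consistent with the recorded spot positions
and the *assumed* photon energy E and camera length D. With Bragg angles
fixed by the spots, the apparent cell lengths scale as

    observed = true · (E_true / E_assumed) · (D_assumed / D_true),

in the small-angle approximation; angles are unaffected except by noise.
This single relation underpins everything: the chirp appears as a cell
drift because E_true varies per pulse while E_assumed is constant, and
re-assuming a corrected energy E′ rescales a frame's cell by
E_assumed / E′. The correction applied by `apply_schedule` therefore
multiplies cell lengths by assumed_energy / schedule_energy (and overwrites
the frame's photon energy with the schedule value), which makes every
pulse's mean cell converge to the reference pulse's — the defining
post-condition of the correction.

## Indexing figure of merit and grid scan

FOM = IR · (1 − Σᵢ σᵢ·|κᵢ|), clamped at 0, with the sum over all six cell
parameters; σ in native units (Å or degrees). κ enters as an absolute
value: a negative skew is as much a symptom of miscalibration as a
positive one, and a signed κ would let it *inflate* the FOM. Both a
signed-κ and a σ/μ-normalised variant are exposed as toggles
(`signed_kappa`, `normalize_sigma`) since either convention is defensible;
the defaults are the ones that make the FOM peak at the true calibration
on synthetic data.

The scan evaluates the FOM on the pooled indexed frames for each assumed
(D, E) combination. Combinations with fewer indexed frames than the
minimum (50) are recorded as *absent* (NaN), not zero — a failed
evaluation is not evidence of a bad calibration. For the centre-of-mass
step the grid is bilinearly interpolated (refinement ×8 per axis by
default), normalised to maximum 1, and the optimum taken as the
FOM-weighted mean coordinate of the full matrix, with no threshold by
default (a threshold option exists). Absent cells contribute zero mass to
the interpolated matrix: the centre of mass needs a definite matrix, and
zero mass is the least-informative completion.

## Per-pulse energy fit and schedule

The reference pulse is the one with the highest indexed-pattern count
(ties to the earliest pulse; in burst-mode data this is typically the
first pulse, which suffers least from droplet disruption). Its energy is
pinned to the grid optimum. For every other pulse the energy E is scanned
over ±25 eV (the SASE bandwidth) in 0.5 eV steps, minimising the mean
squared relative deviation of the rescaled lengths {a, b, c} from the
reference. The objective is exactly quadratic in g = e0/E, so once the
scan brackets the minimum the closed-form minimiser E = e0·Σr²/Σr
(r = pulse/reference length ratios) is returned; this recovers noise-free
synthetic chirps to machine precision while the scan still guards against
out-of-range minima (boundary hits warn that the range is too narrow).
A first-order equivalent closed form is E ≈ e0·mean(r).

Per-pulse energy uncertainties are propagated from the standard errors of
the fitted cell means (σᵢ/√IR, pulse and reference in quadrature); with
1000 frames/pulse and 0.1 % cell noise this gives ≈0.25 eV per pulse,
consistent with the observed RMS recovery error (≈0.2 eV).

## Cell-distribution statistics

Each pulse's parameter distribution is summarised by a Gaussian fit to its
histogram (Freedman–Diaconis binning, floored at 20 bins; nonlinear least
squares seeded at the sample moments). Failed or implausible fits (centre
outside the data range, width >10× the sample std) fall back to sample
mean/std with an `ok=False` flag; both the fit and the moment estimates
are kept on the result so either can be inspected. Samples whose standard
deviation is indistinguishable from zero at float precision (std ≤ 1e-12
relative to the mean) are treated as degenerate: σ = 0, skewness 0 with a
warning. Skewness is the adjusted (bias-corrected) Fisher–Pearson
estimator, the standard small-sample choice. Pulses with fewer than 50
indexed frames carry no statistics and are excluded downstream.

## Synthetic data: what it emulates, and what it does not

Defaults encode the documented study conditions: 16 pulses/train at
47 kHz, 10 Hz trains, 4 droplets × 4 hits; tetragonal lysozyme cell
a = 79.45, b = 79.47, c = 38.32 Å, 90° angles; multiplicative cell noise
0.1–0.3 % (default 0.2 %; the chirp-recovery condition uses 0.1 %);
e_start = 9295.5 eV with slope −15.5/15 eV/pulse (last-minus-first drift
−15.5 eV) inside the 25 eV bandwidth, indexing assumed at 9290 eV and
236 mm. Hit probability decays per hit within a droplet (×0.82) and
weakly per droplet (×0.97) from a first-hit rate of 0.40, giving a
scheme-wide mean of 0.291; the per-slot decay constants are free
parameters chosen to reproduce the ≈29 % average, since only the average
is documented.

The `MiscalibrationEvaluator` emulates what re-indexing at a wrong (D, E)
does, with all per-frame randomness frozen at construction so the FOM
surface is smooth and deterministic: indexing survival falls off as
exp(−m²/2) in the normalised mismatch (widths 5 eV / 1 mm), and a
contaminant fraction (15 %) of frames picks up a positive cell shift
proportional to the mismatch (0.3 % per unit m), so σ and |κ| grow away
from the optimum. These response widths are phenomenological — real
indexing-failure profiles are software- and sample-dependent — so
synthetic FOM tests validate the *location machinery* (grid, interpolation,
centre of mass), not any particular falloff shape.

Pixel statistics draw each moment independently per pixel from normal
distributions (mean 100±5, std 30±3, skew 0±0.3, kurtosis 0±0.5 in
detector units); hot pixels are offset in the mean and std features.
Real detector moments are correlated across features and spatially
structured (panel edges, gain boundaries); passing the planted-outlier
test shows the feature/forest pipeline separates 10 σ outliers, not that
real LPD masking reaches any particular masked fraction (the documented
~17 % is data-dependent and out of scope).

Half-dataset intensities: true intensities are exponential (Wilson-like
for acentric reflections); each half accumulates 4 observations per
reflection, each tagged to a random pulse whose |energy error| inflates
the observation's relative error in quadrature with the base noise
(sd_eff = √(noise² + (scale·|ΔE|)²), scale 0.01/eV, noise 0.02). This is
a reduced model — no partiality, scaling, or resolution-dependent falloff
— built to carry exactly one effect: energy error degrades half-dataset
agreement, so removing it lowers Rsplit and raises CC* in every shell.

## Merging statistics

Rsplit = 2^(−1/2)·Σ|I1−I2| / (½Σ(I1+I2)); CC1/2 is the Pearson
correlation of half intensities; CC* = √(2CC1/2/(1+CC1/2)), left
undefined (NaN) for CC1/2 ≤ 0 rather than clipped — the extrapolation is
only meaningful for positive correlation. Halves are assigned by even/odd
frame index (deterministic, seedless, reproducible); reflections observed
in one half only are dropped and counted. Shells are 10
equal-reflection-count bins in 1/d by default.

## Injection and consumption

Effective repetition rate = pulses/train × train rate. Data rate =
indexed frames per second, reported to 1 decimal; sample over beamtime =
(target frames / data rate / 60) min × consumption rate (mg/min) / 1000,
reported to 3 decimals — the rounding conventions of the published
comparison table, which the package reproduces exactly for the four
self-consistent rows (one published row's grams figure is inconsistent
with its own consumption rate and is excluded). The waveform validator
checks the documented piezo envelope (5 μs rise to 70–90 V, 5 μs hold,
5–10 μs fall to −40 V, 10–20 μs hold, 5 μs return). The inter-hit droplet
volume is not modelled; its geometric basis is under-determined.

## Stream and mask I/O

Only the post-indexing subset of the stream format is handled: chunk
markers, `Event: //<train>-<pulse>` (the event-id convention this package
defines, 0-based pulse within train), `indexed_by`, `photon_energy_eV`,
`average_camera_length`, and the crystal `Cell parameters` line (nm/deg on
file, Å/deg in memory). Reflection tables and geometry blocks are
skipped; malformed numerics fail with a line number, unknown lines are
ignored. Masks are JSON (shape, 0-based row/col pixel list, per-pixel
rule provenance) with a 0/1 text-matrix export; pixel-statistic maps are
HDF5. Excluded panels are represented as a pre-mask fed to the
feature/combination steps, not as statistics.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give bit-identical outputs. The
bundled analyses use 16 pulses × 1000 frames/pulse for chirp recovery, an
11×11 (D, E) grid (0.5 mm × 2.5 eV steps, window centred 2 steps off
truth) with 250 trains per evaluation for the optimum-location check,
256×256 pixels with 1 % planted hot pixels for masking, and 2000
reflections × 10 shells for merging statistics — sizes at which the
stochastic checks are stable across seeds.

## Known limitations

- The calibration operates purely through the cell-scaling model; it
  cannot separate a photon-energy drift from a genuine per-pulse
  detector-distance drift (the experiment excluded the latter by imaging;
  the package holds D fixed after the reference optimisation).
- The energy schedule is per-pulse, not per-frame; shot-to-shot SASE
  jitter within a pulse slot is averaged over.
- The peakogram "non-continuous accumulation" rule is an
  operationalisation (isolated occupied bins above an intensity
  percentile); other formalisations are plausible.
- Synthetic tests validate machinery, not beamline-specific constants;
  no claim is made about reproducing data-dependent figures such as the
  masked-pixel fraction or absolute merging-statistic values.
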