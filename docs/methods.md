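# Methods

## Signal model and the hypersampling procedure

The package models the fMRI signal of a coherently pulsating compartment as a
sum of sinusoidal physiological oscillations on a per-slice baseline:

    s_v(t) = b(z_v) + Σ_c a_{comp(v),c} · sin(2π f_c (t − τ_c(v))) + ε

where voxel v in slice z is sampled at t = k·TR + offset[z] for volume k,
a is the compartment-specific amplitude of component c (LFO, respiratory,
cardiac, possibly with 1/h-amplitude harmonics), τ_c(v) is an optional
travelling-wave delay, and ε is white Gaussian noise. The model deliberately
omits BOLD neuronal dynamics, motion, and EPI artifacts: its purpose is to
make the temporal sampling arithmetic, the aliasing behaviour, and the
averaging effects exactly checkable, not to look like a brain.

Hypersampling proceeds in three steps per ROI:

1. voxels are grouped by their unique slice timing (n_time = N_Slice / MB
   groups; derived from a BIDS `SliceTiming` sidecar, with sub-millisecond
   tolerance clustering, or from acquisition parameters);
2. voxels within a group are averaged per volume and the group series is
   first-order detrended. Detrending the group mean is mathematically
   identical to detrending each voxel before averaging (both operations are
   linear; asserted by a test) at 1/V the cost. The linear detrend also
   absorbs per-slice baseline differences which would otherwise inject
   spectral lines at multiples of 1/TR into the stitched signal; any such
   lines remaining inside a requested band are reported via
   `stitching_lines_in_band`;
3. the n_time detrended series are interleaved in ascending slice-timing
   order onto the nominal uniform grid k·TR + j·TR/n_time. If the true
   offsets deviate from that grid by more than 10 % of TR/n_time a warning is
   raised; no resampling is attempted.

No motion correction is ever applied: realignment would destroy the exact
slice-timing correspondence the method relies on, so motion is gated (below),
not fixed.

### Gaps and coverage

An ROI missing a timing group leaves periodic gaps in the stitched signal.
An ROI covering half or fewer of the timing groups is rejected outright (the
coverage quality gate). Above that floor the default `gap_policy`
"interpolate" fills gaps linearly, keeping the uniform grid the periodogram
requires; "zero" and "strict" are available for users who prefer explicit
failure. Whether partial gaps should be interpolated at all is genuinely
open — only the more-than-half rule is prescribed — so the policy is an
explicit argument rather than a hidden default. Group series are not
variance-normalised before stitching (detrend only).

## Spectral estimation

Power spectra are one-sided rectangular-window periodograms of the demeaned
signal without zero padding, so that Σ psd·df equals the signal variance
(Parseval, tested at 1e-6 relative). Welch averaging is deliberately not
offered: absolute bandpower is the quantity of interest and segment averaging
would change it. Bandpower integrates psd·df over the bins whose centre
frequency falls inside the band — a fixed, stated convention, under which a
partition of [0, Nyquist] sums exactly to the total variance. Bands are LFO
0.01–0.1 Hz, respiratory 0.2–0.4 Hz, and cardiac f_heart ± 0.15 Hz; a heart
rate below 0.55 Hz makes the cardiac band overlap the respiratory band and
sets a warning flag rather than silently trimming either band.

Two closed forms support validation:

* `alias_frequency(f, fs) = |f − round(f/fs)·fs|` — where an undersampled
  sinusoid appears;
* `averaging_attenuation(f, TR, n) = |sin(πfTR)| / (n·|sin(πfTR/n)|)` — the
  amplitude ratio left after averaging the n uniformly time-shifted copies of
  a sinusoid (Dirichlet kernel). Its square predicts the ROI-mean/hypersampled
  power ratio for a coherent oscillation; phantom measurements match it to
  well under 1 % (the acceptance suite enforces 5 %). At the fast-TR
  comparison geometry (TR = 0.366 s, n_time = 5) it evaluates to ≈ 1.00 at
  0.05 Hz, 0.96 at 0.3 Hz, and 0.70 at 0.9 Hz — which is why
  hypersampled-vs-ROI-mean regression slopes sit near 1 for LFO/respiratory
  power but well above 1.3 for cardiac power.

## PPG processing

The heart frequency is the PSD argmax of the linearly detrended PPG within a
configurable search range (default 0.6–2.0 Hz ≈ 36–120 bpm). PPG quality is
the fraction of total power (excluding < 0.01 Hz drift, so baseline wander
cannot deflate the score) inside the cardiac band; the QC threshold defaults
to 0.3 and is configuration — no published value exists for it. Beats are
local maxima of the PPG band-passed to ±0.3 Hz around the heart frequency
with a minimum separation of half a cardiac period; cardiac phase at any scan
time is the elapsed fraction of the surrounding beat-to-beat interval. This
beat picker is a simple, fully tested stand-in for lab-specific pulse
detectors; phase is invariant to PPG scaling and offset by construction.

## Vessel segmentation

Volumes with a defined cardiac phase are randomly split (seeded permutation)
into two halves; each half is phase-binned (default 10 bins) per voxel after
detrending, and the Pearson correlation between the two binned waveforms
scores pulsatility reproducibility. Voxels at or above `r_threshold`
(default 0.5) inside an anatomical search-region mask form the vessel ROI,
optionally reduced to the largest connected component (default on — isolated
supra-threshold noise voxels are implausible vessels). Both defaults are
package choices surfaced in the run report, not published values. The
volume-level cardiac phase is evaluated once per volume at the scan's mean
slice offset; a voxel's constant offset from that reference shifts both half
waveforms identically and cancels in the correlation. Per-slice phase
assignment is a possible refinement, not currently needed at the tested
noise levels. Fewer than `min_voxels` (default 5) surviving voxels raises an
"unreliable vessel segmentation" error, mirroring the scan-exclusion rule.

## Quality gates

* Motion: fail if *more than* 15 % of volumes exceed 1 mm absolute
  displacement — the boundary is strict in both comparisons (exactly 15 %
  passes; exactly 1 mm is not an excursion) and unit-tested there. Motion
  traces are consumed (single displacement column, or six motion parameters
  reduced to the Euclidean norm of the translations), never computed.
* PPG: fail below `min_quality` (default 0.3).
* Coverage: fail if an ROI spans half or fewer of the unique slice timings
  (4 of 9 fails, 5 of 9 passes).

All gates are pure functions; the report serialises to JSON and round-trips.

## The phantom: what it emulates and what it does not

Presets mirror two real acquisition geometries: `hcp_like` (72 slices, MB 8,
TR 0.8 s, 488 volumes, 2.0 mm voxels) and `local_like` (40 slices, MB 8,
TR 0.366 s, 500 volumes, 2.5 mm voxels). The in-plane grid is 8×8: the
method consumes ROI-mean time series, so in-plane extent only sets voxel
counts, and a small grid keeps simulations cheap. Four z-slab compartments
with strictly distinct per-band amplitudes mirror the characteristic regional
dominance patterns (cardiac-dominant artery, mixed SSS, LFO-dominant GM/WM).
Default components: LFO 0.05 Hz (coherent), respiratory 0.3 Hz (0.1 m/s
wave), cardiac 1.1 Hz (2 m/s wave), with propagation delays measured as
Euclidean distance in mm from a source voxel divided by the wave speed — the
simplest model consistent with the wavelength argument λ = T·v. Default
noise_sd 0.2. The PPG is a harmonic pulse train (3 harmonics, 100 Hz) locked
to the cardiac component. All randomness flows from one integer seed through
one generator.

Passing tests on this phantom demonstrate that the sampling arithmetic,
detrending, stitching, spectral estimation, phase realignment and the
attenuation/propagation mechanics are implemented correctly, and that
bandpower is recovered quantitatively under additive white noise. They do
not demonstrate robustness to real-data complications the phantom omits:
BOLD fluctuations, motion, heart-rate variability, scanner drift beyond
linear, or EPI artifacts.

Two phantom conditions are worth noting. The vessel-segmentation
demonstration uses a 1.23 Hz heart rate: at TR = 0.8 s a 1.0 Hz rhythm hits
only five distinct cardiac phases (0.8·f mod 1 cycles with period 5),
starving the phase bins — an aliasing quirk of the demonstration geometry,
not of the method. And the amplitude-recovery conditions (SNR 3, i.e.
noise_sd = largest amplitude / 3, 20 seeds) leave a small (< 5 %) upward
noise-floor bias on the weakest bands, comfortably inside the 15 % recovery
tolerance the acceptance suite checks.

## Numerical choices and degenerate inputs

* Slice-offset grouping tolerance 1 ms; TR metadata disagreement > 1 ms is an
  error (hypersampling with wrong timings is meaningless, so metadata
  conflicts never degrade to warnings).
* Masks must match the scan grid and affine (1e-3); no resampling ever.
* n_time = 1 (MB = N_Slice) degenerates exactly to the detrended ROI mean.
* Detrending needs ≥ 3 samples; periodograms ≥ 8; phase binning errors when
  more than half the bins are empty; correlation of a zero-variance waveform
  is defined as 0.
* `start_offset_s` aligns physio to the scan (default 0: recording starts
  with the first volume); scan times outside the detected beat span get no
  cardiac phase and are excluded from realignment.

## Problem sizes

Simulation-based tests and the acceptance script run the full preset volume
counts (488/500 volumes) on the 8×8 in-plane grid, 20 seeds for the
stochastic checks — about 150 tests in ~15 s and a ~6 s acceptance run on one
CPU. These sizes were chosen as the smallest that exercise every mechanism at
realistic durations.

## Pipeline configuration (CLI)

`fmripulse run config.yaml` expects keys: `fmri`, `sidecar`, `physio`,
`physio_fs_hz`, `motion`, `out_dir`, `masks` (label → NIfTI path); optional
`search_masks` (enables vessel segmentation), `min_quality`,
`max_abs_motion_mm`, `max_motion_fraction`, `n_phase_bins`, `r_threshold`,
`gap_policy`, `cardiac_halfwidth_hz`, `physio_start_offset_s`, `seed`. Exit
codes: 0 ok, 2 QC failure (override with `--force`), 1 error. Every
effective parameter, band edge, and warning lands in `run_report.json`;
outputs are TSV (hypersampled signals, spectra, long-format bandpower table
ready for external mixed-effects modelling of e.g. age/sex effects) and JSON
(QC, run report).

## Known limitations

* The method trades spatial for temporal resolution: it needs ROIs spanning
  most slice timings, so it cannot target small structures.
* Regions with internally heterogeneous dynamics (e.g. the ventricular
  system) violate the coherence assumption; the incoherent part is
  suppressed ∝ 1/(voxels per timing group), which is a feature for systemic
  physiology and a caveat for everything else.
* Respiratory bandpower is the most sensitive to pulse propagation (short
  wavelength) and should be interpreted with caution — quantified here by
  the hypersampled/voxel-wise power ratio.
* Group-level statistics are exported, not fitted: the long-format table is
  the interface to external modelling.
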