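# Methods

`physiofc` quantifies how four nuisance processes — systemic low-frequency
oscillations (SLFOs), cardiac pulsatility (CP), breathing motion (BM) and head
motion (HM) — imprint themselves on static and time-varying functional
connectivity (FC) of parcellated resting-state BOLD fMRI, and how well common
denoising strategies remove those imprints.  Because the quantities of
interest require *known* ground truth, the package ships a synthetic-cohort
generator that emulates the multi-session, dual-phase-encoding resting-state
design the analysis was built for.

## The nuisance model

Each scan's parcellated series `y(t)` (frames × ROIs) is modelled per ROI as

    y = b0 + b_SLFO x_SLFO + B_CP x_CP + B_BM x_BM + B_HM x_HM + e

with 25 regressors in total:

* **SLFO (1 regressor).** Heart rate (bpm, 10 Hz grid) and respiratory flow
  (squared derivative of the smoothed belt signal) are convolved with cardiac
  and respiratory response functions (PRFs) and summed.  Each PRF is a
  difference of two peak-normalized gamma densities (5 shape parameters per
  curve; the positive lobe's amplitude is absorbed into an OLS combination
  weight).  In `scan_specific` mode the shape parameters are fitted by
  bounded multi-start optimization (L-BFGS-B, 8 starts) maximizing the
  multiple correlation between the two convolved series and the scan's global
  signal; `canonical` mode uses fixed curves peaking near 4 s (cardiac,
  undershoot ≈ 12 s) and 3.5 s (respiratory, undershoot ≈ 15 s), matching
  published response-function shapes.  If every optimization start fails the
  canonical curves are used and flagged.
* **CP and BM (6 regressors each).** 3rd-order RETROICOR expansions
  `[cos(mφ), sin(mφ)], m = 1..3` of the cardiac phase (linear between
  detected beats, extrapolated with the first/last inter-beat interval
  outside the beat span) and the respiratory phase
  (amplitude-histogram-equalized, 100 bins, signed by the derivative of the
  belt signal).
* **HM (12 regressors).** The six realignment parameters and their
  backward-difference derivatives (first frame set to 0), each residualized
  against the 6 BM regressors plus intercept, so breathing-locked true and
  factitious motion is credited to the breathing-motion process.

All regressors are high-pass filtered at 0.01 Hz (2nd-order Butterworth,
forward–backward, DC removed exactly afterwards) and z-scored (sd with
`ddof=1`), in that order, so normalization reflects the final spectral
content.  A collinearity report (max pairwise |r|, per-column VIF) accompanies
every design; VIF > 10 warns but does not fail.

## Isolation and the synthetic nuisance datasets

From the joint OLS fit, the fitted fluctuation of one process is
`y_npi = X_p @ b_p`, and its "clean" companion `y_npi_plus_neur` subtracts the
intercept and every *other* process from `y`.  The per-ROI contributions

    r_nuis = corr(y_npi, y_npi_plus_neur),  r_neur = corr(y_neur, y_npi_plus_neur)

with `y_neur = y_npi_plus_neur − y_npi` satisfy `r_nuis² + r_neur² = 1`
exactly (OLS orthogonality); this identity is asserted in the tests at 1e−8.

A nuisance dataset replaces the residual by a stationary first-order
autoregressive process:

    y_nuis = r_nuis · Z[y_npi] + r_neur · Z[ψ],  ψ_t = a1 ψ_{t−1} + ξ_t

where `Z` is z-scoring, `a1` is drawn per ROI per scan from an empirical pool
of lag-1 autocorrelations fitted to the cohort's parcellated series, and ψ
discards a 200-sample burn-in so it is stationary.  Without the AR(1) term
two ROIs weakly but commonly driven by a process would correlate at ±1,
overstating the process's imprint on FC; the tests verify that a constructed
two-ROI case with `r_nuis = 0.1` stays below |r| = 0.5.

## Denoising registry

Six base strategies × {GSR off, on} = 12 pipelines: `raw` (identity), `FIX`
(externally ICA-denoised input; pass-through here, only the GSR stage runs),
`MildA` (WM/CSF means + 12 motion regressors), `MildB` (WM/CSF means and
derivatives + 24-parameter motion expansion: parameters, derivatives, squares,
squared derivatives), `WM_50` and `WM_200` (white-matter principal-component
time courses, deterministic sign convention).  GSR adds the mean series across
ROIs (and its derivative for `MildB`).  Regressor blocks are high-passed and
the ROI series residualized against them plus an intercept.  With no separate
CSF pool configured, the WM voxel pool is split in half and the two half-pool
means serve as the WM-like and CSF-like regressors.  Note that because the GS
regressor is re-filtered before residualization, a small transition-band
remainder of the global signal can survive GSR on data that was not itself
filtered by the identical filter.

## Connectivity and fingerprinting

Static FC is the ROI × ROI Pearson matrix over the whole scan.  Time-varying
FC uses 60-sample windows (43.2 s at TR 0.72 s) with 70% overlap
(step = round(0.3·60) = 18); the FCD matrix correlates vectorized window-FC
upper triangles.  For 1200 frames this yields floor((1200−60)/18)+1 = 64
windows; analyses of this design are sometimes quoted with 62 windows, which
the window arithmetic cannot produce — the count here follows the formula and
is configurable.  Similarity between two connectomes is the Pearson
correlation of upper-triangular entries, Fisher z-transformed (clipped at
1 − 1e−15); for FCD matrices, window pairs whose starts differ by less than
one window length are excluded (overlap lags 1–3 at the default geometry,
leaving 1830 of 2016 pairs for 64 windows).

Fingerprinting identifies a target subject as the database subject whose FC
upper triangle (over a whole-brain or network-restricted edge mask; networks
under 10 ROIs excluded) correlates most strongly with the target matrix.
Ties within 1e−12 count as failures.  With 4 sessions per subject all 12
ordered database–target pairs are evaluated.  The permutation null shuffles
database identity (uniform permutations, fixed points allowed); the
target-database correlation matrix is computed once per session pair, so
permutations only relabel its argmax.

## Surrogate statistics

Inter-subject surrogates replace the examined process's regressors in each
scan's design with those of a donor scan from a different subject (a
derangement over subjects per repetition; 1000 repetitions at study scale).
The statistic is the cross-scan mean `r_nuis` per ROI; the empirical p-value
uses the +1 correction, one-sided right tail (contributions are positive
under the alternative).  Multiple comparisons: Benjamini–Hochberg FDR
(default) and Bonferroni; group comparisons: two-sided Wilcoxon rank-sum,
exact for samples ≤ 20 without ties, normal approximation with tie correction
otherwise.

## The synthetic cohort

`SimConfig` defaults emulate the target design: per subject 2 days × {LR, RL}
phase encodings, 1200 frames at TR 0.72 s, physiological channels at 100 Hz
(ample for pulse timing of the simulated waveform widths).  Per subject the
generator draws: heart-rate baseline N(65, 7) bpm clipped to [50, 90] with
HRV 2–5 bpm; breathing rate N(0.27, 0.04) Hz; breathing-depth variability
10–30%; PRF shape jitter ±15% around the canonical curves; a motion coupling
of 0.04–0.08 mm per unit breathing amplitude on the phase-encoding axis; a
spike rate of 0.2–1 displacement steps per minute; a modular neural
covariance (within-network 0.35, between 0.05, subject edge jitter sd 0.1,
projected to the nearest unit-diagonal PSD matrix); and subject-jittered
per-ROI nuisance gain maps.  The group SLFO gain is elevated ×1.5 in the
visual network; the BM gain carries a left/right-hemisphere contrast whose
sign flips between LR and RL encodings.  Neural dynamics follow a
multivariate AR(1) (coefficient 0.3 at TR 0.72 s) with the subject covariance
as stationary spatial covariance.  WM voxels carry the same nuisance
processes with voxel-specific per-process gains (so the pool spans the
nuisance subspace) plus white noise.

The default per-process gain scales (SLFO 0.8, CP 0.3, BM 0.35, HM 0.4,
applied to z-scored regressors) put the simulator in a strong-confound
regime: every process is detectable within a single scan and the forward
model is invertible — the GLM recovers the mixing coefficients with < 15%
relative RMSE over 20 default-size scans.  What the generator does *not*
emulate: voxel-level imaging (no NIfTI), nonlinear hemodynamics, CO2 or
blood-pressure dynamics, scanner drift or spatial autocorrelation of noise,
and genuinely non-stationary neural connectivity (the neural model is
stationary, so FCD fluctuations in the synthetic data reflect window
estimation noise and nuisance modulation only).  Passing tests therefore
demonstrate correctness of the estimators under the forward model, not the
magnitudes to expect in real recordings.

## Numerical and design choices

* Peak detection: `scipy.signal.find_peaks` with prominence relative to a
  rolling 5–95% amplitude range and a two-pass distance rule (first bound by
  the maximum plausible rate, then half the running RR estimate).
* Hampel filter: exact windowed median/MAD via a sliding-window view,
  reflect-padded edges, strict-inequality rule so a spike over a locally
  constant background is replaced while constant data pass unchanged.
  Heart-rate outlier replacement runs on beatwise values before gridding,
  where a spurious beat is an isolated spike.
* Cardiac-phase edge rule: frames outside the detected beat span reuse the
  first/last inter-beat interval.
* Convolution edges: series are demeaned and zero-padded pre-scan; warm-up
  transients are handled by the subsequent high-pass rather than truncation.
* Regressor sampling times: t = k·TR (no slice-timing model).
* Degenerate inputs: zero-variance ROI columns fail static FC loudly with the
  ROI named; a process explaining no variance yields `r_nuis = 0` with a flag
  and a pure-AR(1) column in the nuisance dataset.
* Workflow: one run seed expands into independent per-stage substreams
  (`numpy.random.SeedSequence`), so stages re-run independently and
  deterministically; every stage writes a provenance JSON.  The demo-scale
  configurations in the tests (3 subjects, ~150–300 frames, ~12–18 ROIs) keep
  the full pipeline in the seconds range; parameter-recovery checks use 20
  scans at the full per-scan geometry.

## Known limitations

Scan-specific PRF estimation is the slowest step (tens of seconds per scan)
and the workflow defaults to canonical curves; the estimator is validated on
convolution-constructed global signals where it attains fit quality > 0.99
and curve recovery r > 0.95.  The QC rule for the 48-bpm flatline artifact
and the automated replacements for visual inspection are heuristics with
configurable thresholds, not replications of any specific lab's procedure.
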