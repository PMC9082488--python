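# Methods

`editfit` is a self-contained laboratory for studying how spectral
*modeling* choices affect the reproducibility of edited magnetic
resonance spectroscopy (MRS). It generates synthetic test–retest cohorts
of J-difference-edited acquisitions — Hadamard-encoded HERMES at
TE = 80 ms (GSH and GABA+ edited simultaneously) and MEGA-PRESS at
TE = 120 ms (GSH only) — processes them through a realistic chain, and
quantifies the difference spectra with two families of models: simple
multi-Gaussian peak fitting and linear-combination modeling (LCM) with a
cubic-spline baseline. This note records the models, the choices behind
their defaults, and what the synthetic data do and do not emulate.

## Forward model

Every signal is a sum of damped complex exponentials,

    s(t) = Σ_m c_m Σ_l a_l e^{iφ_l} e^{i2π(δ_l − δ_0)ν_0 t}
           e^{−t/T2_m} e^{−(g_m t)²},

with line positions δ_l in ppm, transmitter frequency ν_0 (127.7 MHz,
i.e. 3 T — assumed, configurable), carrier on water at δ_0 = 4.68 ppm,
per-multiplet Lorentzian (T2) and Gaussian (g) decay. Editing physics is
*encoded* rather than simulated: each catalog species stores one line
table per sub-experiment, and a species responding to an editing pulse
simply inverts (180° phase) when that pulse is off. This makes the
ground truth exact and lets the matching LCM basis be generated from the
identical forward model — which in turn enables exact-recovery tests
that a density-matrix simulation would not admit.

The committed catalog covers the species that matter for the difference
spectra: GSH (2.95 ppm, edited at 4.56 ppm), the co-edited aspartyl
multiplet near 2.6 ppm, GABA (3.01 ppm, edited at 1.9 ppm; HERMES only),
Glx (3.71/3.79 ppm, co-edited with GABA), unedited NAA/tCr/tCho (which
cancel in the differences but drive the alignment steps), macromolecule
resonances at 0.93/1.2/1.4/3.0 ppm, and residual water. Two preset
contrasts carry the study's central hazard:

* **TE-80 aspartyl**: eight lines spanning 2.39–2.86 ppm with strongly
  mixed phases (+40°…−150°), an oscillatory lineshape whose upfield
  lobes reach under the GSH peak and which no small set of absorptive
  Gaussians plus a smooth baseline can represent;
* **TE-120 aspartyl**: five compact, near-absorptive lines (|φ| ≤ 15°)
  at reduced amplitude (T2 attenuation at the longer TE).

These presets are versioned fixtures chosen to reproduce the qualitative
short-vs-long-TE contrast of co-edited aspartyl signals; they are not
spin physics. Macromolecule "concentrations" are spectral areas in ppm
units: the MM lineshape is a Gaussian normalized to unit
baseline-corrected area (a one-sided FID splits s(0) equally between the
absorption peak and a flat spectral pedestal, hence a factor 2 in the
time-domain amplitude; the pedestal is absorbed by fitted baselines).

## Synthetic cohorts

Defaults mirror the reference protocol: 12 subjects × 2 scans, TR
2,000 ms, 2.5 kHz spectral width, 2,048 complex points, 256 transients
per sequence (HERMES splits them over four sub-experiments A–D,
MEGA-PRESS over ON/OFF — equal total scan time), editing pulses at 1.9
and 4.56 ppm, and a matched unsuppressed-water acquisition per scan.
Subject-level true concentrations are log-normal around the catalog
means with a 10% between-subject CV; scan-level values jitter with a 5%
within-subject CV (the water reference stays fixed within a subject, so
metabolite/water ratios carry the 5%). Log-normal variation keeps
concentrations positive; CV parameters are interpreted as SD/mean with
the mean preserved.

Instrumental terms (all configurable, defaults in parentheses):

* complex white noise per transient point (SD 6.0) — set so that
  single-scan GSH fit CVs land in the 5–10% range that motivates
  averaging 256 transients in vivo;
* linear frequency drift (0.05 Hz/transient, centered) and per-transient
  frequency (SD 0.3 Hz) and phase (SD 2°) jitter, applied over the
  interleaved acquisition order so drift spreads across sub-experiments;
* slow additive baseline distortion (three fast-decaying random
  components per sub-experiment, amplitude scale 1.0) emulating
  baseline roll that survives the difference;
* an eddy-current phase e^{iφ(t)}, φ(t) = 0.3·e^{−t/60 ms}, applied to
  every FID of a scan including the water reference;
* residual water: the 4.56-ppm editing pulse attenuates water to 60% in
  GSH-ON sub-experiments, leaving a difference-spectrum residual about
  five times the GSH amplitude (so the HSVD filter has real work), plus
  a small GABA-state asymmetry.

What the generator does **not** emulate: J-evolution and TE-dependent
multiplet structure beyond the committed presets, spatial localization
and chemical-shift displacement, phase cycling, frequency-dependent
editing-pulse profiles, subject motion, and lineshape distortions beyond
Voigt. Passing tests therefore demonstrate correctness of the analysis
chain and the *relative* behavior of the two modeling families under
controlled, realistic instabilities — not absolute in vivo accuracy.

## Preprocessing

1. **Eddy-current correction**: the unwrapped water-FID phase is
   subtracted from every FID (zero-magnitude samples carry the previous
   phase forward).
2. **Spectral registration**, separately within each sub-experiment set:
   each transient is aligned to a robust (pointwise median) reference
   over the first 200 ms by solving min_{Δf,φ} Σ|s·e^{i(2πΔf t+φ)} − ref|²
   exactly — the optimal phase has a closed form given Δf, reducing the
   problem to maximizing |H(Δf)| with H the windowed cross-correlation,
   located on a zero-padded FFT grid and refined by parabolic
   interpolation. Two passes with the reference rebuilt. This evaluates
   the same objective a derivative-free search would, but vectorizes
   across transients.
3. **Weighted averaging** with w_n ∝ 1/d_n², d_n the squared deviation
   of transient n from the pointwise median (gross outliers are
   down-weighted; identical transients reduce to the plain mean).
4. **Sub-spectrum alignment**: sequential pairwise frequency/phase
   optimization minimizing the pair difference restricted to a signal
   region — residual water (4.2–5.2 ppm) to align B→D, the 2-ppm tNAA
   signal for C→D, the 3.2-ppm tCho signal for A→C (HERMES), or tNAA in
   the ON−OFF difference (MEGA-PRESS). Because the pair difference also
   contains the *genuinely edited* signals, whose dispersive wings exert
   a first-order pull on any plain difference-minimization, the
   model-predicted edited shapes (catalog responses, amplitudes free)
   are projected out of the residual first; the region's carrier species
   (water for B→D) is kept out of the projection since its misalignment
   residue is the information the alignment runs on. With the
   projection, the noiseless optimum is exactly zero correction and the
   estimator is unbiased. Corrections are bounded (±3 Hz, ±3°): residual
   misalignment after registration is small, and the phase information
   in one narrow region of a single averaged sub-spectrum is
   noise-limited.
5. **Combination**: GSH difference = (A − B + C − D)/4, GABA+ difference
   = (A + B − C − D)/4, MEGA difference = (ON − OFF)/2. Dividing by the
   number of summed sub-spectra keeps amplitudes per-average comparable;
   the convention cancels in water-scaled ratios.
6. **HSVD water removal**: Hankel matrix of the first 1,024 points
   (512 in the reduced profile), truncated SVD (rank 25 / 15), poles
   from the shift-invariance eigenproblem, amplitudes by linear least
   squares; components inside 4.4–5.0 ppm are reconstructed over the
   full FID and subtracted. Growing poles are clamped to |z| ≤ 1 so
   full-length reconstructions stay bounded.
7. **Apodization and FFT**: 3-Hz exponential line broadening,
   zero-filling to 32K by default.

The full chain is deterministic, permutation-equivariant in transient
order (to floating-point reordering noise), and on a noiseless,
distortion-free scan reproduces the direct catalog prediction to
~10⁻⁷ relative.

## Simple peak fitting

Three models over the real part of the spectrum, each with a curved
baseline of constant/linear/quadratic terms plus one global zero-order
phase applied to the complex data (four non-Gaussian parameters):

* GABA+/Glx: three Gaussians on 2.79–4.10 ppm (seeds 3.02, 3.71,
  3.79 ppm), target = 3-ppm Gaussian;
* GSH at TE 80: five Gaussians on 2.25–3.50 ppm (GSH at 2.95 ppm, four
  aspartyl seeds across 2.45–2.75 ppm);
* GSH at TE 120: six Gaussians (five aspartyl).

Widths are bounded to [0.01, 0.2] ppm and centers to ±0.1 ppm of their
seeds (prevents peak swapping); amplitudes are free-signed. Three
jittered starts are run and the best residual kept, ties broken by the
smallest target-center deviation. The reported quantity is the analytic
area A·σ·√(2π) of the target Gaussian. The optimizer budget (100
evaluations per start) is part of the model: the target area stabilizes
to <0.1% long before the sloppy width/baseline directions fully
converge, and a fit is flagged only when the optimizer neither hits its
tolerance nor do independent starts agree on the area within 2%.

A Gaussian-model area of a Voigt peak systematically misses the
Lorentzian tail mass contributed by the protocol's 3-Hz exponential
broadening; on noiseless fixtures this deficit is 10–15% (GSH, GABA+)
and deterministic. Tests therefore check linearity (0.1%), clean-Gaussian
self-fits (~10⁻⁶), and the TE-80 > TE-120 error ordering tightly, but
bound absolute area agreement one-sidedly at 20%. The water reference is
fit with a Gaussian–Lorentzian product lineshape (phase + linear
baseline, Gaussian-dominant and Lorentzian-dominant starts) and
integrated numerically over 4.2–5.2 ppm.

## Linear-combination modeling

The difference spectrum is modeled on 0.5–4.2 ppm as

    Re{ e^{i(φ0 + φ1(δ−δ̄))} Σ_m A_m B̃_m(δ) } + Σ_k β_k B_k(δ),

where B̃_m is the basis FID after per-basis Lorentzian broadening γ_m,
global Gaussian broadening σ_G, and per-basis shift δ_m; B_k are cubic
B-splines on evenly spaced knots (0.4 ppm spacing → 13 regressors on the
default range, a partition of unity reproducing cubics exactly). The
basis carries the same exponential line broadening as the data.
Estimation is by variable projection: for every trial of the nonlinear
parameters, amplitudes are re-solved by non-negative least squares with
the spline block eliminated through a fixed QR projection and
amplitude-ratio soft constraints (MM12:MM14 = 2 ± 0.2, MM30:MM093 =
2 ± 0.2 — invented defaults, configurable) appended as penalty rows;
the nonlinear parameters move under a bounded trust-region step with
Gaussian priors on shifts (SD 0.02 ppm, bound ±0.05 ppm) and Lorentzian
broadenings (SD 2 Hz, bound 15 Hz). Per-basis broadening (rather than a
single global Lorentzian) was chosen because the MM and metabolite
linewidths genuinely differ; the priors keep the extra parameters from
absorbing noise. GABA+ is reported as A_GABA + A_MM30. The water
reference is fit in the frequency domain with a simulated water basis
function and exactly six parameters (amplitude, zero-/first-order
phase, Gaussian and Lorentzian broadening, frequency shift).

With the exact basis and noiseless data the fit recovers amplitudes to
<0.1%, applied zero-order phases to <0.5°, and shifts to <0.005 ppm.
Multi-replicate studies cap the outer optimizer at 12 steps; the
amplitude estimates agree with full convergence to well under the
scan-to-scan noise level.

## Quantification and statistics

Estimates are water-scaled institutional units, κ·met/water with
κ = 1000 (one arbitrary global constant; no relaxation or
tissue-segmentation corrections anywhere in the path — asserted against
the processing provenance). Each method uses its own water metric (GL
area for peak fitting, six-parameter amplitude for LCM), so absolute
i.u. levels differ between methods while all scale-invariant statistics
are unaffected.

Test–retest statistics per (sequence, metabolite, method) cell:

* within-subject CV = 100·s_w/x̄ with s_w = √(Σ_i d_i²/(2n)), d_i the
  paired scan difference and x̄ the grand mean (RMS-of-differences
  estimator; scale-invariant);
* Bland–Altman mean difference and 95% limits of agreement
  (±1.96·SD of differences) on unit-mean-normalized pairs;
* a two-sample variance-ratio test (R's `var.test` convention) between
  the two methods on unit-mean-normalized subject means, F = s²_peak /
  s²_LCM with df (n−1, n−1), two-sided p by doubling the smaller tail,
  and 95% CI (F/q₀.₉₇₅, F/q₀.₀₂₅) from the F quantiles.

## Problem sizes and profiles

Full-resolution defaults (32K zero-fill, 1,024-point HSVD) are used for
single-scan analyses. Multi-replicate studies use a reduced profile —
no zero-filling (the native 2,048-point grid resolves the 3-Hz-broadened
~10-Hz lines with ~8 points per width), 512-point/rank-15 HSVD, 10
outer LCM steps, a 40-evaluation peak-fit budget per start, and 32
transients per HERMES sub-experiment (128 per sequence, equal scan time
for MEGA-PRESS) — whose estimates agree with the defaults to well under
the scan-to-scan noise level. The reproducibility studies
run 50 cohort replicates in the test suite and 10 in the acceptance
script. All randomness flows from a single integer seed through
counter-style `SeedSequence` derivations, so every stage is
independently reproducible and whole runs are bit-identical.

## Known limitations

* The catalog's editing behavior is binary (full inversion), so editing
  efficiency enters only through line amplitudes; TE-dependence of
  J-evolution is represented solely by the committed aspartyl presets.
* The alignment-bias projection uses the catalog's own edited shapes —
  legitimate prior knowledge in this synthetic setting, but a real
  pipeline would have to derive them from simulated basis functions.
* Gaussian peak areas of Voigt lineshapes are biased low by design of
  the estimator (see above); the package's comparisons are about
  *reproducibility*, where this common-mode bias cancels.
* Between-method F tests at n = 12 have limited power; single-cohort F
  statistics are reported but fluctuate strongly across seeds.
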