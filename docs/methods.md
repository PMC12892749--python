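# Methods

`eznetsi` implements a noninvasive localization chain for the epileptogenic
zone (EZ) in focal drug-resistant epilepsy: preictal scalp EEG is projected
into cortical source space, directed frequency-band networks are estimated
there, and regions are scored by degree centralities and by a
dynamical seizure index.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Signal conditioning

The conditioning chain mirrors standard clinical preprocessing: a 0.5–80 Hz
band-pass, a 48–52 Hz mains stop band, selection of the 10-minute window
preceding electrographic seizure onset, and segmentation into 2-s epochs.
All filters are 4th-order Butterworth run forward–backward
(`sosfiltfilt`), i.e. zero-phase, so that preictal timing relationships
survive filtering; linearity and zero-lag are property-tested.  ICA-based
artifact rejection is deliberately not reimplemented — component selection
is a manual, rater-dependent step — so the pipeline takes pre-cleaned
recordings and documents the insertion point.  The reference montage is
configurable; common-average is applied inside the inverse operator (the
conventional choice for sLORETA) and optionally to the data.

## Forward model

In place of an MRI-derived boundary-element head model the package uses the
closed-form potential of a current dipole in a homogeneous conducting
sphere (insulating exterior, conductivity 0.33 S/m).  For a dipole moment
**m** at **r₀**, surface electrode **rₑ**, `d = rₑ − r₀`:

    V = (1/4πσ) m · [ 2d/|d|³ + (r̂ + d/|d|) / (R(R − r₀·r̂ + |d|)) ]

This is the source-position gradient of the classical monopole solution
`2/|d| + (1/R)·log(2R/(R − r₀·r̂ + |d|))`; it is verified against a
Legendre-series evaluation to 1e-8 in the tests.  A central dipole gives
the pure n = 1 term `V = 3 m·r̂/(4πσR²)` — a dipolar pattern, not zero; the
"silent central radial source" intuition belongs to magnetic recordings and
does not apply to EEG.

Electrodes are the 21 positions of the international 10–20 montage
(idealized coordinates from the standard montage definition, projected to
the unit sphere).  Sources sit at 0.75 of the head radius on a
quasi-uniform Fibonacci shell restricted to a cortical cap (z ≥ −0.2):
cortex does not reach the inferior pole, and a source the montage cannot
see reconstructs as pure leakage, which poisons downstream connectivity.
Radius 0.75 was retained after testing 0.85, which is nominally more
anatomical but aliases badly through 21 electrodes.

## Inverse solution

sLORETA with scalar (fixed-orientation) sources: minimum-norm kernel
`T = Gᵀ(GGᵀ + αI)⁺` after common-average referencing, standardized by the
resolution-derived variance `R_jj = (TG)_jj`:

    ŝ_j(t) = (T y(t))_j / sqrt(R_jj)

Auto-regularization uses `α = trace(GGᵀ)/(n_sensors · SNR²)` with an
assumed amplitude SNR of 3.  Identity noise covariance is used throughout
(no noise-covariance estimation procedure is defined for this data).
Because the resolution matrix is positive semidefinite, Cauchy–Schwarz
gives the zero-localization-error property for noiseless single sources at
any α ≥ 0; this is tested on random lead fields and the spherical model.
Scalar orientation (rather than free 3-component dipoles) keeps the region
time series signed and single-valued, which the MVAR, Hilbert and
seizure-index stages require.

The default source model places one source per region of the
Desikan–Killiany parcellation (68 regions), so region extraction is the
identity; a dense-vertex mode with sign-aligned within-region averaging
(flip a member when negatively correlated with the region's first member)
exists for imaging tests.  21 electrodes cannot resolve dense grids, so
region-level sources are what every downstream stage consumes.

## Spectral analysis

Welch PSD with 2-s Hann windows and 50% overlap, one-sided density
normalized so its integral equals signal variance.  Band aggregation takes
the *mean* in-band density and reports `10·log₁₀` (dB/Hz), preserving the
printed units.  Band edges: delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
low-gamma 30–48, high-gamma 52–80 Hz, half-open `[lo, hi)`; the 48–52 Hz
gap is forced by the mains notch.  Only the delta edges are fixed by the
source material; the others are the conventional choices and are
config-exposed.  Hilbert envelope and wrapped phase come from the FFT-based
analytic signal.

## Directed networks

A multivariate autoregressive (MVAR) model is fitted to the region series
by ridge-regularized least squares, pooling the 2-s epochs as independent
realizations; the penalty is `ridge · mean(diag(XᵀX))` with ridge 1e-3, and
the order is chosen by BIC over 1–10 on a common effective sample.
Regularization is not optional: 68 regions reconstructed from 21 sensors
leave the per-epoch problem rank-deficient.

The directed transfer function of the fitted model,
`γ²ᵢⱼ(f) = |Hᵢⱼ(f)|² / Σₘ|Hᵢₘ(f)|²` with
`H(f) = (I − Σₖ Aₖ e^{−i2πfk/rate})⁻¹`, is averaged over in-band
frequencies and transposed to a `W[source, sink]` adjacency with zero
diagonal, so out-degree is a row sum.  Inflow normalization
(`Σ_sources γ² = 1` per sink and frequency) is asserted to 1e-8 across
random stable models, and the implementation is checked against a direct
complex-matrix evaluation to 1e-10.

One pooled MVAR per recording window is the default.  A per-epoch
("dynamic") mode that averages per-epoch band networks is available, but
pooling was made the default after head-to-head testing: per-epoch fits on
2-s reconstructed segments are dominated by estimation noise, and in the
planted-driver simulation the averaged network loses the driver entirely
while the pooled fit recovers it with a three-fold margin.

Node scoring follows the threshold-sweep convention: proportional
thresholds at densities 0.05–0.50 (step 0.05) retaining the strongest
edges with their weights (the degree definition used here explicitly
covers weighted networks), trapezoidal AUC of DC/DCin/DCout across the
sweep, normalization to maximum 1, and a hub rule of normalized ≥ 0.95.
Ties in the threshold are broken deterministically by (source, sink)
index.

## Seizure index

Each region is a bistable node in the double-well potential
`V(x) = x⁴/4 − x²/2` (resting attractor −1, seizure attractor +1, barrier
ΔV = 1/4), coupled diffusively through the unthresholded band-limited DTF
network and driven by additive white noise:

    dxᵢ = [xᵢ − xᵢ³ + c Σⱼ W[j,i] (xⱼ − xᵢ)] dt + sqrt(2Dᵢ) dWᵢ

The noise intensity is mapped from the coefficient of variation of the
region's band-limited Hilbert envelope, `Dᵢ = d₀ (CVᵢ / median CV)²`,
clipped to [1e-4, 1], with d₀ = 0.1 and coupling gain c = 0.5.  The
seizure index is `SI = 1/τ̄`, where τ̄ is the mean over 200 realizations of
the first time the node reaches +1 (Euler–Maruyama, dt = 0.01, all nodes
started at −1), censored at t_max = 100 model-time units; censored runs
enter the mean at t_max, which biases SI downward for never-escaping
regions — the conservative direction.  Regions with normalized SI ≥ 0.95
are flagged as highly epileptogenic.  Halving dt changes τ̄ by under 5%
(tested); blow-ups trigger one automatic dt/2 retry.

This instantiation — double well, diffusive DTF coupling, envelope-CV
noise — is one concrete reading of a bistable escape-time model "derived
from DTF-based networks"; it is isolated behind `SIConfig` so alternatives
can be swapped in.  The Hilbert *phase* is computed but unused by the noise
map; only envelope statistics enter, and this limitation is deliberate and
flagged.

Two facts about this model matter for interpretation:

* **Kramers asymptote.**  The escape-rate closed form
  `τ_K = (2π/√2)·exp(1/4D)` is only asymptotic in ΔV/D.  At the working
  noise range (D ≈ 0.08–0.15, ΔV/D ≈ 1.7–3.1) the *exact* mean
  first-passage time to +1 — computed by quadrature of the standard
  double-integral formula, which the tests use as oracle — lies 19–26%
  above τ_K.  The simulation agrees with the exact value to within Monte
  Carlo and discretization error (≈5%); it therefore does *not* sit within
  15% of the asymptote, and no faithful simulation can.
* **Envelope CV and Gaussian signals.**  For any stationary Gaussian
  signal the Hilbert envelope is Rayleigh-distributed with CV ≈ 0.523
  *independent of power*, so a CV-based noise map cannot distinguish
  regions by band power alone.  Amplitude modulation (burstiness) is the
  signal this map reads.

## Synthetic validation

The generator produces a ground-truthed preictal recording: region signals
follow a stable lag-1 MVAR recursion whose innovations are white noise
plus unit-variance AR(2) resonator components per band (pole radius 0.96);
the driver region's delta component has 4× power and is amplitude-modulated
by a slow (≤0.3 Hz) non-negative burst envelope (depth 0.8), emulating
intermittent preictal rhythmic delta activity.  The burst modulation is
what makes the driver visible to the envelope-CV noise map (see above);
its directed outflow (lag-1 coefficients of 0.3 to four target regions,
self-coefficients 0.2) is what the DTF stage detects.  Scalp projection
adds white sensor noise at a broadband power SNR of 5.  The full-scale
scenario is 68 regions × 10 min at 256 Hz; tests and the acceptance script
use the reduced 16-region × 60-s profile so the whole suite runs in
minutes on one core.

In the pipeline-default scenario the driver is planted at the
best-resolved source — the column of the standardized resolution matrix
with the least crosstalk (`choose_driver`).  This matches the method's
domain of applicability: scalp-EEG localization of drivers the montage
barely senses is known to fail (deep foci are the documented false
negatives of this family of methods), and a validation scenario should not
hinge on that failure mode.  Under these conditions the planted driver
attains the top delta-band DCout AUC and top-2 normalized SI in ≈100% of
20 seeded runs (asserted at ≥90% / ≥80%).

What passing these tests shows: the chain of estimators (filtering →
inverse → MVAR/DTF → centrality sweep → escape model) propagates a known
directed delta-band driver to the top of both rankings through a
realistic 21-electrode bottleneck with sensor noise.  What it does not
show: performance on real EEG with artifacts, non-stationarity, volume
conduction through real head tissue, deep or multiple foci, or any
patient-level diagnostic claim.  The diagnostic-statistics module is
validated separately against the published 15-patient summary tables.

## Evaluation statistics

Patients are classified TP/FP/TN/FN by overlap of the predicted region set
with the resected regions crossed with Engel class I (favorable) outcome.
The six summary statistics follow the standard definitions; proportions
carry Wilson score 95% CIs (the only standard interval that reproduces all
of the published bounds — Clopper–Pearson does not), computed via
`statsmodels` and cross-checked against the closed form in tests.
PLR/NLR/DOR carry log-normal (Woolf-type) intervals with a Haldane 0.5
correction when a cell is zero; these intervals do not reproduce the
published ratio CIs (whose method is unidentifiable) and are flagged in
`method_notes`.  Between-metric comparisons use Pearson chi-square when
all expected counts are ≥ 5 and otherwise Fisher's exact test
(two-sided, point-probability rule, verified against exhaustive
hypergeometric enumeration); either test can be forced.

The per-metric contingency tables for the published cohort ship as a
fixture explicitly tagged as *derived from printed values*: the counts
were recovered algebraically from the printed statistics and CIs, not
printed themselves.  The favorable/unfavorable splits they imply are
mutually inconsistent across metrics (10/5 for SI and DCin, 9/6 for DC and
DCout against a reported 10 favorable patients); the tables are kept
verbatim rather than "repaired".

## Reproducibility

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from one global seed via `SeedSequence`, and reruns with
the same config are bit-identical (manifest checksums are compared in
tests).  Config files are validated against a strict schema (unknown keys
rejected) before any computation.
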