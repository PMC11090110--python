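# Methods

This note documents the models implemented in `smflux`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Diffusion-state HMM (`smflux.diffusion_hmm`)

**Model.** A particle switches among K discrete diffusion states following a
first-order Markov chain sampled at the frame interval Δt. In state k each
2D displacement is zero-mean Gaussian with per-axis variance `2 D_k Δt`
(squared step magnitude `r²` exponential with mean `4 D_k Δt`). All
trajectories are analysed jointly; sequences are cut at gap-closed frames so
only consecutive-frame displacements enter the chain.

**Inference.** Maximum-likelihood EM with scaled forward–backward
recursions, batched over trajectories. Diffusion coefficients, fraction
occupancies (expected fraction of steps per state), the per-step transition
matrix, and the initial-state distribution are all estimated; states are
reported sorted by ascending D. The number of states is selected by BIC
over K = 1..K_max with ties toward fewer states. This is a deliberate
simplification of variational-Bayes HMM treatments (vbSPT): on
well-separated states the point estimates coincide, and every piece is
verifiable against closed forms (for K = 1 the estimator reduces exactly to
`Σ‖Δr‖²/(4NΔt)`).

**Localization noise.** By default the emission ignores localization noise,
matching the vbSPT convention; every `D_k` then carries a positive offset of
about `σ_loc²/Δt` (0.004 µm²/s at σ = 20 nm, Δt = 0.1 s) — negligible for
fast states, substantial for confined ones. Passing `loc_sigma` switches to
the noise-corrected emission (per-axis variance `2 D_k Δt + 2σ²`) and
removes the bias. The correction ignores the small negative correlation
between successive observed steps that shared localization errors induce.

**Iterations.** `max_iter` defaults to 200 with relative log-likelihood
tolerance 1e-8. ML-EM sweeps are not comparable to variational iteration
counts quoted for vbSPT-style software; at ~25 sweeps the low-occupancy
confined state is still visibly short of its optimum (its D is ~25% high on
1000-trajectory benchmarks), while convergence is typically reached near
100 sweeps.

**Dwell times and transition rates** are derived from the fitted transition
matrix (`Δt/(1−A_kk)`; `A_jk/Δt`) but are flagged low-confidence: they are
biased by photobleaching truncation, gap handling, and finite trajectory
length in ways the occupancies and D are not.

**Bootstrap.** Uncertainties resample whole trajectories with replacement
(default 100 resamples), refit at fixed K starting from the fitted model,
and report per-state standard deviations after sorting by D.

## Photobleaching step counting (`smflux.photobleach`)

**Corrections.** The excitation field is estimated from the temporal median
of the movie's last 10 frames (most fluorophores are bleached by then),
opened with a disk of radius 8 px (well above the 5 px spot size), and
normalized to unit mean; raw intensities are divided by it. Spot selection
smooths the first frames with a 1 px Gaussian, thresholds at background
median + 3 robust σ, requires each candidate to also pass the same 3σ
criterion on its background-corrected integrated 5×5 intensity (ring-median
background; the shot-noise σ of a 25-pixel sum is 5× the per-pixel σ), and
then removes candidates closer than 0.8 µm to each other or within 0.5 µm
of the image edge. Per-frame local background is the mean of the 4 dimmest
of the 24 pixels in the 7×7 ring around the spot (robust to bright
neighbours, deliberately biased low — which is why the selection step uses
the ring median instead); the corrected spot intensity is
`Σ(inner 5×5) − 25·background`.

**Change points.** Downward steps are detected by recursive binary
segmentation with the Gaussian generalized-likelihood-ratio statistic for a
mean shift: within each segment the maximal standardized difference of
segment means over all admissible split points is compared with a normal
critical value Bonferroni-corrected for the number of candidate splits at
confidence 95% (default). The noise σ is estimated once per trace from the
median absolute successive difference (robust to the steps themselves).
After recursion, each breakpoint is re-tested against its two adjacent
segments only and the weakest insignificant one is pruned iteratively —
recursive splitting alone admits marginal splits at roughly the
per-segment rate. Minimum segment length is 3 frames. Upward shifts
(blinking recovery) are located but excluded from the step list. The
photon-counting change-point variant is a reasonable alternative for
uncorrected camera data; the Gaussian form is appropriate for the
background- and illumination-corrected traces produced here, and its
false-positive rate on pure-noise traces is verified ≤ 5% at 95%
confidence.

**Ensemble statistics.** `I0` is the mean of the first segment; its
ensemble distribution is fit by Gaussian MLE on the samples (histogram-free;
a histogram-based fit is available in figure-parity workflows). `T_pb` is
the time of the last accepted downward step; the lifetime is the
censored/truncated exponential MLE: traces still fluorescent at the movie
end contribute right-censored exposure, traces whose fluorophore bleached
before the first resolvable segment (`min_seg` frames) are left-truncated
and excluded, and the detector reports the first frame after the bleach
(+Δt/2 on average), so callers pass `t_min = (min_seg − 0.5)·Δt`. Against
an oracle reading true bleach times, the pipeline estimator is unbiased to
within 0.2 s at the benchmark conditions; its spread is the intrinsic
`τ/√n` sampling error.

## Brightness mixtures (`smflux.oligomer`)

Per-particle brightnesses are the mean intensities over detections within
the movie's first 20 frames (2 s at 10 fps), before photobleaching erodes
the distribution. A 1- vs 2-component Gaussian mixture is fit by EM; the
monomer mean is softly anchored (10 pseudo-observations) to the
control-protein prior, and the second mean is constrained to 1.5–2.5× the
monomer mean (dimer hypothesis; an unconstrained mode exists). "Area under
each Gaussian" is implemented as the mixture weight — identical for
normalized components.

By default the two components share one coefficient of variation (sd
proportional to mean). This reflects that particle-brightness spread grows
with brightness, and it matters in practice: with free sds the global MLE
of an overlapping mixture can trade weight between components almost
freely (on benchmark samples it drifted by 8 percentage points while
*improving* the likelihood), whereas the tied-CV estimator stays within ~3
points at n = 2000. `tie_cv=False` restores free sds. Model choice is BIC
with a strict-improvement rule, so a pure-monomer sample selects one
component. The oligomer fraction is labelled an upper limit: transient
colocalization of independently diffusing particles is not excluded.

## FCS / dcFCS (`smflux.fcs`)

**Models.** The autocorrelation is the standard 2D anomalous-diffusion form
with one multiplicative dark-state term,
`G(τ) = (1/⟨N⟩)·[1+(τ/τ_D)^α]⁻¹·[1 + f_ds/(1−f_ds)·e^(−τ/τ_ds)]`;
the additive-exponential photophysics convention differs only in amplitude
normalization and can be emulated by reparametrization. The
cross-correlation carries no photophysics term because the two
fluorophores' dark states are uncorrelated:
`G_x(τ) = N_x/(N_g N_r)·[1+(τ/τ_Dx)^α]⁻¹`.

**Fitting.** Weighted least squares (lmfit Levenberg–Marquardt, tolerances
1e-12) restricted to 100 µs – 10 s, which excludes sub-100 µs photophysics
and lags beyond the acquisition. Weights are 1/std per lag when repeat
curves provide one, else uniform. A deterministic grid of starting points
(⟨N⟩ from 1/G(first lag), τ_D from the half-decay lag ×{0.3, 1, 3},
f_ds ∈ {0, 0.2}) makes the fit reproducible with no RNG. α is free in
[0.3, 1.5] by default; fix it at 1 for pure Brownian fits. When τ_ds
approaches τ_D the two decays are inherently degenerate and parameters
trade off at constant residuals; recovery guarantees hold for
τ_D ≳ 10·τ_ds, which the fit window presumes.

**Derived quantities.** `D = w²/4τ_D` with the calibrated beam waist w
(never assumed — calibration uses `w = √(4 D_ref τ_D,ref)` from a reference
dye); surface density `⟨N⟩/(πw²)`. The codiffusion fraction uses fitted
zero-lag amplitudes: `fcd_g = G_x(0)/(G_r(0)·OVCF_g)` and symmetrically for
red, the OVCF dividing the reference-channel amplitude (conventions for
OVCF placement vary; this one is switchable by passing transformed
factors). Because dual labeling is stochastic and binding kinetics differ
between dyes, the smaller of the two fcd values is reported, read as a
lower limit. Dark-state amplitude boosts must not enter the ratio, so
amplitudes are taken from the diffusion part (1/⟨N⟩), not the raw G(0).

## Spot detection and linking (`smflux.spotlink`)

DoG band-pass with σ₁ = d/(2√2·1.6), σ₂ = 1.6σ₁ for estimated diameter d
(0.8 µm default, 0.167 µm pixels); threshold either absolute or a quantile
of the filtered image (the SPT detection threshold is exposed — it is a
per-dataset choice). Sub-pixel positions are intensity-weighted centroids
in a 5×5 window; integrated intensity is median-background-subtracted.
Linking solves, per frame pair, the optimal assignment under squared
displacement cost gated at the 0.5 µm tracking radius, with birth/death
alternatives priced at radius² (the LAP-tracker convention); unmatched
track ends stay alive for the 100 ms gap window. Splitting and merging are
not modelled. Input spot order is canonicalized, so linking is
permutation-invariant. Trajectories shorter than 3 displacements should be
excluded from HMM analysis (estimator stability); the pipeline does this.

## Synthetic data (`smflux.simulate`)

The generator reproduces the statistical structure every analysis stage
assumes:

* **Trajectories** — continuous-time Markov switching (generator matrix Q)
  sampled at Δt; per-state Brownian steps; i.i.d. Gaussian localization
  noise per coordinate (default σ = 20 nm — the imaging study quotes
  localization precision only qualitatively, so this default is a
  placeholder at the typical single-molecule scale); geometric bleach
  truncation with default mean trajectory duration 1.6 s; uniform starting
  positions in a 30×30 µm field. Defaults: 10 fps.
* **Traces** — n fluorophores per particle (configurable distribution),
  common per-fluorophore brightness drawn from N(4.4, 0.88²) kHz,
  independent exponential bleach times (default τ = 14.7 s), optional
  multiplicative illumination field and additive background, Gaussian
  noise σ = 1 kHz, 200 frames at 2 fps. Component brightness CV defaults
  to 20% wherever a spread is needed but unreported.
* **Correlation curves** — evaluated from the very model functions in
  `smflux.fcs` (shared implementation, verified bitwise equal at zero
  noise) on a 160-point log grid over 100 µs – 10 s, with optional
  relative Gaussian noise and per-lag std from repeats.
* **Movies** — pixel-integrated Gaussian PSFs (erf-based), EMCCD-like
  Poisson + Gaussian read noise. The camera noise statistics are not
  published for the source setup; this model is the generic choice and its
  parameters are configurable.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: receptor internalization and membrane
nanodomains, anomalous (non-Markov) motion beyond the α parameter in curve
synthesis, fluorophore blinking within trajectories, detector nonlinearity,
stochastic dual-color labeling competition, and spatial heterogeneity of
diffusion. Parameter-recovery results certify the estimators under the
stated generative model, not the biology.

## Benchmark problem sizes

The recovery suite (`smflux demo`, `scripts/acceptance.py`) uses 1000
trajectories × 20 steps for the HMM, 300 traces for the bleaching ensemble,
2000 samples for the mixtures, and 160-point noiseless curves for FCS —
sizes at which each estimator's sampling error is comfortably inside the
reported uncertainties while a full run stays interactive (~2 s on one
core). At n = 300 the exponential-lifetime MLE has sampling sd ≈ τ/√300
(≈ 1 s), which dominates any pipeline bias.

## Known limitations

* Transition rates/dwell times are reported but low-confidence by design.
* The Gaussian GLR change-point test assumes corrected, roughly
  homoscedastic traces; strongly Poisson-limited data would want the
  counting-statistics variant.
* The two-component mixture stops at dimers; higher oligomers at high
  expression fold into the second component.
* fcd is a lower limit (stochastic labeling), the SPT-derived oligomer
  fraction an upper limit (transient colocalization); the two bracket the
  truth rather than estimate it jointly.
* No 3D models anywhere: membrane (2D) geometry is assumed throughout.
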