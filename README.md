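# smflux

Single-molecule fluorescence analysis of membrane-protein diffusion and
oligomerization.

`smflux` implements the complete analysis chain used to characterize how a
membrane receptor (e.g. a GPCR such as the muscarinic M1 receptor) moves and
assembles in the plasma membrane of live cells, across three expression
regimes:

* **Single-particle tracking (SPT)** at sparse expression: difference-of-
  Gaussians spot detection in TIRF movies, gap-closed trajectory linking by
  optimal bipartite assignment, and hidden-Markov inference of discrete
  diffusion states. The K-state model treats each frame-to-frame
  displacement as zero-mean Gaussian with per-axis variance `2 D_k Δt`;
  EM over all trajectories jointly yields the diffusion coefficients `D_k`,
  fraction occupancies, and the per-step transition matrix, with BIC model
  selection and bootstrap uncertainties.
* **Single-molecule photobleaching (smPB)** in fixed cells: illumination-
  field correction by morphological opening, 3σ spot selection with
  proximity/edge filters, 7×7-ring local background, downward change-point
  (bleach step) detection by a Gaussian generalized-likelihood-ratio test,
  and ensemble fits of the initial brightness `I0` (Gaussian) and
  time-to-photobleaching `T_pb` (censoring-aware exponential MLE).
* **Brightness mixtures**: monomer/oligomer area fractions from a
  two-Gaussian fit of initial particle intensities, anchored to the monomer
  brightness `I_m` of a monomeric control protein.
* **FCS / dual-color FCS** at physiological expression: weighted
  Levenberg–Marquardt fits of

  `G(τ) = (1/⟨N⟩) · [1 + (τ/τ_D)^α]⁻¹ · [1 + f_ds/(1−f_ds) · e^(−τ/τ_ds)]`

  for each autocorrelation channel and
  `G_x(τ) = N_x/(N_g N_r) · [1 + (τ/τ_Dx)^α]⁻¹` for the cross-correlation,
  over the 100 µs – 10 s window; `D = w²/4τ_D`, surface density
  `⟨N⟩/(πw²)`, and the codiffusion (oligomer) fraction
  `fcd = G_x(0)/(G_ref(0)·OVCF)` with the smaller of the two channel values
  reported as a lower limit.

A first-class synthetic-data generator (`smflux.simulate`) produces
multi-state Brownian trajectories, stepwise-bleaching intensity traces,
correlation curves, brightness mixtures, and rendered TIRF-like movies with
ground truth, so every stage is testable end to end without raw microscope
data.

## Worked example

The `demo` verb simulates data at the study conditions of each stage and
recovers the generative parameters:

```sh
$ smflux demo --seed 1
hmm_fast_D_um2_s: 0.1484
hmm_fast_occupancy_pct: 73.3691
smpb_I0_center_kHz: 4.3759
smpb_tau_pb_s: 14.5226
control_tau_pb_s: 19.5568
mixture_oligomer_pct: 26.3969
mixture_dimer_mean_kHz: 8.0613
mixture_low_monomer_pct: 84.8078
fcs_D_um2_s: 0.0890
fcs_dark_fraction: 0.3700
dcfcs_fcd_min_pct: 50.0000
```

Reading the output: 1000 three-state trajectories were simulated with a fast
state at `D₃ = 0.144 µm²/s` occupied 73% of the time, and the 3-state HMM
recovered `0.148 µm²/s` at 73.4% occupancy. 300 single-fluorophore bleaching
traces generated with brightness 4.4 kHz and lifetime 14.7 s (plus a
CD86-like control at 18.0 s) came back as 4.38 kHz / 14.5 s (control
19.6 s). A 27%-dimer brightness mixture (components 4.6 / 8.0 kHz) was fit
to a 26.4% oligomer fraction with dimer mean 8.06 kHz; a 86%-monomer
low-expression mixture to 84.8% monomeric. A noiseless autocorrelation
synthesized for `D = 0.089 µm²/s` (w = 0.25 µm) refit exactly, as did a
curve with the red-fluorophore dark state (`f_ds = 0.37`, `τ_ds = 2.7 ms`);
amplitudes built with half the molecules codiffusing gave
`fcd_min = 50.0%`.

Other CLI verbs operate on standard files:

```sh
smflux track movie.tif --pixel 0.167 --dt 0.1 --radius 0.5 --max-gap 0.1
smflux hmm trajectories.csv --dt 0.1 --kmax 5 --boot 100 --seed 1
smflux smpb fixed_cells.tif --fps 2 --confidence 0.95
smflux fcs fit curve.g --w 0.25
smflux fcs fcd curve.g curve.r curve.x --ovcf-g 0.9 --ovcf-r 0.9
smflux oligomer trajectories.csv --monomer-mean 4.3 --monomer-sd 0.9
smflux run config.yaml          # multi-stage pipeline with JSON manifest
```

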