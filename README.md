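# hpwhmm

Bayesian segmentation of single-particle tracking (SPT) trajectories into
free diffusion and transient confinement, with full profiling of the
detected confinement events.

High-speed SPT (e.g. interferometric scattering microscopy of
nanoparticle-tagged membrane lipids, kHz frame rates, nm localization)
shows particles alternating between free Brownian motion and trapping in
nanoscale zones.  Plain diffusivity-switching HMMs often cannot segment
such data because the effective diffusion coefficient barely changes
during trapping; what changes is the *restoring force*.  `hpwhmm`
implements a hidden Markov model whose confined state is an
Ornstein–Uhlenbeck (OU) process in a harmonic potential well:

- hidden binary state `z_i` (free / confined) with per-frame switching
  probabilities `p_trap`, `p_esc`;
- free state: `X_{i+1} − X_i ~ N(0, 2·D·Δt)` per coordinate;
- confined state (exact OU step):
  `X_{i+1} − X_i ~ N((C_i − X_i)(1 − e^{−κΔt}), (D/κ)(1 − e^{−2κΔt}))`;
- latent well center: `C_{i+1} − C_i ~ N(0, 2Δt(DC·z_i + Dest(1 − z_i)))`.

A blocked Gibbs / Metropolis sampler (forward-filter backward-sampling for
both the states and the centers, exact joint single-site and window moves,
conjugate draws for `D`, `DC` and the switching probabilities, Metropolis
on log κ) yields the joint posterior of all five parameters and the hidden
paths from a single trajectory.  Convergence is certified by the
Gelman–Rubin PSRF across independent chains (threshold 1.2, run doubling
up to 4×10⁵ sweeps).  Thresholding the per-frame confinement probability
at 0.5 turns the posterior into confinement events, which are profiled by
lifetime (exponential-mixture fits, Q-Q R²), radial shape statistics
(mean radius, radial skewness, mean–median distance, radial SD),
repeat-site detection (30 nm rule), across-trajectory heterogeneity tests
and within-trajectory conservation clustering (k-means++ / Shannon
diversity).  See `docs/methods.md` for the full model account.

## Worked example

Simulate a 3000-frame trajectory at 5 kHz (D = 0.5 µm²/s, κ = 3000 s⁻¹,
DC = 0.01 µm²/s, p_esc = 0.001, p_trap = 0.002), fit it with three chains,
and extract events:

```sh
hpwhmm simulate --n-frames 3000 --seed 7 --out-prefix demo
hpwhmm fit demo.traj.tsv --chains 3 --sweeps 2000 --burn-in 1000 \
    --seed 8 --out-prefix demo
hpwhmm events demo.traj.tsv demo.states.tsv --out demo.events.tsv
```

The fit prints the per-parameter PSRF and converges at the first stage:

```
PSRF[D] = 1.0122
PSRF[DC] = 1.0375
PSRF[kappa] = 1.0579
PSRF[p_esc] = 1.0629
PSRF[p_trap] = 1.0884
converged after 2000 sweeps per chain
```

Posterior summaries from `demo.params.tsv` (mean and central 95% interval;
simulation truth in brackets):

```
D      0.488  [0.470, 0.508]   (0.5   µm²/s)
DC     0.011  [0.006, 0.020]   (0.01  µm²/s)
kappa  2727   [1696, 3345]     (3000  s⁻¹)
p_esc  0.0083 [0.0021, 0.0182] (0.001)
p_trap 0.0017 [0.0003, 0.0043] (0.002)
```

The thresholded states agree with the simulation truth on 97.3% of frames,
and `demo.events.tsv` contains the trajectory's single confinement event —
478 frames (0.0956 s, censored at the trajectory start), mean confinement
radius 33 nm, radial skewness 0.36:

```
trajectory_id  start_frame  end_frame  lifetime_s  touches_boundary  mean_radius_um  radial_skewness
demo.traj      0            477        0.0956      True              0.0330          0.363
```

`hpwhmm events` also reports the fraction of frames with uncertain state
probability (between 0.2 and 0.8) — 3.9% here, i.e. the segmentation is
confident almost everywhere.  With several event tables,
`hpwhmm report` aggregates lifetimes and shapes into mixture fits,
heterogeneity tests and conservation-clustering curves.

The same pipeline is available as a library
(`hpwhmm.simulate`, `hpwhmm.run_chain`, `hpwhmm.run_until_converged`,
`hpwhmm.events`), which is what the test suite and the acceptance script
use.

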