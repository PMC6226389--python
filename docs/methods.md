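# Methods

## The model

A tracked particle in a 2D membrane switches between two hidden states:
free Brownian diffusion (`z = 0`) with diffusivity `D` (μm²/s), and
confinement (`z = 1`) in a harmonic potential well centered at a latent
position `C` that itself diffuses slowly (diffusivity `DC` while the
particle is confined).  While the particle is free, the center keeps
diffusing with a larger diffusivity `Dest` so that it can relocate between
confinement sites; it simply does not enter the particle's dynamics then.
State switching is a first-order Markov chain with per-frame trapping and
escape probabilities `p_trap` and `p_esc`.

Confined motion is an Ornstein–Uhlenbeck (OU) process with mean-reversion
rate `kappa` (1/s).  The discrete-time transition uses the *exact* OU
solution: over a step `dt` the particle covers a fraction
`beta = 1 − e^{−kappa·dt}` of its distance to the center, with
per-coordinate variance `(D/kappa)(1 − e^{−2·kappa·dt})`.  At the reference
conditions (`kappa·dt = 0.6`) the frame-to-frame displacement is comparable
to the well radius `sqrt(D/kappa)` (≈13 nm), so an Euler–Maruyama
discretization would be visibly biased; the exact step is essential.
Free steps are zero-mean Gaussian with per-coordinate variance `2·D·dt`.
Center steps are zero-mean Gaussian with variance `2·DC·dt` (confined) or
`2·Dest·dt` (free).  Both coordinates are independent (isotropic well).

The initial state carries a uniform Bernoulli(0.5) law — the model never
specifies it otherwise, and for trajectories of thousands of frames its
influence is negligible; the likelihood conditions on the first observed
position, which makes everything translation invariant.

## Reference conditions

The simulator's defaults are the validation conditions used throughout:
`D = 0.5 μm²/s`, `DC = 0.01 μm²/s`, `Dest = 0.5 μm²/s`, `kappa = 3000 /s`,
`p_esc = 0.001`, `p_trap = 0.002`, `N = 5000` frames at `dt = 2×10⁻⁴ s`
(a 5 kHz track, i.e. a 50 kHz acquisition decimated tenfold to suppress
motion-blur correlation).  At stationarity the chain spends
`p_trap/(p_trap + p_esc) = 2/3` of its time confined.  A printed source
value of "2×10⁴ s" for this time step is treated as a typo for 2×10⁻⁴ s;
every other quoted rate (5 kHz subsampled from 50 kHz) confirms it.

During simulation only, the free-state center follows the particle through
an extra Euler drift `alpha·dt·(X − C)` with `alpha = 1/(50·dt)` (a
50-frame relaxation time), so that confinement onsets occur near the
particle.  The drift is deliberately absent from the inference model —
center diffusion alone suffices for the posterior to find high-probability
center paths — and parameter recovery is insensitive to its exact value.
Static localization noise, when requested, is added to the full-rate track
before decimation, matching the acquisition order of real experiments.

## Inference

The joint posterior π(θ, z, C | X) is sampled by a blocked Gibbs sweep;
every update is an exact draw from its full conditional:

1. **Centers** `C` — per-coordinate scalar Kalman forward filter and
   backward sampler.  During confined increments the rescaled displacement
   `y_i = X_i + ΔX_i/beta_i` observes `C_i` with variance
   `(D/kappa)(1−e^{−2·kappa·dt})/beta_i²`; during free increments the center
   evolves unobserved.  The first center carries a diffuse Gaussian prior
   (variance 10⁴ μm²) centered on the first observation.
2. **States** `z` — discrete forward-filter backward-sampler over the
   2-state chain, with per-increment emission equal to the particle
   displacement density times the center displacement density.
3. **Window nucleation** — a Metropolis pass proposing to flip entire
   uniform-state windows (50 increments, alignment rotating across sweeps)
   wholesale, with the center path integrated out analytically over the
   window *and its adjoining free runs*, anchored at the nearest confined
   centers.  Free centers carry no observations, so a distant anchor
   contributes accumulated random-walk variance rather than vetoing the
   proposal; the acceptance ratio is the exact marginal ratio, and on
   acceptance the region's centers are redrawn from their conditional.
   This is the only move that can *create* a confinement event in the
   middle of a long free stretch (or dissolve a spurious one) at a useful
   rate.
4. **Pair refinement** — one sequential pass of exact joint `(z_j, C_j)`
   single-site draws, integrating `C_j` out analytically when choosing
   `z_j` (direction alternates between sweeps).  This move also matters:
   in the two blocked updates above, the center-increment variance
   mismatch between states (`Dest/DC = 50`) effectively vetoes flipping
   any frame whose center step was drawn under the other state, so a
   confinement boundary in the wrong place would creep at only ~1 frame
   per hundred sweeps.  With `C_j` marginalized the boundary moves freely
   and misplaced segments cascade away within a few sweeps.  All these
   moves are exact conditional draws or valid Metropolis updates, so the
   posterior remains invariant; a Geweke-style successive-conditional test
   in the suite checks the whole sweep.
5. **Diffusivities** — `D` and `DC` have inverse-gamma full conditionals
   (displacement variances are linear in them); each 2D increment
   contributes one unit of shape.
6. **Well strength** — Metropolis random walk on `log kappa`.  The proposal
   SD is adapted toward a 25–40% acceptance rate during burn-in only, then
   frozen, preserving detailed balance for all retained samples.
7. **Switching probabilities** — conjugate Beta updates from the transition
   counts of `z`.

Priors: inverse-gamma(0.001, 0.001) for `D` and `DC` (near-flat),
log-uniform `kappa` on [1, 10⁶] s⁻¹, and informative Beta(1, 50) for both
switching probabilities (mean ≈ 0.02) to discourage frame-level state
flicker.  All are configurable.  `Dest` is an algorithm parameter, not
inferred; by default it tracks the current sample of `D`, which keeps it
high enough for center relocation, and estimates are unchanged (≲2%
observed) across a decade of fixed `Dest` values.

Initialization is deterministic and data-driven: a two-means split of the
windowed local diffusivity labels provisional confined frames (only when
the cluster means are separated by ≥1.25×, and dropping runs shorter than
half a window — a conservative start that keeps the center path from
latching onto genuinely free segments), the center starts at a 50-frame
running mean of the positions, and parameters come from method-of-moments
on that segmentation.  The first sweep updates `C | z` before `z | C`.

Numerical guards: log-domain HMM filtering; a 10⁻¹² μm² variance floor in
all Kalman recursions (active only when `DC` is sampled extremely small);
conditional draws from the near-flat inverse-gamma priors are clipped to
[10⁻¹⁰, 10⁴] μm²/s (relevant only when a trajectory has no confined
increments and `DC` reverts to its prior, which is logged).

## Convergence protocol

Five independent chains of 2000 sweeps with a 1000-sweep burn-in are the
default.  Convergence requires the Gelman–Rubin potential scale reduction
factor `sqrt((n−1)/n + B/(nW))` of each of the five scalar parameters to
fall below 1.2.  Per-frame states are not monitored: a PSRF of a
near-binary chain is ill-defined, and the five parameters summarize the
same information.  Failed runs are re-run at doubled length (burn-in =
first half, standard split practice) up to 4×10⁵ sweeps, after which the
trajectory is flagged for exclusion rather than raising.

## Event profiling

The per-frame confinement probability π(z_i | X) (the posterior mean of
z_i) is thresholded at 0.5 — ties count as free, a conservative choice that
is measure-zero in practice.  Maximal runs of ones are confinement events.
Each state index covers one increment `[t_i, t_{i+1}]`, so an event over
state indices a..b has lifetime `t_{b+1} − t_a`: a 50-frame event at 5 kHz
lasts exactly 0.01 s, and lifetimes partition the trajectory duration.
Lifetime analyses exclude events touching either end of the trajectory
(their duration is censored); shape analyses keep them but require at
least 0.01 s (50 frames).

Shape statistics use the radii `R_i = ‖X_i − C̄‖` about the event's mean
posterior center: mean radius, radial skewness (population moment
convention), |mean − median| distance, and the radial SD.  A label printed
as "var[R]" in the source's statistic table is implemented as the standard
deviation — the name wins over the formula — with the variance also
exposed.  An isotropic Gaussian occupation profile gives Rayleigh radii
with skewness `2√π(π−3)/(4−π)^{3/2} ≈ 0.63`; larger values indicate
heavier-tailed, non-Gaussian confinement.  An event whose mean center lies
within 30 nm of *any* earlier event's center in the same trajectory is
flagged as a repeat visit; analyses can include or exclude repeats.

Lifetime populations are fit by maximum likelihood with one exponential
(closed form) or a two-exponential mixture (EM to relative tolerance 10⁻⁸,
best of 20 restarts, one of them started at the nested single-exponential
solution so the 2-component fit never scores below the 1-component MLE).
Q-Q goodness against a reference distribution or sample is summarized by
R² about the line through the first and third quartile points; gross
misfit can push R² to zero or below, which is informative and preserved.
Heterogeneity across trajectories uses Kruskal–Wallis (lifetimes) and
one-way ANOVA (shape statistics).  Within-trajectory conservation is
quantified by k-means++ clustering of the standardized statistic (50
restarts) and the summed Shannon diversity `H_l = −Σ p_j log p_j` of each
trajectory's cluster occupancies, averaged over restarts; statistics are
standardized even when clustering on one of them so that values are
comparable across statistics with different units.

The windowed local diffusivity estimate (default 100 frames, centered,
truncated at the edges) is the 2D Brownian MLE `Σ‖ΔX‖²/(4·M·dt)`; it is
model-free and serves as an independent check on inferred state changes.

## What the synthetic data does and does not emulate

The generator reproduces the switching OU dynamics, the static localization
error, and the acquisition-then-decimation order of real high-speed
nanoparticle tracking.  It does not emulate motion-blur (dynamic) error,
anisotropic or multi-well confinement, tag-geometry effects, or
heterogeneity across trajectories (every simulated trajectory shares one
parameter set unless varied explicitly).  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated model,
not robustness to every artifact of real data.

## Known limitations and observed behaviour

- Measurement noise is not part of the emission model.  Under added static
  noise the full joint fit *overestimates* `kappa` (the apparent free
  diffusivity inflates by `sd²/dt`, and noise anti-correlates successive
  displacements with the apparent distance to the center); holding states
  and centers at truth isolates the opposite, variance-driven
  underestimation.  Both trends are computed by the acceptance script.
  Data noisier than a few nm at 5 kHz needs a noise-augmented emission
  model, which is out of scope here.
- Inference degrades as `DC` approaches ~10% of `D`: the posterior SD of
  `kappa` grows steeply (the well becomes indistinguishable from slow
  free diffusion).  This degeneracy is a property of the model, not the
  sampler.
- Short events near the information limit may be honestly undetected:
  a ~50-frame event whose likelihood evidence barely exceeds the
  switching penalty can have posterior confinement probability below the
  0.5 threshold everywhere.  Detection probability rises quickly with
  event duration; events of a few hundred frames are detected essentially
  always at the reference conditions.
- A single latent well center is maintained; adjacent simultaneous wells
  (hop diffusion) require a different model.
- Problem sizes in the test suite and acceptance script (10–20 trajectories
  of 2000–5000 frames, 2–5 chains) were chosen to exercise the full
  reference protocol at single-workstation scale.
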