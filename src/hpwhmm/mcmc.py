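"""Blocked-Gibbs sampler for the joint posterior pi(theta, z, C | X).

One sweep updates, in order: the state path z by discrete forward-filter
backward-sampling (FFBS), the center path C by per-coordinate scalar Kalman
FFBS, the diffusivities D and DC by conjugate inverse-gamma draws, the well
strength kappa by a Metropolis step on log(kappa), and the switching
probabilities by conjugate Beta draws.  Every update is exact for its full
conditional, so the sweep leaves the posterior invariant.

Priors are near-flat for D, DC (inverse-gamma) and kappa (log-uniform); the
switching probabilities get an informative Beta prior that discourages
rapid state flickering.  The free-state center diffusivity ``Dest`` is an
algorithm parameter, not inferred: by default it tracks the current sample
of D, which keeps it "sufficiently high" for the center to relocate between
confinement sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._kernels import (
    build_arrays,
    diffusivity_sums,
    ffbs_binary,
    kalman_ffbs,
    kappa_loglik_confined,
    pair_gibbs_pass,
    state_emissions,
    window_flip_pass,
)
from .model import HPWParams, Trajectory

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "sample_states",
    "sample_centers",
    "sample_diffusivities",
    "sample_kappa",
    "sample_switching",
    "run_chain",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

# numerical guards on conditional draws from near-flat priors
_DIFFUSIVITY_DRAW_BOUNDS = (1e-10, 1e4)
_PROB_EPS = 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    D and DC carry inverse-gamma(shape, rate) priors (defaults near-flat);
    kappa is log-uniform on [kappa_min, kappa_max]; the switching
    probabilities carry informative Beta(a, b) priors with mean
    a / (a + b) ~ 0.02, which restricts rapid switching while remaining
    weaker than the data for trajectories with thousands of frames.
    """

    D_shape: float = 0.001
    D_rate: float = 0.001
    DC_shape: float = 0.001
    DC_rate: float = 0.001
    kappa_min: float = 1.0
    kappa_max: float = 1e6
    pesc_a: float = 1.0
    pesc_b: float = 50.0
    ptrap_a: float = 1.0
    ptrap_b: float = 50.0

    def __post_init__(self) -> None:
        vals = [
            self.D_shape, self.D_rate, self.DC_shape, self.DC_rate,
            self.kappa_min, self.kappa_max,
            self.pesc_a, self.pesc_b, self.ptrap_a, self.ptrap_b,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all hyperparameters must be positive")
        if not self.kappa_min < self.kappa_max:
            raise ValueError("kappa_min must be below kappa_max")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws and derived per-frame summaries.

    ``state_prob[i]`` is the posterior confinement probability
    pi(z_i | X), i.e. the mean of z_i over the retained samples; ``mean_C``
    is the posterior-mean center path.  ``z_samples`` holds the full hidden
    paths only when the chain was run with ``store_paths=True``.
    """

    D: np.ndarray
    DC: np.ndarray
    kappa: np.ndarray
    p_esc: np.ndarray
    p_trap: np.ndarray
    chain: np.ndarray
    state_prob: np.ndarray
    mean_C: np.ndarray
    kappa_acceptance: float = float("nan")
    z_samples: np.ndarray | None = None

    PARAM_NAMES = ("D", "DC", "kappa", "p_esc", "p_trap")

    @property
    def n_samples(self) -> int:
        return self.D.size

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": self.chain,
                "D": self.D,
                "DC": self.DC,
                "kappa": self.kappa,
                "p_esc": self.p_esc,
                "p_trap": self.p_trap,
            }
        )

    def credible_interval(self, name: str, level: float = 0.95):
        draws = getattr(self, name)
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(draws, [lo, 1.0 - lo]))

    @classmethod
    def pool(cls, parts: list["PosteriorSamples"]) -> "PosteriorSamples":
        """Pool retained samples from several chains (sample-count weighted)."""
        if not parts:
            raise ValueError("nothing to pool")
        ks = np.array([p.n_samples for p in parts], dtype=float)
        w = ks / ks.sum()
        zs = None
        if all(p.z_samples is not None for p in parts):
            zs = np.concatenate([p.z_samples for p in parts], axis=0)
        return cls(
            D=np.concatenate([p.D for p in parts]),
            DC=np.concatenate([p.DC for p in parts]),
            kappa=np.concatenate([p.kappa for p in parts]),
            p_esc=np.concatenate([p.p_esc for p in parts]),
            p_trap=np.concatenate([p.p_trap for p in parts]),
            chain=np.concatenate([p.chain for p in parts]),
            state_prob=np.einsum(
                "c,ci->i", w, np.stack([p.state_prob for p in parts])
            ),
            mean_C=np.einsum(
                "c,cij->ij", w, np.stack([p.mean_C for p in parts])
            ),
            kappa_acceptance=float(
                np.average([p.kappa_acceptance for p in parts], weights=ks)
            ),
            z_samples=zs,
        )


def sample_states(
    traj: Trajectory,
    C: np.ndarray,
    params: HPWParams,
    rng: np.random.Generator,
    arrays: "SweepArrays | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw z from its full conditional given C and the parameters.

    The per-increment emission multiplies the particle displacement density
    by the center displacement density (the latter exists for all but the
    final increment).  Returns ``(z, filtered_p1)``.
    """
    a = arrays if arrays is not None else _sweep_arrays(traj, params)
    log_b = state_emissions(
        a.y, a.r, a.log_jac, a.lp_free, a.q_conf, a.q_free,
        np.ascontiguousarray(C, dtype=float),
    )
    u = rng.random(a.r.shape[0])
    return ffbs_binary(log_b, a.trans, 0.5, u)


def sample_centers(
    traj: Trajectory,
    z: np.ndarray,
    params: HPWParams,
    rng: np.random.Generator,
    c1_prior_mean: np.ndarray | None = None,
    c1_prior_var: float = 1e4,
    arrays: "SweepArrays | None" = None,
) -> np.ndarray:
    """Draw the center path C from its linear-Gaussian full conditional.

    During confined increments the (rescaled) displacement observes C_i with
    Gaussian noise; during free increments C diffuses unobserved with
    diffusivity Dest.  Each coordinate is filtered and backward-sampled
    independently.  The first center carries a diffuse Gaussian prior
    centered on the first observed position unless overridden.
    """
    a = arrays if arrays is not None else _sweep_arrays(traj, params)
    z = np.asarray(z)
    m = a.r.shape[0]
    obs = z == 1
    q = np.where(z[:-1] == 1, a.q_conf[:-1], a.q_free[:-1])
    if c1_prior_mean is None:
        c1_prior_mean = traj.positions[0]

    C = np.empty((m, 2))
    for k in range(2):
        normals = rng.standard_normal(m)
        C[:, k] = kalman_ffbs(
            np.ascontiguousarray(a.y[:, k]),
            a.r,
            obs,
            q,
            float(c1_prior_mean[k]),
            float(c1_prior_var),
            normals,
        )
    return C


def refine_pairs(
    traj: Trajectory,
    z: np.ndarray,
    C: np.ndarray,
    params: HPWParams,
    rng: np.random.Generator,
    forward: bool = True,
    c1_prior_var: float = 1e4,
    arrays=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One sequential pass of exact joint (z_j, C_j) single-site updates.

    Complements the blocked FFBS moves: because C_j is integrated out when
    z_j is drawn, a confinement boundary sitting in the wrong place can move
    frame by frame (and cascade along the pass) without being vetoed by the
    center-increment term.  Returns the updated (z, C); updates are exact
    Gibbs draws, so the posterior is left invariant.
    """
    m = traj.n_frames - 1
    a = arrays if arrays is not None else _sweep_arrays(traj, params)
    z = np.ascontiguousarray(z, dtype=np.int8)
    C = np.ascontiguousarray(C, dtype=float)
    pair_gibbs_pass(
        z, C, a.y, a.r, a.log_jac, a.lp_free, a.q_conf, a.q_free, a.trans,
        traj.positions[0].astype(float), float(c1_prior_var),
        rng.random(m), rng.standard_normal((m, 2)), forward,
    )
    return z, C


class SweepArrays(NamedTuple):
    """Per-increment quantities shared by the within-sweep moves."""

    y: np.ndarray
    r: np.ndarray
    log_jac: np.ndarray
    lp_free: np.ndarray
    q_conf: np.ndarray
    q_free: np.ndarray
    beta: np.ndarray
    g_conf: np.ndarray
    trans: np.ndarray


def _sweep_arrays(traj: Trajectory, params: HPWParams) -> SweepArrays:
    y, r, log_jac, lp_free, q_conf, q_free, beta, g_conf = build_arrays(
        traj.dts, traj.displacements, traj.positions[:-1],
        params.D, params.DC, params.Dest, params.kappa,
    )
    trans = np.array(
        [
            [1.0 - params.p_trap, params.p_trap],
            [params.p_esc, 1.0 - params.p_esc],
        ]
    )
    return SweepArrays(y, r, log_jac, lp_free, q_conf, q_free, beta, g_conf, trans)


def flip_windows(
    traj: Trajectory,
    z: np.ndarray,
    C: np.ndarray,
    params: HPWParams,
    rng: np.random.Generator,
    window: int = 50,
    offset: int = 0,
    c1_prior_var: float = 1e4,
    arrays=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis pass proposing whole-window state flips.

    Each uniform-state window of ``window`` increments is proposed flipped
    wholesale, with the centers integrated out over the window and its
    adjoining free runs (the acceptance ratio is the exact marginal ratio)
    and redrawn from their conditional on acceptance.  This is the
    sampler's nucleation move: it can seed a new confinement event inside
    a free stretch, or dissolve a spurious one, in a single accepted
    proposal.
    """
    m = traj.n_frames - 1
    a = arrays if arrays is not None else _sweep_arrays(traj, params)
    z = np.ascontiguousarray(z, dtype=np.int8)
    C = np.ascontiguousarray(C, dtype=float)
    n_windows = m // window + 2
    window_flip_pass(
        z, C, a.y, a.r, a.log_jac, a.lp_free, a.q_conf, a.q_free, a.trans,
        traj.positions[0].astype(float), float(c1_prior_var),
        window, offset % window,
        rng.random(n_windows), rng.standard_normal((m, 2)),
        np.empty((m, 2)), np.empty(m),
    )
    return z, C


def _invgamma_draw(
    shape: float, rate: float, rng: np.random.Generator
) -> float:
    # gamma draws at tiny shape can underflow to exactly 0
    return rate / max(rng.gamma(shape), 1e-300)


def sample_diffusivities(
    traj: Trajectory,
    z: np.ndarray,
    C: np.ndarray,
    kappa: float,
    priors: PriorSpec,
    rng: np.random.Generator,
    arrays: "SweepArrays | None" = None,
) -> tuple[float, float]:
    """Conjugate inverse-gamma draws of D and DC.

    The particle displacement variance is linear in D in both states
    (2*dt free; (1/kappa)(1 - e^{-2 kappa dt}) confined), and confined
    center increments have variance 2*DC*dt, so both conditionals are
    inverse-gamma.  Each 2D increment contributes two half-degrees of
    freedom, i.e. one unit of shape.
    """
    dts = traj.dts
    m = dts.size
    z = np.ascontiguousarray(z, dtype=np.int8)
    C = np.ascontiguousarray(C, dtype=float)
    if arrays is not None:
        beta, g_conf = arrays.beta, arrays.g_conf
    else:
        beta = -np.expm1(-kappa * dts)
        g_conf = -np.expm1(-2.0 * kappa * dts) / kappa
    rate_d_sum, n_conf, rate_dc_sum = diffusivity_sums(
        z, C, traj.positions[:-1], traj.displacements, dts, beta, g_conf
    )
    d_shape = priors.D_shape + m
    d_rate = priors.D_rate + rate_d_sum
    D = _invgamma_draw(d_shape, d_rate, rng)

    if n_conf == 0:
        logger.debug("no confined center increments; DC drawn from its prior")
        DC = _invgamma_draw(priors.DC_shape, priors.DC_rate, rng)
    else:
        DC = _invgamma_draw(
            priors.DC_shape + n_conf, priors.DC_rate + rate_dc_sum, rng
        )

    lo, hi = _DIFFUSIVITY_DRAW_BOUNDS
    return float(np.clip(D, lo, hi)), float(np.clip(DC, lo, hi))


def sample_kappa(
    traj: Trajectory,
    z: np.ndarray,
    C: np.ndarray,
    D: float,
    priors: PriorSpec,
    rng: np.random.Generator,
    kappa: float,
    step_sd: float = 0.5,
) -> tuple[float, bool]:
    """Metropolis random-walk update of kappa on the log scale.

    The prior is log-uniform on [kappa_min, kappa_max] (flat in log kappa),
    so with a symmetric Gaussian proposal in log space the acceptance ratio
    is the likelihood ratio over confined increments.  With no confined
    increments the draw comes straight from the prior.
    """
    z = np.ascontiguousarray(z, dtype=np.int8)
    if not z.any():
        log_k = rng.uniform(
            np.log(priors.kappa_min), np.log(priors.kappa_max)
        )
        return float(np.exp(log_k)), True

    C = np.ascontiguousarray(C, dtype=float)
    X = traj.positions[:-1]
    dX = traj.displacements
    dts = traj.dts

    log_k = np.log(kappa)
    log_k_new = log_k + step_sd * rng.standard_normal()
    if not (
        np.log(priors.kappa_min) <= log_k_new <= np.log(priors.kappa_max)
    ):
        return kappa, False
    ll_old = kappa_loglik_confined(z, X, dX, C, dts, D, kappa)
    ll_new = kappa_loglik_confined(
        z, X, dX, C, dts, D, float(np.exp(log_k_new))
    )
    if np.log(rng.random()) < ll_new - ll_old:
        return float(np.exp(log_k_new)), True
    return kappa, False


def sample_switching(
    z: np.ndarray, priors: PriorSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Conjugate Beta draws of the switching probabilities from z's counts."""
    z = np.asarray(z)
    z0, z1 = z[:-1], z[1:]
    n01 = int(np.sum((z0 == 0) & (z1 == 1)))
    n00 = int(np.sum((z0 == 0) & (z1 == 0)))
    n10 = int(np.sum((z0 == 1) & (z1 == 0)))
    n11 = int(np.sum((z0 == 1) & (z1 == 1)))
    p_trap = rng.beta(priors.ptrap_a + n01, priors.ptrap_b + n00)
    p_esc = rng.beta(priors.pesc_a + n10, priors.pesc_b + n11)
    p_esc = float(np.clip(p_esc, _PROB_EPS, 1.0 - _PROB_EPS))
    p_trap = float(np.clip(p_trap, _PROB_EPS, 1.0 - _PROB_EPS))
    return p_esc, p_trap


def _two_means_states(
    est: np.ndarray, min_run: int, min_separation: float = 1.25
) -> np.ndarray:
    """Provisional confined labels from a 1D two-means split of local D.

    Lloyd iterations on the local-diffusivity values; the lower cluster is
    labelled confined only if the cluster means differ by at least
    ``min_separation`` (ratio), and confined runs shorter than ``min_run``
    are reset to free.  Deterministic.
    """
    x = np.asarray(est, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo * min_separation:
        return np.zeros(x.size, dtype=np.int8)
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new_c = np.array(
            [
                x[assign == k].mean() if np.any(assign == k) else c[k]
                for k in range(2)
            ]
        )
        if np.allclose(new_c, c):
            break
        c = new_c
    if c.max() <= c.min() * min_separation:
        return np.zeros(x.size, dtype=np.int8)
    z = (assign == int(np.argmin(c))).astype(np.int8)
    # drop short confined runs: likely windowing noise, not events
    i = 0
    while i < z.size:
        if z[i] == 1:
            j = i
            while j < z.size and z[j] == 1:
                j += 1
            if j - i < min_run:
                z[i:j] = 0
            i = j
        else:
            i += 1
    return z


def initialize(
    traj: Trajectory, priors: PriorSpec
) -> tuple[HPWParams, np.ndarray, np.ndarray]:
    """Deterministic data-driven starting point for a chain.

    States come from a two-means split of the windowed local diffusivity:
    frames in the lower cluster are provisionally confined, but only when
    the clusters are meaningfully separated, and confined runs shorter than
    half a window are discarded (a conservative start keeps the center path
    from latching onto genuinely free segments).  Centers start at a running
    mean of the positions; parameters by method of moments from the
    provisional segmentation.
    """
    from .events import local_diffusivity

    m = traj.n_frames - 1
    window = min(50, m)
    est = local_diffusivity(traj, window=window)
    z0 = _two_means_states(est, min_run=window // 2)

    C0 = (
        pd.DataFrame(traj.positions)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()[:m]
    )

    dts = traj.dts
    dX = traj.displacements
    free = z0 == 0
    sq = np.sum(dX * dX, axis=1)
    if free.any():
        D0 = float(np.sum(sq[free]) / (4.0 * np.sum(dts[free])))
    else:
        D0 = float(np.sum(sq) / (4.0 * np.sum(dts)))
    D0 = max(D0, 1e-8)

    conf = ~free
    if conf.any():
        dev = traj.positions[:-1] - C0
        v_hat = float(np.mean(np.sum(dev[conf] * dev[conf], axis=1)) / 2.0)
        kappa0 = D0 / max(v_hat, 1e-10)
    else:
        kappa0 = np.sqrt(priors.kappa_min * priors.kappa_max)
    kappa0 = float(np.clip(kappa0, priors.kappa_min, priors.kappa_max))

    z0_, z1_ = z0[:-1], z0[1:]
    n01 = np.sum((z0_ == 0) & (z1_ == 1))
    n00 = np.sum((z0_ == 0) & (z1_ == 0))
    n10 = np.sum((z0_ == 1) & (z1_ == 0))
    n11 = np.sum((z0_ == 1) & (z1_ == 1))
    p_trap0 = float(np.clip((n01 + 1.0) / (n00 + n01 + 2.0), 1e-5, 0.3))
    p_esc0 = float(np.clip((n10 + 1.0) / (n10 + n11 + 2.0), 1e-5, 0.3))

    params = HPWParams(
        D=D0,
        DC=max(0.02 * D0, 1e-8),
        kappa=kappa0,
        p_esc=p_esc0,
        p_trap=p_trap0,
        Dest=D0,
    )
    return params, z0, C0


def run_chain(
    traj: Trajectory,
    priors: PriorSpec | None = None,
    n_sweeps: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    dest: float | None = None,
    kappa_step_sd: float = 0.5,
    adapt_kappa: bool = True,
    store_paths: bool = False,
    c1_prior_var: float = 1e4,
    chain_id: int = 0,
) -> PosteriorSamples:
    """Run one MCMC chain and return the post-burn-in samples.

    ``dest=None`` sets Dest to the current sample of D at every sweep;
    a float fixes it.  The kappa proposal SD is adapted toward a 25-40%
    acceptance rate during burn-in only, so detailed balance holds for all
    retained samples.  Fully reproducible given ``seed``.
    """
    if traj.n_frames < 3:
        raise ValueError("trajectory too short for inference (N < 3)")
    if not 0 <= burn_in < n_sweeps:
        raise ValueError("need 0 <= burn_in < n_sweeps")
    priors = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    params, z, C = initialize(traj, priors)
    if dest is not None:
        params = HPWParams(
            D=params.D, DC=params.DC, kappa=params.kappa,
            p_esc=params.p_esc, p_trap=params.p_trap, Dest=dest,
        )

    m = traj.n_frames - 1
    n_keep = n_sweeps - burn_in
    out = {name: np.empty(n_keep) for name in PosteriorSamples.PARAM_NAMES}
    z_sum = np.zeros(m)
    c_sum = np.zeros((m, 2))
    z_store = np.empty((n_keep, m), dtype=np.int8) if store_paths else None

    step_sd = kappa_step_sd
    n_acc_total = 0
    n_prop_total = 0
    acc_window = 0
    window_len = 50

    for s in range(n_sweeps):
        arrays = _sweep_arrays(traj, params)
        # centers first: on sweep 0 this detaches C from the particle in
        # segments the initializer labelled free, which keeps a rough start
        # from seeding spurious confinement
        C = sample_centers(
            traj, z, params, rng, c1_prior_var=c1_prior_var, arrays=arrays
        )
        z, _ = sample_states(traj, C, params, rng, arrays=arrays)
        # nucleation windows rotate their alignment across sweeps so every
        # 50-frame stretch is eventually proposed as one block
        z, C = flip_windows(
            traj, z, C, params, rng,
            window=min(50, traj.n_frames - 2) or 1,
            offset=(s * 13) % 50, c1_prior_var=c1_prior_var,
            arrays=arrays,
        )
        z, C = refine_pairs(
            traj, z, C, params, rng,
            forward=bool(s % 2 == 0), c1_prior_var=c1_prior_var,
            arrays=arrays,
        )
        D, DC = sample_diffusivities(
            traj, z, C, params.kappa, priors, rng, arrays=arrays
        )
        kappa, accepted = sample_kappa(
            traj, z, C, D, priors, rng, params.kappa, step_sd
        )
        p_esc, p_trap = sample_switching(z, priors, rng)
        dest_val = dest if dest is not None else D
        params = HPWParams(
            D=D, DC=DC, kappa=kappa, p_esc=p_esc, p_trap=p_trap,
            Dest=dest_val,
        )

        acc_window += accepted
        if s >= burn_in:
            n_acc_total += accepted
            n_prop_total += 1
        if (
            adapt_kappa
            and s < burn_in
            and (s + 1) % window_len == 0
        ):
            rate = acc_window / window_len
            if rate < 0.25:
                step_sd *= 0.7
            elif rate > 0.40:
                step_sd *= 1.4
            acc_window = 0
        elif (s + 1) % window_len == 0:
            acc_window = 0

        if s >= burn_in:
            k = s - burn_in
            for name, val in zip(
                PosteriorSamples.PARAM_NAMES, (D, DC, kappa, p_esc, p_trap)
            ):
                out[name][k] = val
            z_sum += z
            c_sum += C
            if z_store is not None:
                z_store[k] = z

    return PosteriorSamples(
        D=out["D"],
        DC=out["DC"],
        kappa=out["kappa"],
        p_esc=out["p_esc"],
        p_trap=out["p_trap"],
        chain=np.full(n_keep, chain_id, dtype=int),
        state_prob=z_sum / n_keep,
        mean_C=c_sum / n_keep,
        kappa_acceptance=(
            n_acc_total / n_prop_total if n_prop_total else float("nan")
        ),
        z_samples=z_store,
    )
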