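"""Harmonic-potential-well (HPW) confinement model: types and transition densities.

A tracked particle switches between free Brownian diffusion (hidden state
``z = 0``) and confinement in a harmonic potential well (``z = 1``) whose
center ``C`` itself diffuses slowly.  While confined the particle follows an
Ornstein-Uhlenbeck (OU) process around ``C`` with mean-reversion rate
``kappa``; the exact one-step transition is used, so the model remains valid
even when the frame-to-frame displacement is comparable to the well radius.

All positions are in micrometres, times in seconds, diffusivities in
micrometres^2 per second and ``kappa`` in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trajectory",
    "HPWParams",
    "HiddenPath",
    "transition_probability",
    "particle_increment_density",
    "center_increment_density",
    "complete_loglikelihood",
    "LOG_HALF",
]

LOG_HALF = float(np.log(0.5))
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Trajectory:
    """A 2D single-particle track: strictly increasing times and positions.

    Attributes
    ----------
    times : (N,) array, seconds
    positions : (N, 2) array, micrometres
    id : opaque label used in event tables
    """

    times: np.ndarray
    positions: np.ndarray
    id: str = "traj"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("trajectory needs at least 2 time points")
        if positions.shape != (times.size, 2):
            raise ValueError(
                f"positions shape {positions.shape} does not match "
                f"({times.size}, 2)"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise ValueError("times and positions must be finite")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        # cached: the sampler touches these thousands of times per run
        object.__setattr__(self, "_dts", dts)
        object.__setattr__(self, "_displacements", np.diff(positions, axis=0))

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dts(self) -> np.ndarray:
        """Per-increment time steps, length N-1."""
        return self._dts

    @property
    def displacements(self) -> np.ndarray:
        """Frame-to-frame displacements, shape (N-1, 2)."""
        return self._displacements


@dataclass(frozen=True)
class HPWParams:
    """Model parameters.

    ``D``, ``DC``, ``kappa``, ``p_esc`` and ``p_trap`` are inferred; ``Dest``
    (center diffusivity while the particle is free) is a fixed algorithm
    parameter that lets the latent center relocate between confinement sites
    and does not affect the particle likelihood.
    """

    D: float
    DC: float
    kappa: float
    p_esc: float
    p_trap: float
    Dest: float = 0.5

    def __post_init__(self) -> None:
        for name in ("D", "DC", "kappa", "Dest"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_esc", "p_trap"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class HiddenPath:
    """Hidden states: z_i in {0, 1} and well center C_i, one per increment.

    ``z[i]`` and ``C[i]`` govern the transition from frame i to frame i+1,
    so both arrays have length N-1 for an N-frame trajectory.  The center is
    defined (and diffusing) even while the particle is free; it simply does
    not enter the particle density then.
    """

    z: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int8)
        C = np.asarray(self.C, dtype=float)
        if z.ndim != 1 or C.shape != (z.size, 2):
            raise ValueError("z must be (M,) and C (M, 2)")
        if not np.all((z == 0) | (z == 1)):
            raise ValueError("states must be binary")
        if not np.all(np.isfinite(C)):
            raise ValueError("centers must be finite")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "C", C)


def transition_probability(
    z_next: int, z_now: int, p_esc: float, p_trap: float
) -> float:
    """P(z_{i+1} = z_next | z_i = z_now) for the 2-state switching chain.

    The success probability of the Bernoulli law is
    ``z_now * (1 - p_esc) + (1 - z_now) * p_trap``: a confined particle stays
    confined with probability 1 - p_esc, a free one is trapped with
    probability p_trap.
    """
    if z_next not in (0, 1) or z_now not in (0, 1):
        raise ValueError("states must be 0 or 1")
    if not (0.0 < p_esc < 1.0 and 0.0 < p_trap < 1.0):
        raise ValueError("switching probabilities must lie in (0, 1)")
    p_one = z_now * (1.0 - p_esc) + (1 - z_now) * p_trap
    return p_one if z_next == 1 else 1.0 - p_one


def confined_moments(kappa: float, D: float, dt):
    """Exact OU one-step shrinkage factor and per-coordinate variance.

    Returns ``(beta, var)`` with ``beta = 1 - exp(-kappa*dt)`` (fraction of
    the distance to the center covered in one step) and
    ``var = (D/kappa) * (1 - exp(-2*kappa*dt))``.
    """
    beta = -np.expm1(-kappa * np.asarray(dt, dtype=float))
    var = (D / kappa) * -np.expm1(-2.0 * kappa * np.asarray(dt, dtype=float))
    return beta, var


def _gauss2_logpdf(dev: np.ndarray, var) -> np.ndarray:
    """Log-density of an isotropic 2D Gaussian at deviations ``dev`` (…, 2)."""
    var = np.asarray(var, dtype=float)
    sq = np.sum(np.square(dev), axis=-1)
    return -_LOG_2PI - np.log(var) - 0.5 * sq / var


def particle_increment_density(
    dX: np.ndarray,
    X_i: np.ndarray,
    C_i: np.ndarray,
    z_i: int,
    D: float,
    kappa: float,
    dt: float,
) -> float:
    """Log-density of one particle displacement given the hidden state.

    Free (``z_i = 0``): isotropic Gaussian, zero mean, per-coordinate variance
    ``2*D*dt``.  Confined (``z_i = 1``): exact OU step, mean
    ``(C_i - X_i) * (1 - e^{-kappa dt})`` and per-coordinate variance
    ``(D/kappa) * (1 - e^{-2 kappa dt})``.
    """
    if dt <= 0 or D <= 0 or kappa <= 0:
        raise ValueError("dt, D and kappa must be positive")
    if z_i not in (0, 1):
        raise ValueError("state must be 0 or 1")
    dX = np.asarray(dX, dtype=float)
    if z_i == 0:
        return float(_gauss2_logpdf(dX, 2.0 * D * dt))
    beta, var = confined_moments(kappa, D, dt)
    mean = (np.asarray(C_i, dtype=float) - np.asarray(X_i, dtype=float)) * beta
    return float(_gauss2_logpdf(dX - mean, var))


def center_increment_density(
    dC: np.ndarray, z_i: int, DC: float, Dest: float, dt: float
) -> float:
    """Log-density of one well-center displacement.

    The center performs zero-mean Brownian motion with diffusivity ``DC``
    while the particle is confined and ``Dest`` while it is free, giving
    per-coordinate variance ``2*dt*(DC*z_i + Dest*(1-z_i))``.
    """
    if dt <= 0 or DC <= 0 or Dest <= 0:
        raise ValueError("dt, DC and Dest must be positive")
    if z_i not in (0, 1):
        raise ValueError("state must be 0 or 1")
    var = 2.0 * dt * (DC if z_i == 1 else Dest)
    return float(_gauss2_logpdf(np.asarray(dC, dtype=float), var))


def complete_loglikelihood(
    traj: Trajectory, path: HiddenPath, params: HPWParams
) -> float:
    """Joint log-density of (X, C, z) given the parameters.

    Sums, over increments, the particle density, the center density (one
    fewer term than particle increments, since C has length N-1) and the
    state-transition probabilities; the initial state carries a uniform
    Bernoulli(0.5) law and the model conditions on the first observed
    position, so the value is invariant under global translations.
    """
    z, C = path.z, path.C
    n_inc = traj.n_frames - 1
    if z.size != n_inc:
        raise ValueError(
            f"hidden path length {z.size} != number of increments {n_inc}"
        )
    dts = traj.dts
    dX = traj.displacements
    X = traj.positions[:-1]

    beta, var_c = confined_moments(params.kappa, params.D, dts)
    mean = (C - X) * beta[:, None] * z[:, None]
    var = np.where(z == 1, var_c, 2.0 * params.D * dts)
    ll = float(np.sum(_gauss2_logpdf(dX - mean, var)))

    if n_inc >= 2:
        dC = np.diff(C, axis=0)
        var_center = 2.0 * dts[:-1] * np.where(
            z[:-1] == 1, params.DC, params.Dest
        )
        ll += float(np.sum(_gauss2_logpdf(dC, var_center)))
        p_one = z[:-1] * (1.0 - params.p_esc) + (1 - z[:-1]) * params.p_trap
        p_step = np.where(z[1:] == 1, p_one, 1.0 - p_one)
        ll += float(np.sum(np.log(p_step)))

    ll += LOG_HALF  # uniform initial state law
    return ll
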