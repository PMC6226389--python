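"""Forward simulation of HPW-model trajectories with known ground truth.

The generator reproduces the conditions used to validate the inference
machinery: a 5 kHz track (dt = 2e-4 s) of N = 5000 frames with free
diffusivity D = 0.5 um^2/s, well strength kappa = 3000 /s, center diffusivity
DC = 0.01 um^2/s while confined, and per-frame switching probabilities
p_trap = 0.002, p_esc = 0.001 (so about two thirds of frames are confined at
stationarity).  While the particle is free the simulated center drifts toward
the particle (rate ``center_tracking_rate``) so that confinement, when it
starts, begins near the current position; this drift is a simulation device
only and is deliberately absent from the inference model.

Optional static localization noise and subsampling mimic the acquisition
pipeline: noise is added to the full-rate track first, then every
``subsample_factor``-th frame is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import HiddenPath, HPWParams, Trajectory

__all__ = [
    "SimulationConfig",
    "default_params",
    "simulate",
    "add_localization_noise",
    "subsample",
]


def default_params() -> HPWParams:
    """Parameters of the reference simulation protocol (5 kHz conditions)."""
    return HPWParams(
        D=0.5, DC=0.01, kappa=3000.0, p_esc=0.001, p_trap=0.002, Dest=0.5
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic trajectory.

    ``center_tracking_rate`` (1/s) is the drift rate pulling C toward X during
    free periods; its default gives a relaxation time of 50 frames at the
    default dt. ``localization_sd`` (um) adds static Gaussian position noise;
    0 disables it. ``subsample_factor`` keeps every k-th frame.
    """

    params: HPWParams = field(default_factory=default_params)
    n_frames: int = 5000
    dt: float = 2e-4
    seed: int = 0
    center_tracking_rate: float | None = None
    localization_sd: float = 0.0
    subsample_factor: int = 1

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be non-negative")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be a positive integer")

    @property
    def tracking_rate(self) -> float:
        # default: relaxation time of 50 frames
        if self.center_tracking_rate is not None:
            return self.center_tracking_rate
        return 1.0 / (50.0 * self.dt)


def simulate(config: SimulationConfig) -> tuple[Trajectory, HiddenPath]:
    """Draw one trajectory and its ground-truth hidden path.

    States evolve by the 2-state switching chain; the particle takes exact OU
    steps while confined and free Brownian steps otherwise; the center takes
    Brownian steps (diffusivity DC confined / Dest free) plus, while free, the
    Euler drift ``alpha*dt*(X_i - C_i)``.  The initial state is drawn from the
    chain's stationary law; X_1 = C_1 = origin.  Deterministic given the seed.
    The returned track is noise-free and at full rate; apply
    :func:`add_localization_noise` and :func:`subsample` separately.
    """
    p = config.params
    n = config.n_frames
    dt = config.dt
    alpha = config.tracking_rate
    rng = np.random.default_rng(config.seed)

    beta = -np.expm1(-p.kappa * dt)
    sd_conf = np.sqrt((p.D / p.kappa) * -np.expm1(-2.0 * p.kappa * dt))
    sd_free = np.sqrt(2.0 * p.D * dt)
    sd_c_conf = np.sqrt(2.0 * p.DC * dt)
    sd_c_free = np.sqrt(2.0 * p.Dest * dt)

    stationary_p_conf = p.p_trap / (p.p_trap + p.p_esc)
    z = np.empty(n - 1, dtype=np.int8)
    z[0] = rng.random() < stationary_p_conf
    u = rng.random(n - 2)
    noise_x = rng.standard_normal((n - 1, 2))
    noise_c = rng.standard_normal((n - 2, 2))

    X = np.zeros((n, 2))
    C = np.zeros((n - 1, 2))
    for i in range(n - 1):
        if z[i] == 1:
            X[i + 1] = X[i] + (C[i] - X[i]) * beta + sd_conf * noise_x[i]
        else:
            X[i + 1] = X[i] + sd_free * noise_x[i]
        if i < n - 2:
            if z[i] == 1:
                C[i + 1] = C[i] + sd_c_conf * noise_c[i]
            else:
                C[i + 1] = (
                    C[i] + alpha * dt * (X[i] - C[i]) + sd_c_free * noise_c[i]
                )
            p_conf = (1.0 - p.p_esc) if z[i] == 1 else p.p_trap
            z[i + 1] = u[i] < p_conf

    times = dt * np.arange(n)
    traj = Trajectory(times=times, positions=X, id=f"sim-{config.seed}")
    return traj, HiddenPath(z=z, C=C)


def add_localization_noise(traj: Trajectory, sd: float, seed: int) -> Trajectory:
    """Add i.i.d. isotropic Gaussian static localization error of SD ``sd`` um."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return traj
    rng = np.random.default_rng(seed)
    noisy = traj.positions + sd * rng.standard_normal(traj.positions.shape)
    return Trajectory(times=traj.times, positions=noisy, id=traj.id)


def subsample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th frame starting from the first; timestamps kept."""
    if factor < 1:
        raise ValueError("subsample factor must be >= 1")
    if factor == 1:
        return traj
    return Trajectory(
        times=traj.times[::factor],
        positions=traj.positions[::factor],
        id=traj.id,
    )


def subsample_path(path: HiddenPath, factor: int) -> HiddenPath:
    """Ground truth aligned with a subsampled track.

    The state attached to subsampled increment j (spanning original
    increments j*factor .. (j+1)*factor - 1) is taken as the state of the
    first covered increment, and the center likewise; this is the natural
    labelling when switching is slow relative to the subsampling window.
    """
    if factor < 1:
        raise ValueError("subsample factor must be >= 1")
    if factor == 1:
        return path
    m = path.z.size  # = N - 1 original increments
    n_out = (m + 1 + factor - 1) // factor  # ceil(N / factor)
    idx = np.arange(n_out - 1) * factor
    return HiddenPath(z=path.z[idx], C=path.C[idx])
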