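"""Multi-chain convergence assessment via the Gelman-Rubin PSRF.

The potential scale reduction factor compares between-chain and within-chain
variance of each monitored scalar parameter,

    PSRF = sqrt( (n-1)/n + B / (n W) ),

where n is the per-chain sample count, W the mean within-chain variance and
B/n the variance of the chain means.  Values near 1 indicate that the chains
are sampling the same distribution; a run is declared converged when the
PSRF of every monitored parameter falls below a threshold (default 1.2).
Runs that fail are extended by doubling the sweep count up to a cap
(default 4e5 sweeps) and flagged for exclusion if still unconverged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mcmc import PosteriorSamples, PriorSpec, run_chain
from .model import Trajectory

__all__ = ["ConvergenceReport", "compute_psrf", "gelman_rubin", "run_until_converged"]

MONITORED = PosteriorSamples.PARAM_NAMES


@dataclass(frozen=True)
class ConvergenceReport:
    psrf: dict
    converged: bool
    total_sweeps: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "psrf": {k: float(v) for k, v in self.psrf.items()},
            "converged": bool(self.converged),
            "total_sweeps": int(self.total_sweeps),
            "threshold": float(self.threshold),
        }


def gelman_rubin(chains: np.ndarray) -> float:
    """PSRF of one scalar parameter from an (m_chains, n_samples) array."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a 2D array with at least 2 chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least 2 samples per chain")
    means = chains.mean(axis=1)
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w <= 0.0:
        warnings.warn("zero within-chain variance; PSRF undefined")
        return float("nan") if b_over_n <= 0 else float("inf")
    return float(np.sqrt((n - 1.0) / n + b_over_n / w))


def compute_psrf(chains_by_param: dict) -> dict:
    """PSRF per monitored parameter.

    ``chains_by_param`` maps a parameter name to an (m_chains, n_samples)
    array of post-burn-in draws with equal per-chain lengths.
    """
    return {name: gelman_rubin(arr) for name, arr in chains_by_param.items()}


def _stack_param(parts: list[PosteriorSamples], name: str) -> np.ndarray:
    return np.stack([getattr(p, name) for p in parts])


def psrf_from_chains(parts: list[PosteriorSamples]) -> dict:
    return compute_psrf({n: _stack_param(parts, n) for n in MONITORED})


def run_until_converged(
    traj: Trajectory,
    priors: PriorSpec | None = None,
    n_chains: int = 5,
    base_sweeps: int = 2000,
    base_burn_in: int | None = None,
    max_sweeps: int = 400_000,
    threshold: float = 1.2,
    seed: int = 0,
    dest: float | None = None,
    store_paths: bool = False,
) -> tuple[PosteriorSamples, ConvergenceReport]:
    """Run parallel chains, doubling the run length until the PSRF passes.

    At the first stage each chain runs ``base_sweeps`` sweeps with the given
    burn-in (default: half).  If any monitored parameter has PSRF >=
    ``threshold``, all chains are re-run from scratch at twice the length
    (burn-in = half, standard split practice) until either convergence or
    ``max_sweeps``.  Chains get deterministic per-chain seeds derived from
    ``seed``.  Returns the pooled samples from the final stage and a report;
    a failed run is reported, not raised.
    """
    priors = priors or PriorSpec()
    sweeps = base_sweeps
    chain_seeds = [seed + 100_003 * (c + 1) for c in range(n_chains)]
    parts: list[PosteriorSamples] = []
    psrf: dict = {}
    while True:
        burn = base_burn_in if sweeps == base_sweeps and base_burn_in is not None else sweeps // 2
        parts = [
            run_chain(
                traj,
                priors=priors,
                n_sweeps=sweeps,
                burn_in=burn,
                seed=chain_seeds[c],
                dest=dest,
                store_paths=store_paths,
                chain_id=c,
            )
            for c in range(n_chains)
        ]
        psrf = psrf_from_chains(parts)
        converged = all(np.isfinite(v) and v < threshold for v in psrf.values())
        if converged or sweeps * 2 > max_sweeps:
            report = ConvergenceReport(
                psrf=psrf,
                converged=converged,
                total_sweeps=sweeps,
                threshold=threshold,
            )
            return PosteriorSamples.pool(parts), report
        sweeps *= 2
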