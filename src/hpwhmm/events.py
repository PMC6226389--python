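"""Confinement-event extraction and profiling.

Posterior per-frame confinement probabilities are thresholded at 0.5 into a
binary state vector; maximal runs of ones become confinement events and runs
of zeros free-diffusion events.  Each state index covers one increment, so an
event over state indices a..b occupies the time interval [t_a, t_{b+1}] and
its lifetime is t_{b+1} - t_a; lifetimes therefore partition the trajectory
duration exactly.  Downstream statistics: event lifetimes with boundary
exclusion, radial shape statistics about the mean posterior well center,
the 30-nm repeat-site filter, exponential-mixture lifetime fits with
Q-Q goodness, across-trajectory heterogeneity tests, within-trajectory
conservation clustering (k-means++ / Shannon diversity), windowed local
diffusivity, and simple correlation helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .model import Trajectory

__all__ = [
    "ConfinementEvent",
    "EventShapeStats",
    "RAYLEIGH_SKEWNESS",
    "threshold_states",
    "extract_events",
    "lifetime_table",
    "shape_statistics",
    "mark_repeats",
    "fit_exponential_mixture",
    "qq_r_squared",
    "heterogeneity_tests",
    "conservation_clustering",
    "local_diffusivity",
    "correlate",
    "events_frame",
]

#: Skewness of the Rayleigh distribution, 2 sqrt(pi) (pi - 3) / (4 - pi)^{3/2}:
#: the radial skewness of an isotropic 2D Gaussian occupation profile.
RAYLEIGH_SKEWNESS = 2.0 * math.sqrt(math.pi) * (math.pi - 3.0) / (4.0 - math.pi) ** 1.5


@dataclass(frozen=True)
class EventShapeStats:
    """Radial shape statistics of one event about its mean well center.

    ``radial_sd`` is the standard deviation of the radii (the variance is
    exposed as ``radial_var``); skewness uses population moment estimators.
    ``degenerate`` marks events whose radii have zero spread, for which the
    skewness is reported as 0.
    """

    mean_radius: float
    radial_skewness: float
    mean_median_distance: float
    radial_sd: float
    radial_var: float
    degenerate: bool = False


@dataclass(frozen=True)
class ConfinementEvent:
    """A maximal confined run of state indices ``start..end`` (inclusive)."""

    trajectory_id: str
    start: int
    end: int
    t_start: float
    t_end: float
    lifetime: float
    touches_boundary: bool
    center: np.ndarray  # mean posterior well center over the event, (2,)
    positions: np.ndarray  # particle positions covered, (n_frames_in_event, 2)
    is_repeat: bool = False
    shape: EventShapeStats | None = None

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def threshold_states(state_probs: np.ndarray) -> np.ndarray:
    """Binary state vector: confined iff pi(z_i | X) > 0.5 (ties -> free)."""
    p = np.asarray(state_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("state probabilities must lie in [0, 1]")
    return (p > 0.5).astype(np.int8)


def uncertain_fraction(
    state_probs: np.ndarray, lo: float = 0.2, hi: float = 0.8
) -> float:
    """Fraction of per-frame probabilities in the uncertain band (lo, hi)."""
    p = np.asarray(state_probs, dtype=float)
    return float(np.mean((p > lo) & (p < hi)))


def _runs(binary: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of a binary vector as (value, start, end) inclusive."""
    b = np.asarray(binary)
    if b.size == 0:
        return []
    change = np.flatnonzero(np.diff(b)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [b.size - 1]))
    return [(int(b[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def extract_events(
    binary: np.ndarray,
    times: np.ndarray,
    positions: np.ndarray | None = None,
    centers: np.ndarray | None = None,
    trajectory_id: str = "traj",
) -> tuple[list[ConfinementEvent], list[ConfinementEvent]]:
    """Split a binary state vector into confinement and free events.

    ``binary`` has one entry per increment (length N-1 against N times).
    State index i covers [t_i, t_{i+1}], so an event over indices a..b has
    lifetime t_{b+1} - t_a and covers particle positions a..b+1.  Runs that
    include the first or last state index are flagged as boundary-touching.
    """
    b = np.asarray(binary)
    times = np.asarray(times, dtype=float)
    if b.size != times.size - 1:
        raise ValueError("need one state per increment (len(times) - 1)")
    confined: list[ConfinementEvent] = []
    free: list[ConfinementEvent] = []
    for value, s, e in _runs(b):
        if centers is not None and value == 1:
            cbar = np.mean(centers[s : e + 1], axis=0)
        else:
            cbar = np.full(2, np.nan)
        pos = (
            positions[s : e + 2]
            if positions is not None
            else np.zeros((0, 2))
        )
        ev = ConfinementEvent(
            trajectory_id=trajectory_id,
            start=s,
            end=e,
            t_start=float(times[s]),
            t_end=float(times[e + 1]),
            lifetime=float(times[e + 1] - times[s]),
            touches_boundary=(s == 0 or e == b.size - 1),
            center=cbar,
            positions=pos,
        )
        (confined if value == 1 else free).append(ev)
    return confined, free


def lifetime_table(
    events: list[ConfinementEvent], exclude_boundary: bool = True
) -> np.ndarray:
    """Event lifetimes in seconds.

    For lifetime analysis, events touching the first or last time point are
    excluded because their full duration is not witnessed.
    """
    return np.array(
        [
            ev.lifetime
            for ev in events
            if not (exclude_boundary and ev.touches_boundary)
        ]
    )


def shape_statistics(
    positions: np.ndarray, center: np.ndarray
) -> EventShapeStats:
    """Radial statistics of an event's positions about the mean well center.

    R_i is the Euclidean distance of each covered position from the mean
    posterior center; reported are mean(R), the population skewness of R,
    |mean(R) - median(R)| and the SD of R.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    r = np.linalg.norm(pos - np.asarray(center, dtype=float), axis=1)
    mean_r = float(np.mean(r))
    var_r = float(np.mean((r - mean_r) ** 2))
    sd_r = math.sqrt(var_r)
    if sd_r <= 1e-9 * max(mean_r, 1e-300):
        return EventShapeStats(
            mean_radius=mean_r,
            radial_skewness=0.0,
            mean_median_distance=float(abs(mean_r - np.median(r))),
            radial_sd=0.0,
            radial_var=0.0,
            degenerate=True,
        )
    skew = float(np.mean((r - mean_r) ** 3) / sd_r**3)
    return EventShapeStats(
        mean_radius=mean_r,
        radial_skewness=skew,
        mean_median_distance=float(abs(mean_r - np.median(r))),
        radial_sd=sd_r,
        radial_var=var_r,
    )


def mark_repeats(
    events: list[ConfinementEvent], radius_nm: float = 30.0
) -> list[ConfinementEvent]:
    """Flag events whose mean center revisits an earlier site.

    An event is a repeat iff its mean posterior center lies within
    ``radius_nm`` of the mean center of ANY earlier event in the same
    trajectory (events must be time-ordered).  The first event at a site is
    never a repeat.
    """
    radius_um = radius_nm * 1e-3
    out: list[ConfinementEvent] = []
    seen: list[np.ndarray] = []
    for ev in events:
        is_rep = any(
            float(np.linalg.norm(ev.center - c)) <= radius_um for c in seen
        )
        out.append(replace(ev, is_repeat=is_rep))
        seen.append(ev.center)
    return out


def attach_shapes(
    events: list[ConfinementEvent],
    min_lifetime: float = 0.01,
    include_repeats: bool = True,
) -> list[ConfinementEvent]:
    """Shape statistics for all events of at least ``min_lifetime`` seconds.

    Unlike the lifetime analysis, boundary-touching events are kept here;
    repeat-site events are kept or dropped according to ``include_repeats``.
    """
    kept = []
    for ev in events:
        if ev.lifetime < min_lifetime:
            continue
        if not include_repeats and ev.is_repeat:
            continue
        kept.append(replace(ev, shape=shape_statistics(ev.positions, ev.center)))
    return kept


def events_frame(events: list[ConfinementEvent]) -> pd.DataFrame:
    """Tabular view of events (one row per event) for serialization."""
    rows = []
    for ev in events:
        row = {
            "trajectory_id": ev.trajectory_id,
            "start_frame": ev.start,
            "end_frame": ev.end,
            "t_start_s": ev.t_start,
            "t_end_s": ev.t_end,
            "lifetime_s": ev.lifetime,
            "touches_boundary": ev.touches_boundary,
            "is_repeat": ev.is_repeat,
            "center_x_um": ev.center[0],
            "center_y_um": ev.center[1],
        }
        if ev.shape is not None:
            row.update(
                mean_radius_um=ev.shape.mean_radius,
                radial_skewness=ev.shape.radial_skewness,
                mean_median_distance_um=ev.shape.mean_median_distance,
                radial_sd_um=ev.shape.radial_sd,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def fit_exponential_mixture(
    lifetimes: np.ndarray,
    n_components: int = 2,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximum-likelihood exponential (mixture) fit of event lifetimes.

    One component: the closed-form MLE (sample mean).  Two components: EM to
    relative log-likelihood tolerance ``tol``, best of ``n_restarts`` random
    restarts.  Returns (means, weights, loglik) with components sorted by
    mean.
    """
    x = np.asarray(lifetimes, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 lifetimes")
    if np.any(x <= 0):
        raise ValueError("lifetimes must be positive")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if n_components == 1:
        mu = float(np.mean(x))
        ll = float(np.sum(stats.expon.logpdf(x, scale=mu)))
        return np.array([mu]), np.array([1.0]), ll

    rng = np.random.default_rng(seed)
    best_ll = -np.inf
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            # start at the (nested) single-exponential solution so the
            # 2-component fit can never score below the 1-component MLE
            mus = np.array([np.mean(x), 1.001 * np.mean(x)])
            w = np.array([0.5, 0.5])
        else:
            q = rng.uniform(0.1, 0.9)
            mus = np.sort(
                np.mean(x) * np.exp(rng.uniform(-2.0, 2.0, size=2))
            )
            w = np.array([q, 1.0 - q])
        ll_prev = -np.inf
        for _it in range(max_iter):
            log_comp = np.log(w)[:, None] - np.log(mus)[:, None] - x[None, :] / mus[:, None]
            log_norm = np.logaddexp(log_comp[0], log_comp[1])
            ll = float(np.sum(log_norm))
            resp = np.exp(log_comp - log_norm[None, :])
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            w = nk / x.size
            mus = resp @ x / nk
            mus = np.maximum(mus, 1e-300)
            if ll - ll_prev < tol * max(1.0, abs(ll)) and _it > 0:
                break
            ll_prev = ll
        if ll > best_ll:
            best_ll = ll
            best = (mus.copy(), w.copy())
    mus, w = best
    order = np.argsort(mus)
    return mus[order], w[order], float(best_ll)


def exponential_mixture_sample(
    means: np.ndarray,
    weights: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n lifetimes from an exponential mixture."""
    comp = rng.choice(len(means), size=n, p=np.asarray(weights) / np.sum(weights))
    return rng.exponential(np.asarray(means)[comp])


def qq_r_squared(data: np.ndarray, reference) -> float:
    """Goodness of a Q-Q plot against a reference distribution or sample.

    Order statistics of ``data`` are plotted against reference quantiles at
    the same plotting positions; a straight line is drawn through the first
    and third quartile points and R^2 = 1 - SS_resid / SS_total is computed
    about that line.  Gross misfit can give R^2 <= 0.
    """
    y = np.sort(np.asarray(data, dtype=float))
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.all(y == y[0]):
        raise ValueError("degenerate (constant) data")
    probs = (np.arange(1, n + 1) - 0.5) / n
    if hasattr(reference, "ppf"):
        x = reference.ppf(probs)
    else:
        ref = np.asarray(reference, dtype=float)
        x = np.quantile(ref, probs)
    x1, x3 = np.quantile(x, [0.25, 0.75])
    y1, y3 = np.quantile(y, [0.25, 0.75])
    if x3 == x1:
        raise ValueError("reference quartiles coincide")
    slope = (y3 - y1) / (x3 - x1)
    intercept = y1 - slope * x1
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def heterogeneity_tests(
    values: np.ndarray, groups: np.ndarray
) -> dict:
    """Across-trajectory heterogeneity of a per-event statistic.

    Returns p-values of the Kruskal-Wallis test (used for lifetimes) and
    one-way ANOVA (used for shape statistics) across trajectory groups.
    Groups with fewer than 2 events are dropped; if fewer than 2 groups
    remain the result records that instead of raising.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    by_group = [
        values[groups == g] for g in pd.unique(groups)
    ]
    by_group = [v for v in by_group if v.size >= 2]
    if len(by_group) < 2:
        return {
            "kruskal_p": float("nan"),
            "anova_p": float("nan"),
            "n_groups": len(by_group),
            "insufficient_groups": True,
        }
    kw = stats.kruskal(*by_group)
    an = stats.f_oneway(*by_group)
    return {
        "kruskal_p": float(kw.pvalue),
        "anova_p": float(an.pvalue),
        "n_groups": len(by_group),
        "insufficient_groups": False,
    }


def shannon_diversity(labels: np.ndarray) -> float:
    """H = -sum p_j log p_j over the cluster occupancy of one trajectory."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def conservation_clustering(
    values: np.ndarray,
    trajectory_ids: np.ndarray,
    n_clusters_range=range(2, 11),
    n_restarts: int = 50,
    seed: int = 0,
) -> dict:
    """Within-trajectory conservation of an event statistic via clustering.

    Events are standardized and clustered with k-means++ (squared Euclidean);
    for each trajectory the Shannon diversity of its events' cluster labels
    is computed and summed over trajectories; the sum is averaged over
    ``n_restarts`` independent clusterings.  Lower values mean events of the
    same trajectory concentrate in few clusters, i.e. the statistic is
    conserved within trajectories.  Returns {n_clusters: mean summed H}.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    ids = np.asarray(trajectory_ids)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - x.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)
    out = {}
    for k in n_clusters_range:
        if k > x.shape[0]:
            raise ValueError(f"fewer events than clusters ({x.shape[0]} < {k})")
        totals = np.empty(n_restarts)
        for r in range(n_restarts):
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(xs)
            labels = km.labels_
            totals[r] = sum(
                shannon_diversity(labels[ids == t]) for t in pd.unique(ids)
            )
        out[int(k)] = float(totals.mean())
    return out


def local_diffusivity(
    traj: Trajectory, window: int = 100
) -> np.ndarray:
    """Moving-average local ML diffusivity estimate, one value per increment.

    Within a centered window of M displacements the 2D Brownian MLE is
    D_hat = sum ||dX||^2 / (4 M dt); edges use truncated windows.  Windows
    with non-uniform time steps are skipped (NaN) with a warning.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    dts = traj.dts
    dX = traj.displacements
    sq = np.sum(dX * dX, axis=1)
    per_step = sq / (4.0 * dts)
    est = (
        pd.Series(per_step)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    ser_dt = pd.Series(dts)
    spread = (
        ser_dt.rolling(window, center=True, min_periods=1).max()
        - ser_dt.rolling(window, center=True, min_periods=1).min()
    ).to_numpy()
    bad = spread > 1e-9 * float(np.median(dts))
    if bad.any():
        warnings.warn(
            "non-uniform time steps inside local-diffusivity windows; "
            "affected windows reported as NaN"
        )
        est[bad] = np.nan
    return est


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
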