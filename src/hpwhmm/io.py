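"""Plain-text file formats and run configuration.

Trajectories are tab-separated text with a header row ``time_s  x_um  y_um``
and ``#``-prefixed comment lines; there is no entrenched binary standard for
SPT tracks, and plain text keeps runs inspectable and diffable.  Posterior
and event tables are TSV with the producing seed and config hash recorded in
a leading comment line; run configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import PosteriorSamples, PriorSpec
from .model import HiddenPath, Trajectory

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "write_ground_truth",
    "read_ground_truth",
    "write_params_table",
    "write_state_table",
    "read_state_table",
]

TRAJ_COLUMNS = ("time_s", "x_um", "y_um")


@dataclass(frozen=True)
class RunConfig:
    """Defaults for a full simulate-fit-profile run.

    The MCMC defaults (5 chains of 2000 sweeps, 1000-sweep burn-in, PSRF
    threshold 1.2 with a 4e5-sweep cap) and the event rules (state threshold
    0.5, minimum event 0.01 s, 30-nm repeat radius) are the reference
    protocol of the method.
    """

    chains: int = 5
    sweeps: int = 2000
    burn_in: int = 1000
    psrf_threshold: float = 1.2
    max_sweeps: int = 400_000
    subsample_factor: int = 1
    state_threshold: float = 0.5
    min_event_s: float = 0.01
    repeat_radius_nm: float = 30.0
    seed: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorSpec(**d["priors"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)


def _provenance_line(config: RunConfig | None, seed: int | None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config.hash()}")
    return "# " + " ".join(parts) if parts else "#"


def read_trajectory(path, trajectory_id: str | None = None) -> Trajectory:
    """Read a tabular trajectory file; errors cite the offending line.

    Expected: a header line with columns time_s, x_um, y_um (any whitespace
    separated), then one numeric row per frame.  Lines starting with '#'
    and blank lines are ignored.
    """
    path = Path(path)
    header: list[str] | None = None
    times, xs, ys = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                header = fields
                missing = [c for c in TRAJ_COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing columns {missing} "
                        f"(found {header})"
                    )
                idx = [header.index(c) for c in TRAJ_COLUMNS]
                continue
            if len(fields) < len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            try:
                t, x, y = (float(fields[i]) for i in idx)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell ({exc})"
                ) from None
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path}:{lineno}: time {t} does not increase "
                    f"(previous {times[-1]})"
                )
            times.append(t)
            xs.append(x)
            ys.append(y)
    if header is None or len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return Trajectory(
        times=np.array(times),
        positions=np.column_stack([xs, ys]),
        id=trajectory_id or path.stem,
    )


def write_trajectory(
    path, traj: Trajectory, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        fh.write("\t".join(TRAJ_COLUMNS) + "\n")
        for t, (x, y) in zip(traj.times, traj.positions):
            fh.write(f"{t:.12g}\t{x:.12g}\t{y:.12g}\n")


def write_ground_truth(
    path, hidden: HiddenPath, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        fh.write("frame\tz\tc_x_um\tc_y_um\n")
        for i, (z, (cx, cy)) in enumerate(zip(hidden.z, hidden.C)):
            fh.write(f"{i}\t{int(z)}\t{cx:.12g}\t{cy:.12g}\n")


def read_ground_truth(path) -> HiddenPath:
    df = pd.read_csv(path, sep="\t", comment="#")
    return HiddenPath(
        z=df["z"].to_numpy(),
        C=df[["c_x_um", "c_y_um"]].to_numpy(),
    )


def write_params_table(
    path, samples: PosteriorSamples, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Parameter draws: one row per retained sweep and chain."""
    df = samples.params_frame()
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index_label="sweep", float_format="%.10g")


def write_state_table(
    path, samples: PosteriorSamples, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Per-frame summary: confinement probability and posterior-mean center."""
    df = pd.DataFrame(
        {
            "frame": np.arange(samples.state_prob.size),
            "p_confined": samples.state_prob,
            "c_x_um": samples.mean_C[:, 0],
            "c_y_um": samples.mean_C[:, 1],
        }
    )
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_state_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
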