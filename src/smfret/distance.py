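"""FRET efficiencies, inter-fluorophore distances, and dwell fluctuations.

Intensities convert to an apparent efficiency E = I_A / (I_A + γ·I_D)
(proximity ratio; γ = 1 by default since no detection correction is
applied) and then to a distance through the Förster relation
R = R0 · (1/E − 1)^(1/6) with R0 = 4.59 nm. Within each dwell interval —
a maximal run of frames decoded in one conformational state — the
root-mean-square fluctuation (RMSF) of R measures how conformationally
restricted that state is; block-jackknife resampling of the per-dwell
RMSF values gives its standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from smfret.simulate import DONOR_EXC

E_CLIP = (0.005, 0.995)


@dataclass(frozen=True)
class DistanceModel:
    """Förster conversion parameters: R0 in nm, detection factor gamma."""

    r0: float = 4.59
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.gamma <= 0:
            raise ValueError("r0 and gamma must be positive")


@dataclass
class DwellInterval:
    """One maximal constant-state run with its per-frame distances."""

    trajectory_id: int
    state: str  # "folded" | "unfolded"
    start_frame: int
    end_frame: int  # inclusive, in donor-excitation frame positions
    distances: np.ndarray  # nm

    @property
    def n_frames(self) -> int:
        return len(self.distances)


@dataclass
class FluctuationResult:
    """Per-state RMSF summary with jackknife standard error."""

    state: str
    mean_rmsf_nm: float
    jackknife_se_nm: float
    n_dwells: int
    n_jackknife: int

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "mean_rmsf_nm": self.mean_rmsf_nm,
            "jackknife_se_nm": self.jackknife_se_nm,
            "n_dwells": self.n_dwells,
            "n_jackknife": self.n_jackknife,
        }


def estimate_channel_background(data: pd.DataFrame, percentile: float = 5.0) -> tuple[float, float]:
    """Per-channel background as the dataset's 5th-percentile count."""
    don = data[data["excitation"] == DONOR_EXC] if "excitation" in data.columns else data
    return (
        float(np.percentile(don["donor"], percentile)),
        float(np.percentile(don["acceptor"], percentile)),
    )


def fret_efficiency(
    donor,
    acceptor,
    gamma: float = 1.0,
    background: tuple[float, float] = (0.0, 0.0),
    clip: Optional[tuple[float, float]] = E_CLIP,
) -> np.ndarray:
    """Apparent FRET efficiency E = I_A / (I_A + γ·I_D) after background subtraction.

    Observations where both corrected channels are non-positive carry no
    signal and return NaN (dropped from distance analysis). ``clip=None``
    returns the raw ratio.
    """
    d = np.asarray(donor, dtype=float) - background[0]
    a = np.asarray(acceptor, dtype=float) - background[1]
    total = a + gamma * d
    dead = (d <= 0) & (a <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(dead | (total <= 0), np.nan, a / np.where(total == 0, np.nan, total))
    if clip is not None:
        e = np.clip(e, clip[0], clip[1])
    return e


def efficiency_to_distance(e, model: DistanceModel = DistanceModel()) -> np.ndarray:
    """Invert the Förster relation: R = R0 · (1/E − 1)^(1/6), E in (0, 1)."""
    e = np.asarray(e, dtype=float)
    valid = np.isnan(e) | ((e > 0) & (e < 1))
    if not np.all(valid):
        raise ValueError("efficiency outside (0, 1): clip upstream before inversion")
    with np.errstate(invalid="ignore"):
        return model.r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)


def distance_to_efficiency(r, model: DistanceModel = DistanceModel()) -> np.ndarray:
    """Förster relation E = 1 / (1 + (R/R0)^6)."""
    r = np.asarray(r, dtype=float)
    return 1.0 / (1.0 + (r / model.r0) ** 6)


def extract_dwells(
    decoded: pd.DataFrame,
    model: DistanceModel = DistanceModel(),
    min_dwell: int = 3,
    background: Optional[tuple[float, float]] = None,
) -> list[DwellInterval]:
    """Split decoded trajectories into constant-state dwell intervals.

    ``decoded`` is a frame-per-row table with a ``state`` column (from
    ``KineticsResults.decoded_frame``); only donor-excitation frames carry
    distance information, so dwells are parsed on those frames. Runs
    shorter than ``min_dwell`` frames are dropped (a fluctuation needs at
    least a few points); dark dwells are ignored.
    """
    if background is None:
        background = estimate_channel_background(decoded)
    don = decoded[decoded["excitation"] == DONOR_EXC] if "excitation" in decoded.columns else decoded
    dwells: list[DwellInterval] = []
    for tid, df in don.groupby("trajectory_id", sort=True):
        states = df["state"].to_numpy()
        e = fret_efficiency(
            df["donor"].to_numpy(float), df["acceptor"].to_numpy(float),
            gamma=model.gamma, background=background,
        )
        r = efficiency_to_distance(e, model)
        boundaries = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(states)]))
        for s, t in zip(starts, ends):
            state = states[s]
            if state not in ("folded", "unfolded"):
                continue
            if t - s < min_dwell:
                continue
            dwells.append(
                DwellInterval(
                    trajectory_id=tid,
                    state=str(state),
                    start_frame=int(s),
                    end_frame=int(t - 1),
                    distances=r[s:t],
                )
            )
    return dwells


def rmsf(dwell) -> float:
    """Root-mean-square fluctuation of the dwell's distances around their mean."""
    r = dwell.distances if isinstance(dwell, DwellInterval) else np.asarray(dwell, float)
    if not np.all(np.isfinite(r)):
        warnings.warn("dwell contains non-finite distances; dropped", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.sqrt(np.mean((r - r.mean()) ** 2)))


def jackknife_se(values: Sequence[float], n_blocks: int = 10, rng_seed=None) -> float:
    """Block-jackknife standard error of the mean of ``values``.

    Values are shuffled (seeded) and partitioned into ``n_blocks`` nearly
    equal blocks; the delete-one-block means θ̂_(i) give
    SE = sqrt((n−1)/n · Σ (θ̂_(i) − θ̄)²) with n = n_blocks. With fewer
    values than blocks, falls back to the delete-one jackknife over
    individual values.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return float("nan")
    if np.ptp(vals) == 0.0:  # identical values: exactly zero spread
        return 0.0
    if len(vals) < n_blocks:
        warnings.warn(
            f"{len(vals)} values < {n_blocks} blocks; using delete-one jackknife",
            RuntimeWarning,
            stacklevel=2,
        )
        n_blocks = len(vals)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(vals))
    blocks = np.array_split(perm, n_blocks)
    total = vals.sum()
    n_total = len(vals)
    means = np.array([(total - vals[b].sum()) / (n_total - len(b)) for b in blocks])
    theta_bar = means.mean()
    n = n_blocks
    return float(np.sqrt((n - 1) / n * np.sum((means - theta_bar) ** 2)))


def fluctuation_analysis(
    decoded: pd.DataFrame,
    model: DistanceModel = DistanceModel(),
    min_dwell: int = 3,
    n_blocks: int = 10,
    rng_seed=None,
    background: Optional[tuple[float, float]] = None,
) -> dict[str, FluctuationResult]:
    """Per-state mean dwell RMSF with block-jackknife errors."""
    dwells = extract_dwells(decoded, model=model, min_dwell=min_dwell, background=background)
    out: dict[str, FluctuationResult] = {}
    for state in ("folded", "unfolded"):
        vals = np.array([rmsf(d) for d in dwells if d.state == state])
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        out[state] = FluctuationResult(
            state=state,
            mean_rmsf_nm=float(vals.mean()),
            jackknife_se_nm=jackknife_se(vals, n_blocks=n_blocks, rng_seed=rng_seed),
            n_dwells=len(vals),
            n_jackknife=min(n_blocks, len(vals)),
        )
    return out


def dwell_table(dwells: Sequence[DwellInterval]) -> pd.DataFrame:
    """Per-dwell summary table (TSV-friendly)."""
    return pd.DataFrame(
        {
            "trajectory_id": [d.trajectory_id for d in dwells],
            "state": [d.state for d in dwells],
            "start_frame": [d.start_frame for d in dwells],
            "end_frame": [d.end_frame for d in dwells],
            "n_frames": [d.n_frames for d in dwells],
            "rmsf_nm": [rmsf(d) for d in dwells],
        }
    )
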