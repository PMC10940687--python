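"""Trajectory quality control: the inclusion filters applied before analysis.

Mirrors the experimental practice for immobilized-molecule FRET data:
exclude aggregates (abnormally bright objects) and non-dual-labeled
objects, truncate each trajectory at the first photobleaching event of
either fluorophore (or at one minute), and analyze only trajectories
with at least four usable frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from smfret.simulate import ACCEPTOR_EXC, DONOR_EXC, TrajectorySet

# Dark-channel threshold in background SDs. Genuine signal sits tens of
# SDs above background at realistic SNR, while a long dark tail contains
# hundreds of background draws: the threshold must be loose enough that
# pure noise essentially never interrupts the below-threshold suffix.
Z_DARK = 4.0


@dataclass
class QcReport:
    """Partition of the input objects by QC outcome.

    Counts are exclusive (priority aggregate > single-label > short) and
    sum to the input total.
    """

    n_input: int
    n_excluded_aggregate: int
    n_excluded_single_label: int
    n_excluded_short: int
    n_retained: int
    truncation_frames: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_excluded_aggregate
            + self.n_excluded_single_label
            + self.n_excluded_short
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QC counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_aggregate": self.n_excluded_aggregate,
            "n_excluded_single_label": self.n_excluded_single_label,
            "n_excluded_short": self.n_excluded_short,
            "n_retained": self.n_retained,
            "truncation_frames": {str(k): int(v) for k, v in self.truncation_frames.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def estimate_background(tset: TrajectorySet) -> tuple[float, float]:
    """Robust per-channel background mean and SD.

    The donor channel during acceptor-direct excitation carries no
    fluorophore signal (absent crosstalk), so its pooled counts sample
    the background distribution directly. Falls back to the 5th
    percentile of all donor counts when the file has no ALEX frames.
    """
    acc = tset.data[tset.data["excitation"] == ACCEPTOR_EXC]
    if len(acc) >= 20:
        vals = acc["donor"].to_numpy(float)
    else:
        vals = tset.data["donor"].to_numpy(float)
        vals = vals[vals <= np.percentile(vals, 5)]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    sd = max(1.4826 * mad, 1e-6)
    return med, sd


def _dark_suffix_start(values: np.ndarray, threshold: float, confirm: int = 3) -> Optional[int]:
    """Index where the signal drops below threshold and stays there.

    Values are median-filtered (width 3) so an isolated noise outlier
    neither breaks a dark tail nor fakes one. Returns None when no dark
    tail of at least ``confirm`` frames exists.
    """
    if len(values) == 0:
        return None
    smoothed = median_filter(values.astype(float), size=min(3, len(values)), mode="nearest")
    below = smoothed <= threshold
    if not below[-1]:
        return None
    above = np.flatnonzero(~below)
    start = 0 if len(above) == 0 else int(above[-1]) + 1
    if len(values) - start < confirm:
        return None
    return start


def detect_bleach_frame(
    traj: pd.DataFrame,
    background_mean: float,
    background_sd: float,
    z: float = Z_DARK,
    confirm: int = 3,
) -> int:
    """First camera frame after which either fluorophore is dark.

    Acceptor presence is read from the direct-excitation check frames;
    donor presence from the total FRET-pair signal on donor-excitation
    frames. Returns the trajectory length when no bleach is detected.
    """
    n = len(traj)
    is_acc = (traj["excitation"] == ACCEPTOR_EXC).to_numpy()
    frames = traj["frame"].to_numpy()

    acc_signal = traj.loc[is_acc, "acceptor"].to_numpy(float)
    acc_frames = frames[is_acc]
    acc_thr = background_mean + z * background_sd

    don = traj.loc[~is_acc]
    total = (don["donor"] + don["acceptor"]).to_numpy(float)
    don_frames = frames[~is_acc]
    don_thr = 2 * background_mean + z * np.sqrt(2) * background_sd

    bleach = n
    for sig, frs, thr in ((acc_signal, acc_frames, acc_thr), (total, don_frames, don_thr)):
        idx = _dark_suffix_start(sig, thr, confirm)
        if idx is not None:
            first = int(frs[idx] - frames[0]) if idx < len(frs) else n
            bleach = min(bleach, first)
    return bleach


def truncate_at_bleach(
    traj: pd.DataFrame,
    background_mean: float,
    background_sd: float,
    hard_cap_s: float = 60.0,
    z: float = Z_DARK,
    confirm: int = 3,
    guard_frames: int = 2,
) -> pd.DataFrame:
    """Drop frames after the first detected photobleach, capping at 60 s.

    The change-point detector localizes the bleach no finer than the
    ALEX check-frame spacing, so ``guard_frames`` extra frames before the
    detected point are dropped as well: frames of ambiguous fluorophore
    status would otherwise masquerade as conformational transitions.
    """
    bleach = detect_bleach_frame(traj, background_mean, background_sd, z=z, confirm=confirm)
    if bleach < len(traj):
        bleach = max(bleach - guard_frames, 0)
    t0 = traj["time_s"].iloc[0]
    keep = (np.arange(len(traj)) < bleach) & ((traj["time_s"] - t0).to_numpy() < hard_cap_s)
    return traj.iloc[keep.nonzero()[0]]


def count_analyzable_frames(traj: pd.DataFrame) -> int:
    """Donor-excitation frames: the observations downstream analysis uses."""
    return int((traj["excitation"] == DONOR_EXC).sum())


def filter_short(trajectories: dict[int, pd.DataFrame], min_frames: int = 4) -> list[int]:
    """Ids of trajectories with at least ``min_frames`` analyzable frames."""
    if not trajectories:
        warnings.warn("filter_short received no trajectories", RuntimeWarning, stacklevel=2)
        return []
    return [tid for tid, df in trajectories.items() if count_analyzable_frames(df) >= min_frames]


def flag_aggregates(
    trajectories: dict[int, pd.DataFrame],
    intensity_cap_mad: float = 5.0,
    absolute_cap: Optional[float] = None,
    relative_floor: float = 1.5,
) -> dict[int, bool]:
    """Flag objects whose total intensity is abnormally high.

    Each trajectory is summarized by its median total intensity over
    donor-excitation frames; objects above the population median plus
    ``intensity_cap_mad`` MADs are flagged. On a very homogeneous
    population the MAD collapses to the per-trajectory noise scale, so
    the cap is floored at ``relative_floor`` times the population median:
    an aggregate carries at least twice the photons of a single FRET
    pair, while single-pair brightness varies far less than 50%. With
    fewer than 10 objects the population statistics are unreliable and a
    fixed ``absolute_cap`` is required instead.
    """
    med_totals = {}
    for tid, df in trajectories.items():
        don = df[df["excitation"] == DONOR_EXC]
        if len(don) == 0:
            med_totals[tid] = np.nan
            continue
        med_totals[tid] = float(np.median((don["donor"] + don["acceptor"]).to_numpy(float)))

    values = np.array([v for v in med_totals.values() if np.isfinite(v)])
    if len(values) >= 10:
        pop_med = np.median(values)
        mad = np.median(np.abs(values - pop_med))
        cap = max(pop_med + intensity_cap_mad * max(mad, 1e-9), relative_floor * pop_med)
    elif absolute_cap is not None:
        cap = absolute_cap
    else:
        warnings.warn(
            "fewer than 10 trajectories and no absolute_cap given; "
            "aggregate flagging skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return {tid: False for tid in trajectories}
    return {tid: bool(np.isfinite(v) and v > cap) for tid, v in med_totals.items()}


def flag_single_label(
    trajectories: dict[int, pd.DataFrame],
    background_mean: float,
    background_sd: float,
    z: float = Z_DARK,
) -> dict[int, bool]:
    """Flag objects that never show both fluorophores.

    A dual-labeled molecule shows direct acceptor signal on ALEX check
    frames and FRET-pair signal on donor-excitation frames from the very
    start; an object whose dark tail in either channel covers its entire
    record lacked that fluorophore altogether (as opposed to losing it
    mid-trajectory to photobleaching).
    """
    flags = {}
    for tid, df in trajectories.items():
        is_acc = (df["excitation"] == ACCEPTOR_EXC).to_numpy()
        if not is_acc.any():
            raise ValueError(
                "no acceptor-direct-excitation frames: dual-label verification "
                "requires ALEX data"
            )
        acc_sig = df.loc[is_acc, "acceptor"].to_numpy(float)
        acc_dark = _dark_suffix_start(acc_sig, background_mean + z * background_sd)
        don = df.loc[~is_acc]
        total = (don["donor"] + don["acceptor"]).to_numpy(float)
        don_dark = _dark_suffix_start(
            total, 2 * background_mean + z * np.sqrt(2) * background_sd
        )
        flags[tid] = (acc_dark == 0) or (don_dark == 0)
    return flags


@dataclass
class QcResult:
    retained: TrajectorySet
    report: QcReport
    flags: pd.DataFrame  # per-object: aggregate, single_label, short, truncation_frame


def run_qc(
    tset: TrajectorySet,
    min_frames: int = 4,
    intensity_cap_mad: float = 5.0,
    absolute_cap: Optional[float] = None,
    hard_cap_s: float = 60.0,
    background: Optional[tuple[float, float]] = None,
) -> QcResult:
    """Full QC pass: contaminant flags, bleach truncation, length filter.

    Aggregate statistics are computed on bleach-truncated frames so that
    half-bleached molecules do not distort the population intensity scale.
    """
    bg_mean, bg_sd = background if background is not None else estimate_background(tset)
    raw = {tid: df for tid, df in tset.iter_trajectories()}

    single = flag_single_label(raw, bg_mean, bg_sd)
    truncated = {
        tid: truncate_at_bleach(df, bg_mean, bg_sd, hard_cap_s=hard_cap_s)
        for tid, df in raw.items()
    }
    candidates = {tid: df for tid, df in truncated.items() if not single[tid] and len(df) > 0}
    aggregate = flag_aggregates(candidates, intensity_cap_mad, absolute_cap)
    aggregate = {tid: aggregate.get(tid, False) for tid in raw}
    long_enough = set(filter_short(truncated, min_frames)) if truncated else set()

    rows = []
    retained_ids = []
    for tid in raw:
        short = tid not in long_enough
        keep = not (aggregate[tid] or single[tid] or short)
        if keep:
            retained_ids.append(tid)
        rows.append(
            {
                "trajectory_id": tid,
                "aggregate": aggregate[tid],
                "single_label": single[tid],
                "short": short,
                "truncation_frame": len(truncated[tid]),
                "retained": keep,
            }
        )
    flags = pd.DataFrame(rows)

    n_agg = int(flags["aggregate"].sum())
    n_single = int((~flags["aggregate"] & flags["single_label"]).sum())
    n_short = int(
        (~flags["aggregate"] & ~flags["single_label"] & flags["short"]).sum()
    )
    report = QcReport(
        n_input=len(raw),
        n_excluded_aggregate=n_agg,
        n_excluded_single_label=n_single,
        n_excluded_short=n_short,
        n_retained=len(retained_ids),
        truncation_frames={tid: len(truncated[tid]) for tid in retained_ids},
    )

    kept = (
        pd.concat([truncated[tid] for tid in retained_ids], ignore_index=True)
        if retained_ids
        else tset.data.iloc[0:0]
    )
    side = None
    if tset.sidecar is not None and retained_ids:
        pairs = kept[["trajectory_id", "frame"]]
        side = tset.sidecar.merge(pairs, on=["trajectory_id", "frame"], how="inner")
    retained = TrajectorySet(kept.reset_index(drop=True), side, tset.acq)
    return QcResult(retained=retained, report=report, flags=flags)
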