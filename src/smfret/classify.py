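"""Unsupervised folded/unfolded classification on donor-acceptor heatmaps.

A 2D histogram of all donor-excitation observations shows two modes: a
high-acceptor/low-donor (folded, high-FRET) population and a
high-donor/low-acceptor (unfolded) population. A straight threshold line
separating them is placed by derivative-free minimization of the
histogram density integrated along a one-bin-wide band around the line
("minimum integrated intensity"). The time-averaged folded fraction
ϕ_F is the number of folded-side observations over the total, averaged
over several threshold fits from random starting lines, whose spread
quantifies the sensitivity of ϕ_F to the threshold placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import minimize

from smfret.simulate import DONOR_EXC, TrajectorySet

_PENALTY = 1e6


@dataclass
class FretHeatmap:
    """2D donor-acceptor intensity histogram."""

    counts: np.ndarray  # (n_donor_bins, n_acceptor_bins)
    donor_edges: np.ndarray
    acceptor_edges: np.ndarray
    n_observations: int

    @property
    def bin_widths(self) -> tuple[float, float]:
        return (
            float(self.donor_edges[1] - self.donor_edges[0]),
            float(self.acceptor_edges[1] - self.acceptor_edges[0]),
        )

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.donor_edges[:-1] + self.donor_edges[1:]),
            0.5 * (self.acceptor_edges[:-1] + self.acceptor_edges[1:]),
        )

    def to_tsv(self, path) -> None:
        """Write the count matrix with two leading header lines of bin edges."""
        with open(path, "w") as fh:
            fh.write("# donor_edges\t" + "\t".join(f"{e:.6g}" for e in self.donor_edges) + "\n")
            fh.write(
                "# acceptor_edges\t" + "\t".join(f"{e:.6g}" for e in self.acceptor_edges) + "\n"
            )
            np.savetxt(fh, self.counts, fmt="%d", delimiter="\t")

    @classmethod
    def read_tsv(cls, path) -> "FretHeatmap":
        with open(path) as fh:
            donor_edges = np.array(fh.readline().split("\t")[1:], dtype=float)
            acceptor_edges = np.array(fh.readline().split("\t")[1:], dtype=float)
            counts = np.loadtxt(fh, delimiter="\t")
        return cls(counts, donor_edges, acceptor_edges, int(counts.sum()))


@dataclass
class ThresholdLine:
    """Separatrix in (donor, acceptor) space: cos(θ)·d + sin(θ)·a = offset.

    ``slope``/``intercept`` give the same line as acceptor = slope·donor +
    intercept (infinite for a vertical line). ``folded_sign`` is the sign
    of cos(θ)·d + sin(θ)·a − offset on the folded (high-acceptor) side.
    """

    theta: float
    offset: float
    objective: float
    folded_sign: int
    modes: Optional[np.ndarray] = None  # (2, 2) mode centers, folded first

    @property
    def normal(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    @property
    def slope(self) -> float:
        s = np.sin(self.theta)
        if abs(s) < 1e-12:
            return np.inf
        return -np.cos(self.theta) / s

    @property
    def intercept(self) -> float:
        s = np.sin(self.theta)
        if abs(s) < 1e-12:
            return np.nan
        return self.offset / s

    def signed_distance(self, donor, acceptor) -> np.ndarray:
        return np.cos(self.theta) * np.asarray(donor) + np.sin(self.theta) * np.asarray(
            acceptor
        ) - self.offset


@dataclass
class FoldedFraction:
    """Time-averaged folded fraction with its threshold-trial spread."""

    phi_f: float
    sd_trials: float
    n_observations: int
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_f <= 1.0:
            raise ValueError("phi_f must lie in [0, 1]")
        if self.sd_trials < 0:
            raise ValueError("sd_trials must be >= 0")

    def to_dict(self) -> dict:
        return {
            "phi_f": self.phi_f,
            "sd_trials": self.sd_trials,
            "n_observations": self.n_observations,
            "n_trials": self.n_trials,
        }


def _observation_array(observations) -> np.ndarray:
    """Coerce a TrajectorySet / DataFrame / (N,2) array to donor-acceptor pairs."""
    if isinstance(observations, TrajectorySet):
        df = observations.donor_excitation()
        return df[["donor", "acceptor"]].to_numpy(float)
    if isinstance(observations, pd.DataFrame):
        if "excitation" in observations.columns:
            observations = observations[observations["excitation"] == DONOR_EXC]
        return observations[["donor", "acceptor"]].to_numpy(float)
    arr = np.asarray(observations, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("observations must be (n, 2) donor/acceptor pairs")
    return arr


def build_heatmap(observations, n_bins: int = 64) -> FretHeatmap:
    """Histogram donor-excitation observations on [0, 99.5th percentile] axes.

    Out-of-range observations are counted in the edge bins so the matrix
    total equals the observation count.
    """
    obs = _observation_array(observations)
    if len(obs) < 1:
        raise ValueError("need at least one observation")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations contain non-finite intensities")
    hi = np.percentile(obs, 99.5, axis=0)
    if np.any(hi <= 0) or np.ptp(obs[:, 0]) == 0 or np.ptp(obs[:, 1]) == 0:
        raise ValueError("degenerate intensity distribution: cannot bin")
    d_edges = np.linspace(0.0, hi[0], n_bins + 1)
    a_edges = np.linspace(0.0, hi[1], n_bins + 1)
    clipped = np.clip(obs, 0.0, hi - 1e-12 * hi)
    counts, _, _ = np.histogram2d(clipped[:, 0], clipped[:, 1], bins=[d_edges, a_edges])
    return FretHeatmap(counts, d_edges, a_edges, len(obs))


def find_modes(heatmap: FretHeatmap, smooth_sigma: float = 1.5, min_separation: int = 5) -> np.ndarray:
    """Centers (donor, acceptor) of the two strongest well-separated modes."""
    smoothed = gaussian_filter(heatmap.counts, smooth_sigma)
    local_max = (maximum_filter(smoothed, size=5) == smoothed) & (smoothed > 0)
    idx = np.argwhere(local_max)
    if len(idx) < 2:
        raise ValueError("heatmap does not show two detectable modes")
    order = np.argsort(smoothed[local_max.nonzero()])[::-1]
    idx = idx[order]
    first = idx[0]
    second = None
    for cand in idx[1:]:
        if np.linalg.norm(cand - first) >= min_separation:
            second = cand
            break
    if second is None:
        raise ValueError("heatmap does not show two separated modes")
    dc, ac = heatmap.bin_centers()
    modes = np.array(
        [[dc[first[0]], ac[first[1]]], [dc[second[0]], ac[second[1]]]]
    )
    # folded mode = high acceptor relative to donor
    if (modes[0, 1] - modes[0, 0]) < (modes[1, 1] - modes[1, 0]):
        modes = modes[::-1]
    return modes


def _band_objective(params: np.ndarray, heatmap: FretHeatmap, modes: np.ndarray,
                    centers: np.ndarray, counts_flat: np.ndarray) -> float:
    theta, offset = params
    n = np.array([np.cos(theta), np.sin(theta)])
    wd, wa = heatmap.bin_widths
    half_width = 0.5 * (abs(n[0]) * wd + abs(n[1]) * wa)
    proj = centers @ n
    band = np.abs(proj - offset) <= half_width
    s0, s1 = modes @ n - offset
    if s0 * s1 >= 0:  # line does not separate the modes
        return _PENALTY * (1.0 + abs(s0 + s1))
    n_band = int(band.sum())
    if n_band == 0:
        return _PENALTY
    return float(counts_flat[band].sum()) / n_band


def default_start_line(modes: np.ndarray) -> tuple[float, float]:
    """Perpendicular bisector of the two mode centers."""
    direction = modes[1] - modes[0]
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("mode centers coincide")
    n = direction / norm
    theta = float(np.arctan2(n[1], n[0]))
    offset = float(n @ (0.5 * (modes[0] + modes[1])))
    return theta, offset


def fit_threshold(
    heatmap: FretHeatmap,
    start_line: Optional[tuple[float, float]] = None,
    max_iter: int = 300,
    modes: Optional[np.ndarray] = None,
) -> ThresholdLine:
    """Place the minimum-integrated-intensity threshold line.

    Runs Nelder-Mead on (angle, offset) from ``start_line`` (default: the
    perpendicular bisector of the two heatmap modes) minimizing the mean
    histogram count in a one-bin-wide band around the line; lines failing
    to keep one mode on each side are penalized out.
    """
    if modes is None:
        modes = find_modes(heatmap)
    if start_line is None:
        start_line = default_start_line(modes)
    dc, ac = heatmap.bin_centers()
    centers = np.stack(np.meshgrid(dc, ac, indexing="ij"), axis=-1).reshape(-1, 2)
    counts_flat = heatmap.counts.reshape(-1)
    args = (heatmap, modes, centers, counts_flat)

    res = minimize(
        _band_objective,
        np.asarray(start_line, dtype=float),
        args=args,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-10},
    )
    theta, offset = res.x
    obj = _band_objective(res.x, *args)
    if obj >= _PENALTY:
        raise RuntimeError(
            "threshold search did not find a line separating the two modes "
            f"(start={start_line}, final objective={obj:.3g})"
        )
    n = np.array([np.cos(theta), np.sin(theta)])
    folded_sign = int(np.sign(modes[0] @ n - offset))
    return ThresholdLine(float(theta), float(offset), float(obj), folded_sign, modes)


def classify(observations, line: ThresholdLine) -> np.ndarray:
    """Boolean per-observation labels, True = folded.

    An observation exactly on the line is assigned unfolded.
    """
    obs = _observation_array(observations)
    signed = line.signed_distance(obs[:, 0], obs[:, 1]) * line.folded_sign
    return signed > 0


def folded_fraction_from_labels(label_sets: Sequence[np.ndarray]) -> FoldedFraction:
    """Pool per-trial labels into a FoldedFraction (mean and SD over trials)."""
    phis = np.array([float(np.mean(lbl)) for lbl in label_sets])
    sd = float(np.std(phis, ddof=1)) if len(phis) > 1 else 0.0
    return FoldedFraction(
        phi_f=float(np.mean(phis)),
        sd_trials=sd,
        n_observations=int(len(label_sets[0])),
        n_trials=len(phis),
    )


def folded_fraction(
    observations,
    n_bins: int = 64,
    n_trials: int = 5,
    rng_seed=None,
    max_iter: int = 300,
) -> tuple[FoldedFraction, list[ThresholdLine]]:
    """ϕ_F over ``n_trials`` threshold fits from random starting lines."""
    obs = _observation_array(observations)
    heatmap = build_heatmap(obs, n_bins=n_bins)
    modes = find_modes(heatmap)
    theta0, offset0 = default_start_line(modes)
    span = float(np.linalg.norm(modes[1] - modes[0]))
    rng = np.random.default_rng(rng_seed)

    lines, labels = [], []
    failures = 0
    for _ in range(n_trials):
        start = (
            theta0 + rng.uniform(-0.3, 0.3),
            offset0 + rng.uniform(-0.2, 0.2) * span,
        )
        try:
            line = fit_threshold(heatmap, start_line=start, max_iter=max_iter, modes=modes)
        except RuntimeError:
            failures += 1
            continue
        lines.append(line)
        labels.append(classify(obs, line))
    if len(lines) < 3:
        raise RuntimeError(
            f"only {len(lines)} of {n_trials} threshold trials converged; "
            "need at least 3"
        )
    result = folded_fraction_from_labels(labels)
    return result, lines


class ThresholdClassificationModel:
    """Folded/unfolded classification model for a set of observations.

    Parameters
    ----------
    observations
        TrajectorySet, frame-per-row DataFrame, or (n, 2) donor/acceptor
        array; only donor-excitation frames are used.
    n_bins
        Heatmap resolution per axis.
    """

    def __init__(self, observations, n_bins: int = 64):
        self.observations = _observation_array(observations)
        self.n_bins = n_bins
        self.heatmap = build_heatmap(self.observations, n_bins=n_bins)

    def fit(self, n_trials: int = 5, rng_seed=None, max_iter: int = 300) -> "ClassificationResults":
        result, lines = folded_fraction(
            self.observations,
            n_bins=self.n_bins,
            n_trials=n_trials,
            rng_seed=rng_seed,
            max_iter=max_iter,
        )
        best = min(lines, key=lambda l: l.objective)
        labels = classify(self.observations, best)
        return ClassificationResults(self, result, lines, best, labels)


@dataclass
class ClassificationResults:
    """Fitted threshold lines, per-observation labels and ϕ_F."""

    model: ThresholdClassificationModel
    folded_fraction: FoldedFraction
    lines: list[ThresholdLine] = field(repr=False)
    best_line: ThresholdLine = field(repr=False)
    labels: np.ndarray = field(repr=False)  # True = folded

    @property
    def phi_f(self) -> float:
        return self.folded_fraction.phi_f

    @property
    def sd_trials(self) -> float:
        return self.folded_fraction.sd_trials

    def state_means(self) -> dict[str, np.ndarray]:
        """Mean (donor, acceptor) of each classified population."""
        obs = self.model.observations
        return {
            "folded": obs[self.labels].mean(axis=0) if self.labels.any() else None,
            "unfolded": obs[~self.labels].mean(axis=0) if (~self.labels).any() else None,
        }

    def summary(self) -> str:
        ff = self.folded_fraction
        lines = [
            "Threshold classification results",
            "=" * 40,
            f"observations        {ff.n_observations}",
            f"threshold trials    {ff.n_trials}",
            f"phi_F               {ff.phi_f:.4f}",
            f"sd over trials      {ff.sd_trials:.4f}",
            f"best-line objective {self.best_line.objective:.4g}",
            f"best-line slope     {self.best_line.slope:.4g}",
            f"best-line intercept {self.best_line.intercept:.4g}",
        ]
        return "\n".join(lines)
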