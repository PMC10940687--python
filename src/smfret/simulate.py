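"""Synthetic single-molecule FRET trajectory generator.

Emulates the data an alternating-excitation (ALEX) TIRF experiment on
surface-immobilized, dual-labeled enzyme molecules produces: each molecule
switches stochastically between a folded (high-FRET) and an unfolded
(low-FRET) conformation, each fluorophore photobleaches irreversibly at
its own rate, and the camera records donor/acceptor counts every frame,
with periodic acceptor-direct-excitation check frames interleaved.

States are encoded as integers: 0 = folded, 1 = unfolded, 2 = dark
(at least one fluorophore bleached; absorbing).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

FOLDED, UNFOLDED, DARK = 0, 1, 2
STATE_NAMES = {FOLDED: "folded", UNFOLDED: "unfolded", DARK: "dark"}

DONOR_EXC = "donor_exc"
ACCEPTOR_EXC = "acceptor_exc"

TRAJECTORY_COLUMNS = ["trajectory_id", "frame", "time_s", "excitation", "donor", "acceptor"]
SIDECAR_COLUMNS = TRAJECTORY_COLUMNS + ["true_state", "contaminant_flag"]


def forster_efficiency(r_nm: float, r0_nm: float = 4.59) -> float:
    """FRET efficiency E = 1 / (1 + (R/R0)^6) at separation ``r_nm``."""
    return 1.0 / (1.0 + (r_nm / r0_nm) ** 6)


# Defaults below define the simulated study conditions: 200 ms alternating
# excitation for up to one minute; folded/unfolded efficiencies from the
# Förster relation at 2.4 nm and 9.8 nm with R0 = 4.59 nm.


@dataclass(frozen=True)
class AcquisitionSettings:
    """Camera timing and excitation-alternation scheme.

    frame_interval
        Seconds per camera frame (Δt).
    max_duration
        Movie length in seconds; trajectories are recorded to the end of
        the movie (analysis-side truncation at photobleaching is the QC
        module's job).
    alternation_period
        One acceptor-direct-excitation check frame every this many frames
        (the last frame of each period); 2 means strict alternation.
    """

    frame_interval: float = 0.2
    max_duration: float = 60.0
    alternation_period: int = 2

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.max_duration < self.frame_interval:
            raise ValueError("max_duration must cover at least one frame")
        if self.alternation_period < 1:
            raise ValueError("alternation_period must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.max_duration / self.frame_interval))

    def excitation_pattern(self, n_frames: Optional[int] = None) -> np.ndarray:
        """Boolean array, True where the frame is acceptor-direct excitation."""
        n = self.n_frames if n_frames is None else n_frames
        frames = np.arange(n)
        return (frames % self.alternation_period) == (self.alternation_period - 1)


@dataclass(frozen=True)
class TransitionModel:
    """First-order rate constants (s^-1) of the hidden dynamics.

    Conformational switching (k_unfold: folded->unfolded, k_fold:
    unfolded->folded) and per-fluorophore irreversible photobleaching are
    independent Poisson processes; per-frame probabilities follow the
    exact exponential embedding p = 1 - exp(-k * Δt).
    """

    k_unfold: float = 0.298
    k_fold: float = 2.40
    k_bleach_donor: float = 0.04
    k_bleach_acceptor: float = 0.04

    def __post_init__(self) -> None:
        for name in ("k_unfold", "k_fold", "k_bleach_donor", "k_bleach_acceptor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def frame_probability(self, k: float, dt: float) -> float:
        p = -np.expm1(-k * dt)
        if k > 0 and p >= 1.0 - 1e-12:
            warnings.warn(
                f"rate {k} s^-1 at dt={dt} s gives per-frame probability "
                "numerically 1: dynamics are undersampled",
                RuntimeWarning,
                stacklevel=2,
            )
        return float(p)

    def stationary_folded_fraction(self, dt: Optional[float] = None) -> float:
        """Stationary folded occupancy of the alive sub-chain.

        Without ``dt``: the continuous-time ratio k_fold/(k_fold+k_unfold).
        With ``dt``: the stationary fraction of the discrete per-frame
        chain, p_fold/(p_fold+p_unfold) with p = 1 − exp(−k·dt) — the
        occupancy a simulation sampled at that frame interval actually
        produces. The two coincide as dt → 0 but differ by a couple of
        percent once k·dt approaches 1, because the exponential embedding
        compresses the faster rate more.
        """
        if self.k_fold + self.k_unfold == 0:
            return 0.5
        if dt is None:
            return self.k_fold / (self.k_fold + self.k_unfold)
        p_f = -np.expm1(-self.k_fold * dt)
        p_u = -np.expm1(-self.k_unfold * dt)
        return float(p_f / (p_f + p_u))


@dataclass(frozen=True)
class EmissionModel:
    """State-dependent photon statistics of the two detection channels.

    total counts are mean detected photons per frame from the FRET pair
    under donor excitation; they split donor/acceptor as (1-E, E) for the
    frame's conformational state. ``direct_acceptor`` is the mean signal on
    acceptor-direct-excitation check frames while the acceptor is alive.
    Noise is Gaussian with variance = dispersion * mean + read_noise_sd^2
    (shot-noise-like plus camera floor); negative draws clip to zero.
    """

    total_folded: float = 600.0
    total_unfolded: float = 600.0
    e_folded: float = forster_efficiency(2.4)
    e_unfolded: float = forster_efficiency(9.8)
    background: float = 20.0
    dispersion: float = 1.0
    read_noise_sd: float = 10.0
    crosstalk: float = 0.0
    direct_acceptor: float = 300.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_folded <= 1.0 and 0.0 <= self.e_unfolded <= 1.0):
            raise ValueError("FRET efficiencies must lie in [0, 1]")
        for name in ("total_folded", "total_unfolded", "background", "direct_acceptor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ValueError("crosstalk must lie in [0, 1)")


@dataclass(frozen=True)
class ContaminantSpec:
    """Fractions of non-analyzable objects mixed into a dataset.

    Aggregates carry 2-5x the total intensity of a single FRET pair;
    donor-only objects lack the acceptor entirely (no FRET, no
    direct-excitation signal).
    """

    fraction_aggregates: float = 0.0
    fraction_donor_only: float = 0.0
    aggregate_scale_range: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_aggregates <= 1 and 0 <= self.fraction_donor_only <= 1):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if self.fraction_aggregates + self.fraction_donor_only >= 1:
            raise ValueError("contaminant fractions must sum to < 1")


@dataclass
class StatePath:
    """Hidden ground truth for one trajectory."""

    states: np.ndarray  # per-frame, 0/1/2, dark absorbing
    conformation: np.ndarray  # pre-bleach 2-state chain, full length
    donor_bleach_frame: int  # first frame with donor dark (n_frames if never)
    acceptor_bleach_frame: int

    @property
    def first_dark_frame(self) -> int:
        return min(self.donor_bleach_frame, self.acceptor_bleach_frame)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _simulate_conformations(
    n_traj: int,
    n_frames: int,
    p_unfold: float,
    p_fold: float,
    rng: np.random.Generator,
    start: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Batched 2-state Markov chain, shape (n_traj, n_frames)."""
    states = np.empty((n_traj, n_frames), dtype=np.int8)
    if start is None:
        pi_folded = p_fold / (p_fold + p_unfold) if (p_fold + p_unfold) > 0 else 0.5
        states[:, 0] = np.where(rng.random(n_traj) < pi_folded, FOLDED, UNFOLDED)
    else:
        states[:, 0] = start
    for t in range(1, n_frames):
        u = rng.random(n_traj)
        prev = states[:, t - 1]
        exit_p = np.where(prev == FOLDED, p_unfold, p_fold)
        flip = u < exit_p
        states[:, t] = np.where(flip, 1 - prev, prev)
    return states


def _bleach_frames(k: float, dt: float, n_frames: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """First dark frame for each of n fluorophores (n_frames if it survives)."""
    if k <= 0:
        return np.full(n, n_frames, dtype=np.int64)
    # lifetime is exponential; the fluorophore is dark from the frame after
    # the one containing the bleach event
    lifetimes = rng.exponential(1.0 / k, size=n)
    frames = np.floor(lifetimes / dt).astype(np.int64) + 1
    return np.minimum(frames, n_frames)


def simulate_state_path(
    transitions: TransitionModel,
    acq: AcquisitionSettings,
    rng_seed=None,
    start_state: Optional[int] = None,
) -> StatePath:
    """Realize the hidden three-state chain for one molecule.

    The folded/unfolded sub-chain starts from its stationary distribution
    (unless ``start_state`` forces it) and evolves with per-frame
    probabilities 1 - exp(-k Δt); the dark state is entered at the first
    photobleaching event of either fluorophore and is absorbing.
    """
    rng = _as_rng(rng_seed)
    dt = acq.frame_interval
    n = acq.n_frames
    p_u = transitions.frame_probability(transitions.k_unfold, dt)
    p_f = transitions.frame_probability(transitions.k_fold, dt)
    start = None if start_state is None else np.array([start_state], dtype=np.int8)
    conf = _simulate_conformations(1, n, p_u, p_f, rng, start=start)[0]
    donor_b = int(_bleach_frames(transitions.k_bleach_donor, dt, n, 1, rng)[0])
    acceptor_b = int(_bleach_frames(transitions.k_bleach_acceptor, dt, n, 1, rng)[0])
    states = conf.copy()
    dark = min(donor_b, acceptor_b)
    states[dark:] = DARK
    return StatePath(states, conf, donor_b, acceptor_b)


def _emission_means(
    conf: np.ndarray,
    donor_alive: np.ndarray,
    acceptor_alive: np.ndarray,
    acceptor_frames: np.ndarray,
    emission: EmissionModel,
    intensity_scale: float = 1.0,
    has_acceptor: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean donor/acceptor signal (background excluded)."""
    e = np.where(conf == FOLDED, emission.e_folded, emission.e_unfolded)
    total = np.where(conf == FOLDED, emission.total_folded, emission.total_unfolded)
    total = total * intensity_scale * donor_alive
    acc_ok = acceptor_alive & has_acceptor
    e_eff = np.where(acc_ok, e, 0.0)
    donor = total * (1.0 - e_eff)
    acceptor = total * e_eff
    # detection crosstalk moves a fixed fraction of donor-channel photons
    ct = emission.crosstalk
    donor, acceptor = donor * (1.0 - ct), acceptor + donor * ct
    direct = emission.direct_acceptor * intensity_scale * acc_ok
    donor = np.where(acceptor_frames, 0.0, donor)
    acceptor = np.where(acceptor_frames, direct, acceptor)
    return donor, acceptor


def emit_intensities(
    path: StatePath,
    emission: EmissionModel,
    acq: AcquisitionSettings,
    rng_seed=None,
    trajectory_id: int = 0,
    intensity_scale: float = 1.0,
    has_acceptor: bool = True,
) -> pd.DataFrame:
    """Draw the recorded donor/acceptor counts for one hidden state path.

    Returns a frame-per-row DataFrame in the package's trajectory schema.
    """
    rng = _as_rng(rng_seed)
    n = len(path.states)
    frames = np.arange(n)
    acc_frames = acq.excitation_pattern(n)
    donor_alive = frames < path.donor_bleach_frame
    acceptor_alive = frames < path.acceptor_bleach_frame
    mean_d, mean_a = _emission_means(
        path.conformation, donor_alive, acceptor_alive, acc_frames, emission,
        intensity_scale=intensity_scale, has_acceptor=has_acceptor,
    )
    donor = _noisy(mean_d, emission, rng)
    acceptor = _noisy(mean_a, emission, rng)
    return pd.DataFrame(
        {
            "trajectory_id": np.full(n, trajectory_id),
            "frame": frames,
            "time_s": frames * acq.frame_interval,
            "excitation": np.where(acc_frames, ACCEPTOR_EXC, DONOR_EXC),
            "donor": donor,
            "acceptor": acceptor,
        }
    )


def _noisy(mean_signal: np.ndarray, emission: EmissionModel, rng: np.random.Generator) -> np.ndarray:
    mean = mean_signal + emission.background
    sd = np.sqrt(emission.dispersion * mean + emission.read_noise_sd**2)
    counts = rng.normal(mean, sd)
    return np.clip(np.round(counts, 3), 0.0, None)


@dataclass
class TrajectorySet:
    """A dataset of per-frame trajectory records plus optional ground truth.

    ``data`` holds one row per recorded frame (trajectory_id, frame,
    time_s, excitation, donor, acceptor); ``sidecar`` mirrors it with
    true_state and contaminant_flag columns when the set was simulated.
    """

    data: pd.DataFrame
    sidecar: Optional[pd.DataFrame] = None
    acq: AcquisitionSettings = field(default_factory=AcquisitionSettings)

    @property
    def trajectory_ids(self) -> np.ndarray:
        return self.data["trajectory_id"].unique()

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectory_ids)

    def iter_trajectories(self) -> Iterator[tuple[int, pd.DataFrame]]:
        for tid, grp in self.data.groupby("trajectory_id", sort=True):
            yield tid, grp

    def donor_excitation(self) -> pd.DataFrame:
        return self.data[self.data["excitation"] == DONOR_EXC]

    def subset(self, trajectory_ids) -> "TrajectorySet":
        mask = self.data["trajectory_id"].isin(trajectory_ids)
        side = None
        if self.sidecar is not None:
            side = self.sidecar[self.sidecar["trajectory_id"].isin(trajectory_ids)].reset_index(drop=True)
        return TrajectorySet(self.data[mask].reset_index(drop=True), side, self.acq)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.3f")
        if sidecar_path is not None:
            if self.sidecar is None:
                raise ValueError("no ground-truth sidecar on this TrajectorySet")
            self.sidecar.to_csv(sidecar_path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def read_tsv(cls, path, sidecar_path=None, acq: Optional[AcquisitionSettings] = None) -> "TrajectorySet":
        data = pd.read_csv(path, sep="\t")
        missing = set(TRAJECTORY_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"trajectory file {path} lacks columns: {sorted(missing)}")
        side = pd.read_csv(sidecar_path, sep="\t") if sidecar_path else None
        if acq is None:
            acq = _infer_acquisition(data)
        return cls(data, side, acq)


def _infer_acquisition(data: pd.DataFrame) -> AcquisitionSettings:
    first = data[data["trajectory_id"] == data["trajectory_id"].iloc[0]]
    times = first["time_s"].to_numpy()
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.2
    acc = np.flatnonzero((first["excitation"] == ACCEPTOR_EXC).to_numpy())
    period = int(np.median(np.diff(acc))) if len(acc) > 1 else 2
    max_dur = float(data["time_s"].max()) + dt
    return AcquisitionSettings(frame_interval=dt, max_duration=max_dur, alternation_period=period)


def generate_dataset(
    n_trajectories: int,
    transitions: Optional[TransitionModel] = None,
    emission: Optional[EmissionModel] = None,
    contaminants: Optional[ContaminantSpec] = None,
    acq: Optional[AcquisitionSettings] = None,
    rng_seed=0,
) -> TrajectorySet:
    """Simulate a full dataset with ground-truth sidecar.

    Contaminant identity, hidden states, bleach times and photon noise are
    all drawn from one seeded generator, so a fixed seed reproduces the
    dataset byte-for-byte.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    transitions = transitions or TransitionModel()
    emission = emission or EmissionModel()
    contaminants = contaminants or ContaminantSpec()
    acq = acq or AcquisitionSettings()
    rng = _as_rng(rng_seed)

    dt = acq.frame_interval
    n_frames = acq.n_frames
    p_u = transitions.frame_probability(transitions.k_unfold, dt)
    p_f = transitions.frame_probability(transitions.k_fold, dt)

    u = rng.random(n_trajectories)
    flags = np.full(n_trajectories, "none", dtype=object)
    flags[u < contaminants.fraction_aggregates] = "aggregate"
    both = contaminants.fraction_aggregates + contaminants.fraction_donor_only
    flags[(u >= contaminants.fraction_aggregates) & (u < both)] = "donor_only"
    lo, hi = contaminants.aggregate_scale_range
    scales = np.where(flags == "aggregate", rng.uniform(lo, hi, n_trajectories), 1.0)

    conf = _simulate_conformations(n_trajectories, n_frames, p_u, p_f, rng)
    donor_b = _bleach_frames(transitions.k_bleach_donor, dt, n_frames, n_trajectories, rng)
    acceptor_b = _bleach_frames(transitions.k_bleach_acceptor, dt, n_frames, n_trajectories, rng)
    acceptor_b = np.where(flags == "donor_only", 0, acceptor_b)

    chunks, side_chunks = [], []
    for i in range(n_trajectories):
        path = StatePath(
            states=_with_dark(conf[i], min(donor_b[i], acceptor_b[i])),
            conformation=conf[i],
            donor_bleach_frame=int(donor_b[i]),
            acceptor_bleach_frame=int(acceptor_b[i]),
        )
        traj = emit_intensities(
            path, emission, acq, rng_seed=rng, trajectory_id=i,
            intensity_scale=float(scales[i]), has_acceptor=flags[i] != "donor_only",
        )
        chunks.append(traj)
        side = traj.copy()
        side["true_state"] = np.vectorize(STATE_NAMES.get)(path.states)
        side["contaminant_flag"] = flags[i]
        side_chunks.append(side)

    data = pd.concat(chunks, ignore_index=True)
    sidecar = pd.concat(side_chunks, ignore_index=True)
    return TrajectorySet(data, sidecar, acq)


def _with_dark(conf: np.ndarray, dark_from: int) -> np.ndarray:
    s = conf.copy()
    s[dark_from:] = DARK
    return s


def transition_model_from_dict(d: dict) -> TransitionModel:
    return _from_dict(TransitionModel, d)


def emission_model_from_dict(d: dict) -> EmissionModel:
    return _from_dict(EmissionModel, d)


def acquisition_from_dict(d: dict) -> AcquisitionSettings:
    return _from_dict(AcquisitionSettings, d)


def contaminants_from_dict(d: dict) -> ContaminantSpec:
    return _from_dict(ContaminantSpec, d)


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    d = dict(d)
    if "aggregate_scale_range" in d and isinstance(d["aggregate_scale_range"], list):
        d["aggregate_scale_range"] = tuple(d["aggregate_scale_range"])
    return cls(**d)
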