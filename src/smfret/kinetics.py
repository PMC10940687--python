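"""Three-state hidden-Markov kinetics of folding/unfolding trajectories.

The hidden chain has states folded, unfolded and dark (photobleached,
absorbing by default) and steps once per camera frame Δt. Donor-excitation
frames emit a (donor, acceptor) pair from a state-specific 2D Gaussian;
acceptor-direct-excitation check frames carry no folded/unfolded
information and enter the likelihood as uninformative observations — the
latent chain still steps through them, so the fitted transition matrix is
a genuine per-frame (Δt) matrix and rates follow the exponential
embedding k = −ln(1 − p)/Δt. Standard errors come from the inverse Fisher
information of the Bernoulli state exit (Cramér–Rao lower bound),
evaluated at the interval where exits are actually observed — the
spacing of informative frames — so the reported uncertainty reflects the
information the interleaved acquisition truly provides.

Baum-Welch is implemented here (vectorized across trajectories) rather
than delegated, because the fit must pin the dark state's absorbing
transition row and emission parameters during M-steps, expose
posterior-weighted expected transition counts, and accept per-frame
uninformative observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from smfret.simulate import DARK, DONOR_EXC, FOLDED, UNFOLDED, STATE_NAMES, TrajectorySet

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmSpec:
    """Parameters of the three-state Gaussian-emission hidden Markov model."""

    means: np.ndarray  # (3, 2) per-state (donor, acceptor) emission means
    variances: np.ndarray  # (3, 2) diagonal emission variances
    transmat: np.ndarray  # (3, 3) per-frame, row-stochastic
    startprob: np.ndarray  # (3,)

    def validate(self) -> None:
        if self.means.shape != (3, 2) or self.variances.shape != (3, 2):
            raise ValueError("means and variances must be (3, 2)")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")
        if self.transmat.shape != (3, 3) or np.any(self.transmat < 0) or np.any(self.transmat > 1):
            raise ValueError("transmat must be (3, 3) with entries in [0, 1]")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transmat rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must sum to 1")


@dataclass
class TransitionCounts:
    """Per-frame transition probabilities with the counts behind them.

    ``probabilities`` rows for states never observed to transition are NaN
    (missing, not zero).
    """

    probabilities: np.ndarray  # (3, 3)
    counts: np.ndarray  # (3, 3) transition (or expected transition) counts
    dt: float


@dataclass
class RateEstimate:
    """Effective folding/unfolding rate constants with CRLB standard errors."""

    k_fold: float
    k_unfold: float
    se_k_fold: float
    se_k_unfold: float
    p_fold: float  # per-frame unfolded->folded probability (bleach-conditioned)
    p_unfold: float
    n_fold_opportunities: float  # frames from which a U->F transition could occur
    n_unfold_opportunities: float
    dt: float

    def to_dict(self) -> dict:
        return {
            "k_fold": self.k_fold,
            "k_unfold": self.k_unfold,
            "se_k_fold": self.se_k_fold,
            "se_k_unfold": self.se_k_unfold,
            "n_transitions": {
                "fold_opportunities": self.n_fold_opportunities,
                "unfold_opportunities": self.n_unfold_opportunities,
            },
            "dt": self.dt,
        }


def rates_from_probabilities(p_exit: float, dt: float) -> float:
    """Convert a per-frame exit probability to a rate, k = −ln(1 − p)/Δt."""
    if not 0.0 <= p_exit < 1.0:
        raise ValueError(
            f"exit probability {p_exit} outside [0, 1): dynamics faster than sampling"
        )
    return float(-np.log1p(-p_exit) / dt)


def crlb_standard_errors(n: float, p: float, dt: float) -> float:
    """CRLB standard error of k̂ from n per-frame Bernoulli exit trials.

    Var(p̂) = p(1−p)/n (inverse Fisher information); the delta method
    through k = −ln(1−p)/Δt gives SE_k = sqrt(p(1−p)/n) / ((1−p)·Δt).
    """
    if n <= 0:
        return float("nan")
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    return float(np.sqrt(p * (1.0 - p) / n) / ((1.0 - p) * dt))


def transition_probabilities(
    state_paths: Sequence[np.ndarray], dt: float, n_states: int = 3
) -> TransitionCounts:
    """Count-based per-frame transition matrix from decoded state paths.

    p_ij = n_ij / Σ_j n_ij over consecutive-frame pairs, pooled across
    trajectories.
    """
    counts = np.zeros((n_states, n_states))
    for path in state_paths:
        path = np.asarray(path)
        if len(path) < 2:
            continue
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
    row_sums = counts.sum(axis=1)
    probs = np.full((n_states, n_states), np.nan)
    visited = row_sums > 0
    probs[visited] = counts[visited] / row_sums[visited, None]
    return TransitionCounts(probs, counts, dt)


def conditional_exit_probabilities(counts: np.ndarray) -> tuple[float, float]:
    """Folded→unfolded and unfolded→folded probabilities conditioned on staying alive.

    Transitions into the dark state are photobleaching, not conformational
    exchange, so they are excluded from the denominators.
    """
    n_f = counts[FOLDED, FOLDED] + counts[FOLDED, UNFOLDED]
    n_u = counts[UNFOLDED, UNFOLDED] + counts[UNFOLDED, FOLDED]
    p_fu = counts[FOLDED, UNFOLDED] / n_f if n_f > 0 else np.nan
    p_uf = counts[UNFOLDED, FOLDED] / n_u if n_u > 0 else np.nan
    return float(p_fu), float(p_uf)


def lag_exit_probability(p_exit: float, p_return: float, lag: float) -> float:
    """Exit probability of a two-state chain observed every ``lag`` frames.

    For per-frame exit/return probabilities (p, q) the chain's relaxation
    factor is λ = 1 − p − q and the probability of being in the other
    state ``lag`` frames later is p/(p+q) · (1 − λ^lag). Falls back to the
    per-frame value when λ ≤ 0 (dynamics at the sampling edge).
    """
    total = p_exit + p_return
    lam = 1.0 - total
    if total <= 0:
        return 0.0
    if lam <= 0 or lag <= 1:
        return p_exit
    return float(p_exit / total * (1.0 - lam**lag))


def rate_estimate_from_counts(counts: np.ndarray, dt: float) -> RateEstimate:
    """Rates and CRLB errors from a (expected) transition-count matrix."""
    p_fu, p_uf = conditional_exit_probabilities(counts)
    n_f = float(counts[FOLDED, FOLDED] + counts[FOLDED, UNFOLDED])
    n_u = float(counts[UNFOLDED, UNFOLDED] + counts[UNFOLDED, FOLDED])
    k_unfold = rates_from_probabilities(p_fu, dt) if np.isfinite(p_fu) else float("nan")
    k_fold = rates_from_probabilities(p_uf, dt) if np.isfinite(p_uf) else float("nan")
    se_unfold = crlb_standard_errors(n_f, p_fu, dt) if np.isfinite(p_fu) else float("nan")
    se_fold = crlb_standard_errors(n_u, p_uf, dt) if np.isfinite(p_uf) else float("nan")
    return RateEstimate(
        k_fold=k_fold,
        k_unfold=k_unfold,
        se_k_fold=se_fold,
        se_k_unfold=se_unfold,
        p_fold=p_uf,
        p_unfold=p_fu,
        n_fold_opportunities=n_u,
        n_unfold_opportunities=n_f,
        dt=dt,
    )


def _pack_trajectories(tset_or_list, dt: Optional[float]):
    """Build padded (N, T, 2) observation and mask arrays."""
    if isinstance(tset_or_list, TrajectorySet):
        dt = tset_or_list.acq.frame_interval if dt is None else dt
        trajs = [df for _, df in tset_or_list.iter_trajectories()]
        ids = [tid for tid, _ in tset_or_list.iter_trajectories()]
    else:
        trajs = list(tset_or_list)
        ids = list(range(len(trajs)))
        if dt is None:
            raise ValueError("dt is required when passing raw trajectory frames")
    if not trajs:
        raise ValueError("no trajectories to fit")
    lengths = np.array([len(df) for df in trajs])
    T = int(lengths.max())
    N = len(trajs)
    obs = np.zeros((N, T, 2))
    informative = np.zeros((N, T), dtype=bool)
    active = np.zeros((N, T), dtype=bool)
    for i, df in enumerate(trajs):
        L = len(df)
        obs[i, :L, 0] = df["donor"].to_numpy(float)
        obs[i, :L, 1] = df["acceptor"].to_numpy(float)
        informative[i, :L] = (df["excitation"] == DONOR_EXC).to_numpy()
        active[i, :L] = True
    return obs, informative, active, lengths, ids, dt


def _default_init(obs: np.ndarray, informative: np.ndarray, background: float) -> HmmSpec:
    """Heuristic initialization: split donor-excitation frames by channel dominance."""
    pts = obs[informative]
    folded_like = pts[:, 1] > pts[:, 0]
    groups = [pts[folded_like], pts[~folded_like]]
    means = np.zeros((3, 2))
    variances = np.ones((3, 2))
    for s, g in zip((FOLDED, UNFOLDED), groups):
        if len(g) < 2:
            raise ValueError("cannot initialize emissions: one population is empty")
        means[s] = g.mean(axis=0)
        variances[s] = np.maximum(g.var(axis=0), 1.0)
    means[DARK] = background
    variances[DARK] = np.maximum(background, 25.0)
    transmat = np.array(
        [[0.89, 0.10, 0.01], [0.10, 0.89, 0.01], [0.0, 0.0, 1.0]]
    )
    startprob = np.array([0.5, 0.5, 0.0])
    return HmmSpec(means, variances, transmat, startprob)


def init_from_classification(results, background: float = 20.0, jitter_seed=None) -> HmmSpec:
    """Seed HMM emissions from threshold-classification cluster statistics."""
    obs = results.model.observations
    labels = results.labels
    means = np.zeros((3, 2))
    variances = np.ones((3, 2))
    for s, mask in ((FOLDED, labels), (UNFOLDED, ~labels)):
        if mask.sum() < 2:
            raise ValueError("classification results leave one state empty")
        means[s] = obs[mask].mean(axis=0)
        variances[s] = np.maximum(obs[mask].var(axis=0), 1.0)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        means[:2] += rng.normal(0.0, 0.01 * np.abs(means[:2]) + 1e-6)
    means[DARK] = background
    variances[DARK] = np.maximum(background, 25.0)
    transmat = np.array(
        [[0.89, 0.10, 0.01], [0.10, 0.89, 0.01], [0.0, 0.0, 1.0]]
    )
    return HmmSpec(means, variances, transmat, np.array([0.5, 0.5, 0.0]))


class KineticsModel:
    """Hidden-Markov kinetics model for a set of smFRET trajectories.

    Parameters
    ----------
    trajectories
        TrajectorySet (typically QC-passed and bleach-truncated) or a list
        of frame-per-row DataFrames.
    dt
        Camera frame interval in seconds; taken from the TrajectorySet's
        acquisition settings when omitted.
    init
        Optional HmmSpec starting point (e.g. from
        ``init_from_classification``); a data-driven heuristic otherwise.
    dark_absorbing
        Pin the dark state's transition row to absorbing (default). Set
        False to let it be estimated.
    update_emissions
        Re-estimate folded/unfolded emission parameters during EM; dark
        emissions stay pinned either way.
    """

    def __init__(
        self,
        trajectories,
        dt: Optional[float] = None,
        init: Optional[HmmSpec] = None,
        dark_absorbing: bool = True,
        update_emissions: bool = True,
        background: float = 20.0,
    ):
        (
            self._obs,
            self._informative,
            self._active,
            self.lengths,
            self.trajectory_ids,
            self.dt,
        ) = _pack_trajectories(trajectories, dt)
        self.dark_absorbing = dark_absorbing
        self.update_emissions = update_emissions
        self.background = background
        self.init = init if init is not None else _default_init(self._obs, self._informative, background)
        self.init.validate()

    # -- E-step pieces -------------------------------------------------

    def _emission_b(self, spec: HmmSpec) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame emission likelihoods, normalized so max over states = 1.

        Returns (b, log_norm): b is (N, T, 3); log_norm the per-frame log
        of the normalization, needed to reconstruct the log-likelihood.
        Uninformative (ALEX check / padded) frames get b = 1 for every
        state.
        """
        N, T, _ = self._obs.shape
        logb = np.zeros((N, T, 3))
        x = self._obs[self._informative]  # (M, 2)
        ll = -0.5 * (
            ((x[:, None, :] - spec.means[None, :, :]) ** 2 / spec.variances[None, :, :]).sum(-1)
            + np.log(spec.variances).sum(-1)[None, :]
            + 2 * _LOG2PI
        )
        logb[self._informative] = ll
        log_norm = logb.max(axis=2)
        b = np.exp(logb - log_norm[:, :, None])
        return b, log_norm

    def _forward_backward(self, spec: HmmSpec):
        b, log_norm = self._emission_b(spec)
        N, T, K = b.shape
        A = spec.transmat
        active = self._active

        alpha = np.zeros((N, T, K))
        c = np.ones((N, T))
        a0 = spec.startprob[None, :] * b[:, 0]
        c[:, 0] = a0.sum(axis=1)
        alpha[:, 0] = a0 / c[:, 0, None]
        for t in range(1, T):
            prop = (alpha[:, t - 1] @ A) * b[:, t]
            ct = prop.sum(axis=1)
            act = active[:, t]
            safe = np.where(act & (ct > 0), ct, 1.0)
            alpha[:, t] = np.where(act[:, None], prop / safe[:, None], alpha[:, t - 1])
            c[:, t] = safe

        beta = np.ones((N, T, K))
        for t in range(T - 2, -1, -1):
            nxt = active[:, t + 1]
            prop = (b[:, t + 1] * beta[:, t + 1]) @ A.T / c[:, t + 1, None]
            beta[:, t] = np.where(nxt[:, None], prop, 1.0)

        gamma = alpha * beta
        gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)

        xi_sum = np.zeros((K, K))
        for t in range(T - 1):
            nxt = active[:, t + 1]
            if not nxt.any():
                continue
            w = (b[:, t + 1] * beta[:, t + 1]) / c[:, t + 1, None]
            xi = alpha[:, t, :, None] * A[None, :, :] * w[:, None, :]
            xi_sum += xi[nxt].sum(axis=0)

        loglik = float((np.log(c[active]) ).sum() + log_norm[active].sum())
        return gamma, xi_sum, loglik

    # -- fitting -------------------------------------------------------

    def fit(self, max_iter: int = 500, tol: float = 1e-6) -> "KineticsResults":
        """Run Baum-Welch to convergence of the mean per-frame log-likelihood."""
        spec = HmmSpec(
            self.init.means.copy(),
            self.init.variances.copy(),
            self.init.transmat.copy(),
            self.init.startprob.copy(),
        )
        n_obs = int(self._active.sum())
        history: list[float] = []
        converged = False
        gamma = xi_sum = None
        for _ in range(max_iter):
            gamma, xi_sum, loglik = self._forward_backward(spec)
            history.append(loglik / n_obs)
            if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
                converged = True
                break

            # M-step: transitions
            new_A = spec.transmat.copy()
            row = xi_sum.sum(axis=1)
            ok = row > 1e-12
            new_A[ok] = xi_sum[ok] / row[ok, None]
            if self.dark_absorbing:
                new_A[DARK] = np.array([0.0, 0.0, 1.0])
            spec.transmat = new_A

            start = gamma[:, 0, :].mean(axis=0)
            spec.startprob = start / start.sum()

            if self.update_emissions:
                w = gamma * self._informative[:, :, None]
                for s in (FOLDED, UNFOLDED):
                    ws = w[:, :, s]
                    tot = ws.sum()
                    if tot < 1e-10:
                        continue
                    mean = (ws[:, :, None] * self._obs).sum(axis=(0, 1)) / tot
                    var = (ws[:, :, None] * (self._obs - mean) ** 2).sum(axis=(0, 1)) / tot
                    spec.means[s] = mean
                    spec.variances[s] = np.maximum(var, 1e-6)
                if np.linalg.norm(spec.means[FOLDED] - spec.means[UNFOLDED]) < 1e-6:
                    raise RuntimeError(
                        "state collapse: folded and unfolded emissions became identical"
                    )
        else:
            delta = history[-1] - history[-2] if len(history) > 1 else float("nan")
            warnings.warn(
                f"EM did not converge in {max_iter} iterations (last Δll = {delta:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
            gamma, xi_sum, loglik = self._forward_backward(spec)
            history.append(loglik / n_obs)

        counts = TransitionCounts(
            probabilities=_probs_from_counts(xi_sum),
            counts=xi_sum,
            dt=self.dt,
        )
        rates = self._rate_estimate(xi_sum, gamma)
        decoded = self._decode_posterior(gamma)
        return KineticsResults(
            model=self,
            spec=spec,
            rates=rates,
            transition_counts=counts,
            posterior=gamma,
            decoded_paths=decoded,
            loglik_path=np.array(history),
            converged=converged,
        )

    def _rate_estimate(self, xi_sum: np.ndarray, gamma: np.ndarray) -> RateEstimate:
        """Rates from per-frame expected counts, SEs at the observation interval.

        Point estimates use the per-frame (Δt) conditional exit
        probabilities via k = −ln(1 − p)/Δt. The CRLB standard errors are
        evaluated where exits are actually observed: with interleaved
        acceptor-excitation check frames, consecutive informative frames
        sit L = total/informative frames apart, and the Bernoulli exit
        statistics that carry the information are the lag-L exit
        probability over the posterior occupancy of informative frames.
        For all-informative data L = 1 and this reduces to the plain
        per-frame formula.
        """
        est = rate_estimate_from_counts(xi_sum, self.dt)
        n_active = float(self._active.sum())
        n_informative = float(self._informative.sum())
        if n_informative <= 0 or n_informative == n_active:
            return est
        lag = n_active / n_informative

        w = gamma * self._informative[:, :, None]
        n_f_obs = float(w[:, :, FOLDED].sum())
        n_u_obs = float(w[:, :, UNFOLDED].sum())
        p_fu, p_uf = est.p_unfold, est.p_fold
        if not (np.isfinite(p_fu) and np.isfinite(p_uf)):
            return est
        b_lag = lag_exit_probability(p_fu, p_uf, lag)
        a_lag = lag_exit_probability(p_uf, p_fu, lag)
        se_unfold = crlb_standard_errors(n_f_obs, b_lag, lag * self.dt)
        se_fold = crlb_standard_errors(n_u_obs, a_lag, lag * self.dt)
        return RateEstimate(
            k_fold=est.k_fold,
            k_unfold=est.k_unfold,
            se_k_fold=se_fold,
            se_k_unfold=se_unfold,
            p_fold=est.p_fold,
            p_unfold=est.p_unfold,
            n_fold_opportunities=est.n_fold_opportunities,
            n_unfold_opportunities=est.n_unfold_opportunities,
            dt=self.dt,
        )

    def _decode_posterior(self, gamma: np.ndarray) -> list[np.ndarray]:
        """Most-probable state per frame (posterior decoding)."""
        out = []
        for i, L in enumerate(self.lengths):
            out.append(gamma[i, :L].argmax(axis=1).astype(np.int8))
        return out

    def decode_viterbi(self, spec: HmmSpec) -> list[np.ndarray]:
        """Jointly most-probable state paths under ``spec`` (Viterbi)."""
        b, _ = self._emission_b(spec)
        logA = np.log(np.maximum(spec.transmat, 1e-300))
        logb = np.log(np.maximum(b, 1e-300))
        out = []
        for i, L in enumerate(self.lengths):
            delta = np.log(np.maximum(spec.startprob, 1e-300)) + logb[i, 0]
            back = np.zeros((L, 3), dtype=np.int8)
            for t in range(1, L):
                score = delta[:, None] + logA
                back[t] = score.argmax(axis=0)
                delta = score.max(axis=0) + logb[i, t]
            path = np.zeros(L, dtype=np.int8)
            path[-1] = delta.argmax()
            for t in range(L - 2, -1, -1):
                path[t] = back[t + 1, path[t + 1]]
            out.append(path)
        return out


def _probs_from_counts(counts: np.ndarray) -> np.ndarray:
    row = counts.sum(axis=1)
    probs = np.full_like(counts, np.nan)
    ok = row > 1e-12
    probs[ok] = counts[ok] / row[ok, None]
    return probs


def fit_hmm(
    trajectories,
    init: Optional[HmmSpec] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    dt: Optional[float] = None,
    **kwargs,
) -> "KineticsResults":
    """Convenience wrapper: build a KineticsModel and fit it."""
    return KineticsModel(trajectories, dt=dt, init=init, **kwargs).fit(
        max_iter=max_iter, tol=tol
    )


@dataclass
class KineticsResults:
    """Fitted HMM with derived rate constants and decoded state paths."""

    model: KineticsModel
    spec: HmmSpec
    rates: RateEstimate
    transition_counts: TransitionCounts
    posterior: np.ndarray = field(repr=False)  # (N, T, 3) state probabilities
    decoded_paths: list = field(repr=False)
    loglik_path: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def k_fold(self) -> float:
        return self.rates.k_fold

    @property
    def k_unfold(self) -> float:
        return self.rates.k_unfold

    def stationary_folded_fraction(self) -> float:
        """k_fold / (k_fold + k_unfold) implied by the fitted rates."""
        return self.k_fold / (self.k_fold + self.k_unfold)

    def occupancy_folded_fraction(self) -> float:
        """Posterior share of folded among folded+unfolded donor-excitation frames."""
        w = self.posterior * self.model._informative[:, :, None]
        n_f = w[:, :, FOLDED].sum()
        n_u = w[:, :, UNFOLDED].sum()
        return float(n_f / (n_f + n_u))

    def viterbi_rate_estimate(self) -> RateEstimate:
        """Rates from hard transition counts along Viterbi paths (alternative route)."""
        paths = self.model.decode_viterbi(self.spec)
        tc = transition_probabilities(paths, self.model.dt)
        return rate_estimate_from_counts(tc.counts, self.model.dt)

    def decoded_frame(self, trajectories: Optional[TrajectorySet] = None) -> pd.DataFrame:
        """Per-frame table with a decoded ``state`` column appended."""
        rows = []
        for tid, path, L in zip(self.model.trajectory_ids, self.decoded_paths, self.model.lengths):
            rows.append(
                pd.DataFrame(
                    {
                        "trajectory_id": tid,
                        "frame_pos": np.arange(L),
                        "state": [STATE_NAMES[int(s)] for s in path],
                    }
                )
            )
        decoded = pd.concat(rows, ignore_index=True)
        if trajectories is not None:
            data = trajectories.data.copy()
            data["frame_pos"] = data.groupby("trajectory_id").cumcount()
            decoded = data.merge(decoded, on=["trajectory_id", "frame_pos"]).drop(
                columns="frame_pos"
            )
        return decoded

    def summary(self) -> str:
        r = self.rates
        lines = [
            "Hidden-Markov kinetics results",
            "=" * 44,
            f"trajectories          {len(self.model.lengths)}",
            f"frames                {int(self.model._active.sum())}",
            f"dt                    {self.model.dt:.3f} s",
            f"EM iterations         {len(self.loglik_path)}"
            + ("" if self.converged else "  (not converged)"),
            f"log-likelihood/frame  {self.loglik_path[-1]:.4f}",
            "-" * 44,
            f"k_fold                {r.k_fold:.3f} ± {r.se_k_fold:.3f} s^-1",
            f"k_unfold              {r.k_unfold:.3f} ± {r.se_k_unfold:.3f} s^-1",
            f"stationary phi_F      {self.stationary_folded_fraction():.4f}",
            f"occupancy phi_F       {self.occupancy_folded_fraction():.4f}",
        ]
        return "\n".join(lines)
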