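"""Generator statistics: Markov dynamics, emissions, bleaching, determinism."""

import numpy as np
import pytest

from smfret.simulate import (
    FOLDED,
    UNFOLDED,
    DARK,
    AcquisitionSettings,
    ContaminantSpec,
    EmissionModel,
    TransitionModel,
    TrajectorySet,
    emit_intensities,
    forster_efficiency,
    generate_dataset,
    simulate_state_path,
)

LONG_ACQ = AcquisitionSettings(frame_interval=0.2, max_duration=0.2 * 100_000)
NO_BLEACH = dict(k_bleach_donor=0.0, k_bleach_acceptor=0.0)


def exit_frequencies(states):
    """Empirical per-frame exit probability from each conformational state."""
    out = {}
    for s in (FOLDED, UNFOLDED):
        here = states[:-1] == s
        out[s] = ((states[1:] != s) & here).sum() / max(here.sum(), 1), here.sum()
    return out


class TestStatePath:
    def test_zero_rates_keep_the_start_state(self):
        tm = TransitionModel(k_unfold=0.0, k_fold=0.0, **NO_BLEACH)
        path = simulate_state_path(tm, AcquisitionSettings(), rng_seed=0, start_state=FOLDED)
        assert np.all(path.states == FOLDED)

    def test_symmetric_rates_give_half_folded_occupancy(self):
        tm = TransitionModel(k_unfold=2.0, k_fold=2.0, **NO_BLEACH)
        path = simulate_state_path(tm, LONG_ACQ, rng_seed=1)
        assert abs(np.mean(path.conformation == FOLDED) - 0.5) < 0.02

    def test_exit_frequencies_match_exponential_embedding(self):
        # 5% EGPMA 45 degC condition: k_unfold = 0.298, k_fold = 2.40 1/s
        tm = TransitionModel(k_unfold=0.298, k_fold=2.40, **NO_BLEACH)
        path = simulate_state_path(tm, LONG_ACQ, rng_seed=2)
        freqs = exit_frequencies(path.conformation)
        for s, k in ((FOLDED, 0.298), (UNFOLDED, 2.40)):
            p_hat, n = freqs[s]
            p = 1.0 - np.exp(-k * 0.2)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) < 3 * se

    def test_stationary_folded_fraction(self):
        tm = TransitionModel(k_unfold=0.298, k_fold=2.40, **NO_BLEACH)
        path = simulate_state_path(tm, LONG_ACQ, rng_seed=3)
        # occupancy follows the discrete per-frame chain's stationary law
        target = tm.stationary_folded_fraction(dt=0.2)
        assert abs(np.mean(path.conformation == FOLDED) - target) < 0.01
        # which approaches the rate-ratio form in the fast-sampling limit
        assert tm.stationary_folded_fraction(dt=1e-6) == pytest.approx(
            tm.stationary_folded_fraction(), abs=1e-6
        )

    def test_dwell_lengths_are_geometric(self):
        tm = TransitionModel(k_unfold=1.5, k_fold=1.5, **NO_BLEACH)
        path = simulate_state_path(tm, LONG_ACQ, rng_seed=4)
        states = path.conformation
        # run lengths of folded dwells
        changes = np.flatnonzero(np.diff(states)) + 1
        bounds = np.concatenate(([0], changes, [len(states)]))
        lengths = np.diff(bounds)
        run_states = states[bounds[:-1]]
        dwells = lengths[run_states == FOLDED]
        p = 1.0 - np.exp(-1.5 * 0.2)
        # KS-style sup-norm between empirical and geometric survival curves
        ks = np.arange(1, 40)
        emp = np.array([(dwells >= k).mean() for k in ks])
        theo = (1 - p) ** (ks - 1)
        assert len(dwells) > 3000
        assert np.max(np.abs(emp - theo)) < 0.02

    def test_dark_state_is_absorbing(self):
        tm = TransitionModel(k_unfold=1.0, k_fold=1.0, k_bleach_donor=0.5, k_bleach_acceptor=0.5)
        path = simulate_state_path(tm, AcquisitionSettings(), rng_seed=5)
        dark = np.flatnonzero(path.states == DARK)
        if len(dark):
            assert np.all(path.states[dark[0]:] == DARK)
            assert dark[0] == path.first_dark_frame

    def test_undersampled_rates_warn(self):
        tm = TransitionModel(k_unfold=500.0, k_fold=1.0, **NO_BLEACH)
        with pytest.warns(RuntimeWarning, match="undersampled"):
            simulate_state_path(tm, AcquisitionSettings(), rng_seed=0)

    def test_bleach_shortens_usable_trajectories(self):
        means = []
        for kb in (0.02, 0.1, 0.5):
            tm = TransitionModel(k_unfold=0.3, k_fold=2.4, k_bleach_donor=kb, k_bleach_acceptor=kb)
            firsts = [
                simulate_state_path(tm, AcquisitionSettings(), rng_seed=100 + i).first_dark_frame
                for i in range(300)
            ]
            means.append(np.mean(firsts))
        assert means[0] > means[1] > means[2]


class TestEmissions:
    def _noiseless(self, **kw):
        base = dict(background=0.0, read_noise_sd=0.0, dispersion=1e-9)
        base.update(kw)
        return EmissionModel(**base)

    def test_full_transfer_silences_donor(self):
        em = self._noiseless(e_folded=1.0)
        tm = TransitionModel(k_unfold=0.0, k_fold=0.0, **NO_BLEACH)
        path = simulate_state_path(tm, AcquisitionSettings(), rng_seed=0, start_state=FOLDED)
        traj = emit_intensities(path, em, AcquisitionSettings(), rng_seed=0)
        don = traj[traj["excitation"] == "donor_exc"]
        assert np.all(don["donor"] == 0.0)

    def test_noiseless_ratio_recovers_state_efficiency(self):
        em = self._noiseless()
        tm = TransitionModel(k_unfold=1.0, k_fold=1.0, **NO_BLEACH)
        path = simulate_state_path(tm, AcquisitionSettings(), rng_seed=1)
        traj = emit_intensities(path, em, AcquisitionSettings(), rng_seed=1)
        don = traj[traj["excitation"] == "donor_exc"]
        ratio = don["acceptor"] / (don["acceptor"] + don["donor"])
        expected = np.where(
            path.conformation[don["frame"].to_numpy()] == FOLDED, em.e_folded, em.e_unfolded
        )
        assert np.allclose(ratio, expected, atol=2e-3)

    def test_default_efficiencies_follow_forster_relation(self):
        # E = 1/(1+(R/R0)^6) at R = 2.4 and 9.8 nm with R0 = 4.59 nm
        em = EmissionModel()
        assert em.e_folded == pytest.approx(0.979966, abs=1e-5)
        assert em.e_unfolded == pytest.approx(0.010446, abs=1e-5)
        assert forster_efficiency(4.59) == pytest.approx(0.5)

    def test_donor_bleach_drops_both_channels_to_background(self):
        em = self._noiseless(background=5.0)
        from smfret.simulate import StatePath

        n = 20
        conf = np.zeros(n, dtype=np.int8)
        path = StatePath(conf.copy(), conf, donor_bleach_frame=10, acceptor_bleach_frame=n)
        traj = emit_intensities(path, em, AcquisitionSettings(), rng_seed=0)
        late = traj[(traj["frame"] >= 10) & (traj["excitation"] == "donor_exc")]
        assert np.allclose(late["donor"], 5.0, atol=1e-3)
        assert np.allclose(late["acceptor"], 5.0, atol=1e-3)


class TestDataset:
    def test_seed_determinism_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_dataset(20, rng_seed=9).to_tsv(a)
        generate_dataset(20, rng_seed=9).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_contaminant_counts_are_binomial(self):
        spec = ContaminantSpec(fraction_aggregates=0.05, fraction_donor_only=0.05)
        ts = generate_dataset(1000, contaminants=spec, rng_seed=10)
        flags = ts.sidecar.groupby("trajectory_id")["contaminant_flag"].first()
        se = 3 * np.sqrt(1000 * 0.05 * 0.95)
        assert abs((flags == "aggregate").sum() - 50) < se
        assert abs((flags == "donor_only").sum() - 50) < se

    def test_tsv_round_trip(self, tmp_path):
        ts = generate_dataset(5, rng_seed=11)
        p, sp = tmp_path / "t.tsv", tmp_path / "s.tsv"
        ts.to_tsv(p, sidecar_path=sp)
        back = TrajectorySet.read_tsv(p, sidecar_path=sp)
        assert back.n_trajectories == 5
        assert np.allclose(back.data["donor"], ts.data["donor"])
        assert back.acq.frame_interval == pytest.approx(0.2)
        assert list(back.sidecar.columns) == list(ts.sidecar.columns)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TransitionModel(k_unfold=-1.0)
        with pytest.raises(ValueError):
            EmissionModel(e_folded=1.5)
        with pytest.raises(ValueError):
            ContaminantSpec(0.6, 0.5)
        with pytest.raises(ValueError):
            AcquisitionSettings(frame_interval=0.0)
        with pytest.raises(ValueError):
            generate_dataset(0)
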