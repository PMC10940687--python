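"""HMM fitting, transition counting, rate conversion, and CRLB errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smfret.kinetics import (
    FOLDED,
    UNFOLDED,
    HmmSpec,
    KineticsModel,
    crlb_standard_errors,
    rate_estimate_from_counts,
    rates_from_probabilities,
    transition_probabilities,
)
from smfret.simulate import TransitionModel, generate_dataset


def label_emission_frames(paths):
    """Trajectories whose donor channel literally encodes the hidden state."""
    out = []
    for p in paths:
        p = np.asarray(p)
        out.append(
            pd.DataFrame(
                {
                    "trajectory_id": 0,
                    "frame": np.arange(len(p)),
                    "time_s": np.arange(len(p)) * 0.2,
                    "excitation": "donor_exc",
                    "donor": p * 100.0,
                    "acceptor": 0.0,
                }
            )
        )
    return out


def label_spec():
    means = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
    variances = np.full((3, 2), 1e-4)
    transmat = np.array([[0.8, 0.15, 0.05], [0.15, 0.8, 0.05], [0.0, 0.0, 1.0]])
    return HmmSpec(means, variances, transmat, np.array([0.5, 0.5, 0.0]))


class TestTransitionCounting:
    def test_direct_count_example(self):
        tc = transition_probabilities([np.array([0, 0, 0, 1])], dt=0.2)
        assert tc.probabilities[FOLDED, UNFOLDED] == pytest.approx(1 / 3)
        assert tc.probabilities[FOLDED, FOLDED] == pytest.approx(2 / 3)
        assert np.all(np.isnan(tc.probabilities[2]))  # dark never visited

    def test_no_refolding_means_zero_rate(self):
        tc = transition_probabilities([np.array([0, 0, 1, 1, 1])], dt=0.2)
        est = rate_estimate_from_counts(tc.counts, 0.2)
        assert est.k_fold == 0.0

    def test_long_chain_matches_exponential_embedding(self):
        from smfret.simulate import AcquisitionSettings, simulate_state_path

        tm = TransitionModel(k_unfold=0.8, k_fold=2.0, k_bleach_donor=0.0, k_bleach_acceptor=0.0)
        acq = AcquisitionSettings(max_duration=0.2 * 50_000)
        path = simulate_state_path(tm, acq, rng_seed=40)
        tc = transition_probabilities([path.conformation], dt=0.2)
        for s, k in ((FOLDED, 0.8), (UNFOLDED, 2.0)):
            p = 1 - np.exp(-k * 0.2)
            n = tc.counts[s].sum()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(tc.probabilities[s, 1 - s] - p) < 3 * se


class TestRateConversion:
    def test_zero_probability_zero_rate(self):
        assert rates_from_probabilities(0.0, 0.2) == 0.0

    def test_inverse_identity(self):
        assert rates_from_probabilities(1 - np.exp(-1), 1.0) == pytest.approx(1.0)

    def test_fast_rate_round_trip(self):
        # largest reported refolding rate: 6.54 1/s at 0.2 s frames
        p = 1 - np.exp(-6.54 * 0.2)
        assert p == pytest.approx(0.7297, abs=2e-4)
        assert rates_from_probabilities(p, 0.2) == pytest.approx(6.54)

    def test_saturated_probability_is_an_error(self):
        with pytest.raises(ValueError):
            rates_from_probabilities(1.0, 0.2)

    @given(st.floats(0.0, 0.999), st.floats(0.01, 1.0))
    def test_round_trip_through_embedding(self, p, dt):
        k = rates_from_probabilities(p, dt)
        assert 1 - np.exp(-k * dt) == pytest.approx(p, abs=1e-12)


class TestCrlb:
    def test_zero_probability_boundary(self):
        assert crlb_standard_errors(100, 0.0, 0.2) == 0.0

    def test_plug_in_arithmetic(self):
        assert crlb_standard_errors(100, 0.5, 1.0) == pytest.approx(0.1)

    def test_no_opportunities_gives_missing(self):
        assert np.isnan(crlb_standard_errors(0, 0.5, 1.0))


class TestEmFit:
    def test_loglik_is_monotone(self, kinetics_results):
        diffs = np.diff(kinetics_results.loglik_path)
        assert np.all(diffs >= -1e-9)
        assert kinetics_results.converged

    def test_fully_observed_chain_equals_count_oracle(self):
        rng = np.random.default_rng(41)
        paths = [rng.integers(0, 2, size=20) for _ in range(40)]
        trajs = label_emission_frames(paths)
        model = KineticsModel(trajs, dt=0.2, init=label_spec(), update_emissions=False)
        res = model.fit(max_iter=50, tol=1e-12)
        oracle = transition_probabilities(paths, dt=0.2)
        est = res.transition_counts
        assert np.allclose(est.probabilities[:2, :2], oracle.probabilities[:2, :2], atol=1e-9)
        assert np.allclose(est.counts[:2, :2], oracle.counts[:2, :2], atol=1e-6)

    def test_separable_emissions_decode_exactly(self):
        rng = np.random.default_rng(42)
        paths = [rng.integers(0, 2, size=30) for _ in range(10)]
        trajs = label_emission_frames(paths)
        model = KineticsModel(trajs, dt=0.2, init=label_spec(), update_emissions=False)
        res = model.fit(max_iter=30)
        for decoded, truth in zip(res.decoded_paths, paths):
            assert np.array_equal(decoded, truth)

    def test_estimates_invariant_to_trajectory_order(self, qc_result, kinetics_results):
        trajs = [df for _, df in qc_result.retained.iter_trajectories()]
        model = KineticsModel(
            trajs[::-1], dt=0.2, init=kinetics_results.model.init
        )
        res = model.fit()
        assert res.k_fold == pytest.approx(kinetics_results.k_fold, rel=1e-9)
        assert res.k_unfold == pytest.approx(kinetics_results.k_unfold, rel=1e-9)

    def test_viterbi_route_agrees_with_posterior_route(self, kinetics_results):
        # hard MAP paths systematically under-count brief excursions
        # relative to posterior-weighted expected counts (the reason the
        # posterior route is the default), so only loose agreement holds
        viterbi = kinetics_results.viterbi_rate_estimate()
        assert viterbi.k_fold == pytest.approx(kinetics_results.k_fold, rel=0.4)
        assert viterbi.k_unfold == pytest.approx(kinetics_results.k_unfold, rel=0.4)
        assert viterbi.n_fold_opportunities <= kinetics_results.rates.n_fold_opportunities

    def test_occupancy_agrees_with_stationary_fraction(self, kinetics_results):
        # both phi_F routes should describe the same bleach-truncated data
        assert kinetics_results.occupancy_folded_fraction() == pytest.approx(
            kinetics_results.stationary_folded_fraction(), abs=0.05
        )

    def test_hmmlearn_cross_check(self):
        """Independent EM implementation recovers the same transition matrix."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        from smfret.simulate import AcquisitionSettings

        # donor-excitation-only acquisition so both fitters see every frame
        acq = AcquisitionSettings(alternation_period=10**6, max_duration=30.0)
        tm = TransitionModel(k_unfold=0.5, k_fold=1.5, k_bleach_donor=0.0, k_bleach_acceptor=0.0)
        ts = generate_dataset(150, transitions=tm, acq=acq, rng_seed=43)

        mine = KineticsModel(ts).fit(tol=1e-9)
        p_mine = mine.transition_counts.probabilities

        X = ts.data[["donor", "acceptor"]].to_numpy(float)
        lengths = ts.data.groupby("trajectory_id").size().to_numpy()
        gh = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="diag", n_iter=300, tol=1e-6, init_params=""
        )
        gh.startprob_ = np.array([0.5, 0.5])
        gh.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        gh.means_ = mine.spec.means[:2] * np.array([[1.02], [0.98]])
        gh.covars_ = np.maximum(mine.spec.variances[:2], 1.0)
        gh.fit(X, lengths)

        # align state order by acceptor mean (folded = high acceptor)
        order = np.argsort(-gh.means_[:, 1])
        p_ref = gh.transmat_[np.ix_(order, order)]
        assert p_mine[FOLDED, UNFOLDED] == pytest.approx(p_ref[0, 1], rel=0.05, abs=5e-3)
        assert p_mine[UNFOLDED, FOLDED] == pytest.approx(p_ref[1, 0], rel=0.05, abs=5e-3)

    def test_summary_reports_rates(self, kinetics_results):
        text = kinetics_results.summary()
        assert "k_fold" in text and "k_unfold" in text
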