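"""Heatmap construction, threshold-line placement, and folded-fraction pooling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smfret.classify import (
    ThresholdClassificationModel,
    ThresholdLine,
    build_heatmap,
    classify,
    default_start_line,
    find_modes,
    fit_threshold,
    folded_fraction_from_labels,
)
from smfret.simulate import EmissionModel, TransitionModel, generate_dataset


def two_clusters(n=2000, c1=(30.0, 600.0), c2=(600.0, 30.0), sd=15.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(c1, sd, size=(n // 2, 2))
    b = rng.normal(c2, sd, size=(n - n // 2, 2))
    return np.clip(np.vstack([a, b]), 0, None)


class TestHeatmap:
    def test_counts_are_conserved(self):
        obs = two_clusters(100)
        hm = build_heatmap(obs)
        assert hm.counts.sum() == 100
        assert hm.n_observations == 100

    def test_two_noiseless_clusters_occupy_two_bins(self):
        obs = np.array([[10.0, 500.0]] * 60 + [[500.0, 10.0]] * 40)
        hm = build_heatmap(obs)
        assert (hm.counts > 0).sum() == 2
        assert hm.counts.max() == 60

    def test_mode_positions_match_emission_means(self):
        em = EmissionModel()
        tm = TransitionModel(k_unfold=1.5, k_fold=1.5, k_bleach_donor=0.0, k_bleach_acceptor=0.0)
        ts = generate_dataset(150, transitions=tm, emission=em, rng_seed=30)
        don = ts.donor_excitation()
        hm = build_heatmap(don)
        modes = find_modes(hm)
        bw = max(hm.bin_widths)
        folded_mean = np.array(
            [600 * (1 - em.e_folded) + em.background, 600 * em.e_folded + em.background]
        )
        unfolded_mean = np.array(
            [600 * (1 - em.e_unfolded) + em.background, 600 * em.e_unfolded + em.background]
        )
        assert np.all(np.abs(modes[0] - folded_mean) <= 1.5 * bw)
        assert np.all(np.abs(modes[1] - unfolded_mean) <= 1.5 * bw)

    def test_degenerate_data_is_an_error(self):
        with pytest.raises(ValueError):
            build_heatmap(np.full((50, 2), 7.0))

    def test_tsv_round_trip(self, tmp_path):
        hm = build_heatmap(two_clusters(500), n_bins=16)
        path = tmp_path / "heatmap.tsv"
        hm.to_tsv(path)
        from smfret.classify import FretHeatmap

        back = FretHeatmap.read_tsv(path)
        assert np.array_equal(back.counts, hm.counts)
        assert np.allclose(back.donor_edges, hm.donor_edges, rtol=1e-5)
        assert back.n_observations == 500


class TestThreshold:
    def test_separated_clusters_reach_zero_objective(self):
        hm = build_heatmap(two_clusters(4000, sd=10.0))
        line = fit_threshold(hm)
        assert line.objective == 0.0

    def test_symmetric_clusters_split_at_the_midpoint(self):
        obs = two_clusters(6000, c1=(100.0, 500.0), c2=(500.0, 100.0), sd=20.0, seed=1)
        hm = build_heatmap(obs)
        line = fit_threshold(hm)
        midpoint = np.array([300.0, 300.0])
        # signed distance of the midpoint from the line, in bin units
        dist = abs(line.signed_distance(*midpoint))
        assert dist <= 2 * max(hm.bin_widths)

    def test_failure_reported_when_no_separating_line(self):
        hm = build_heatmap(two_clusters(2000, sd=10.0))
        # a start so far off that the local search cannot separate the modes
        with pytest.raises((RuntimeError, ValueError)):
            modes = np.array([[30.0, 600.0], [32.0, 598.0]])  # bogus coincident modes
            fit_threshold(hm, start_line=(0.0, 1e9), modes=modes, max_iter=5)


class TestClassify:
    def _diagonal_line(self):
        # acceptor = donor, folded above
        return ThresholdLine(
            theta=np.arctan2(1.0, -1.0), offset=0.0, objective=0.0, folded_sign=1
        )

    def test_extreme_points(self):
        line = self._diagonal_line()
        assert classify(np.array([[0.0, 1000.0]]), line)[0]
        assert not classify(np.array([[1000.0, 0.0]]), line)[0]

    def test_on_line_ties_break_to_unfolded(self):
        # vertical line donor = 250 with folded on the low-donor side:
        # the signed distance of an on-line point is exactly zero
        line = ThresholdLine(theta=0.0, offset=250.0, objective=0.0, folded_sign=-1)
        assert not classify(np.array([[250.0, 123.0]]), line)[0]
        assert classify(np.array([[249.0, 123.0]]), line)[0]

    def test_noiseless_clusters_classified_exactly(self):
        em = EmissionModel(background=0.0, read_noise_sd=0.0, dispersion=1e-9)
        tm = TransitionModel(k_unfold=1.0, k_fold=1.0, k_bleach_donor=0.0, k_bleach_acceptor=0.0)
        ts = generate_dataset(50, transitions=tm, emission=em, rng_seed=31)
        don = ts.donor_excitation()
        truth = (
            ts.sidecar[ts.sidecar["excitation"] == "donor_exc"]["true_state"] == "folded"
        ).to_numpy()
        res = ThresholdClassificationModel(don).fit(rng_seed=0)
        assert np.array_equal(res.labels, truth)


class TestFoldedFraction:
    def test_all_folded_trials_give_unit_fraction(self):
        labels = [np.ones(500, dtype=bool)] * 5
        ff = folded_fraction_from_labels(labels)
        assert ff.phi_f == 1.0 and ff.sd_trials == 0.0

    def test_trial_spread_is_small_on_separated_data(self, classification):
        assert classification.sd_trials <= 0.01
        assert classification.folded_fraction.n_trials == 5

    def test_phi_invariant_to_bin_count(self, qc_result):
        phis = [
            ThresholdClassificationModel(qc_result.retained, n_bins=nb).fit(rng_seed=5).phi_f
            for nb in (32, 128)
        ]
        assert abs(phis[0] - phis[1]) <= 0.02

    def test_phi_invariant_to_trajectory_order(self, qc_result, classification):
        data = qc_result.retained.data
        shuffled = data.sort_values(["frame", "trajectory_id"], kind="stable")
        res = ThresholdClassificationModel(shuffled[shuffled["excitation"] == "donor_exc"]).fit(
            rng_seed=7
        )
        assert res.phi_f == pytest.approx(classification.phi_f, abs=1e-6)

    def test_phi_equals_weighted_mean_of_per_trajectory_fractions(self, qc_result, classification):
        don = qc_result.retained.donor_excitation().copy()
        don["folded"] = classify(don, classification.best_line)
        per_traj = don.groupby("trajectory_id")["folded"].agg(["mean", "size"])
        pooled = np.average(per_traj["mean"], weights=per_traj["size"])
        single_line_phi = don["folded"].mean()
        assert pooled == pytest.approx(single_line_phi, abs=1e-12)

    @given(st.integers(1, 499))
    def test_phi_counts_folded_share(self, n_folded):
        labels = np.zeros(500, dtype=bool)
        labels[:n_folded] = True
        ff = folded_fraction_from_labels([labels])
        assert ff.phi_f == pytest.approx(n_folded / 500)


def test_summary_mentions_key_quantities(classification):
    text = classification.summary()
    assert "phi_F" in text and "trials" in text
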