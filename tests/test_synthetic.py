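import dataclasses

import numpy as np
import pytest

from migconn import (
    CohortSpec,
    coupled_series,
    framewise_displacement,
    generate_4d_dataset,
    generate_clinical_table,
    generate_motion_traces,
    generate_node_timeseries_cohort,
    planted_precision,
    trim_and_scrub,
)
from migconn.preprocess import PreprocConfig


def sample_partial_corr(ts):
    """Brute-force partial correlation from the unregularized precision."""
    P = np.linalg.inv(np.cov(ts.T))
    d = np.sqrt(np.diag(P))
    R = -P / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return R


class TestSpecValidation:
    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            CohortSpec(n_em=1, n_cm=5)

    def test_rejects_bad_spike_rate(self):
        with pytest.raises(ValueError):
            CohortSpec(motion_spike_rate=1.5)

    def test_rejects_effect_node_out_of_range(self):
        with pytest.raises(ValueError):
            CohortSpec(n_nodes=4, effect_node=4)

    def test_non_positive_definite_precision_rejected(self):
        spec = CohortSpec(effect_node=2, effect_size=5.0)
        with pytest.raises(ValueError, match="positive definite"):
            planted_precision(spec, "CM")


class TestNodeTimeseries:
    def test_determinism_bit_identical(self):
        spec = CohortSpec(n_em=3, n_cm=3, n_volumes=50, seed=11)
        a = generate_node_timeseries_cohort(spec)
        b = generate_node_timeseries_cohort(spec)
        assert np.array_equal(a.node_timeseries, b.node_timeseries)
        assert np.array_equal(a.motion, b.motion)
        assert a.clinical.equals(b.clinical)

    def test_null_cohort_groups_match_in_distribution(self):
        # effect_size = 0: the two groups share the planted precision, so
        # group-mean partial correlations differ only by sampling noise.
        spec = CohortSpec(n_em=20, n_cm=20, n_volumes=2000, effect_node=2,
                          effect_size=0.0, seed=5)
        c = generate_node_timeseries_cohort(spec)
        mats = np.array([sample_partial_corr(ts) for ts in c.node_timeseries])
        diff = mats[:20].mean(0) - mats[20:].mean(0)
        assert np.abs(diff).max() < 0.05

    def test_partial_correlation_converges_to_planted(self):
        # mean absolute deviation from the planted values shrinks with T
        mads = []
        for T in (100, 1000, 10000):
            spec = CohortSpec(n_em=2, n_cm=2, n_volumes=T, seed=3)
            c = generate_node_timeseries_cohort(spec)
            P = c.truth["precision"]["EM"]
            d = np.sqrt(np.diag(P))
            planted = -P / np.outer(d, d)
            np.fill_diagonal(planted, 0.0)
            est = sample_partial_corr(c.node_timeseries[0])
            mads.append(np.abs(est - planted).mean())
        assert mads[0] > mads[1] > mads[2]
        assert mads[2] < 0.01

    def test_effect_scales_cm_precision_edges(self):
        spec = CohortSpec(effect_node=2, effect_size=0.5)
        em = planted_precision(spec, "EM")
        cm = planted_precision(spec, "CM")
        incident = np.abs(cm[2]) - 1.5 * np.abs(em[2])
        incident[2] = 0.0  # diagonal untouched
        assert np.allclose(incident, 0.0)
        mask = np.ones_like(em, bool)
        mask[2, :] = mask[:, 2] = False
        assert np.array_equal(em[mask], cm[mask])

    def test_ar_coloring_preserves_stationary_covariance(self):
        base = CohortSpec(n_em=2, n_cm=2, n_volumes=20000, seed=9)
        colored = dataclasses.replace(base, ar_coeff=0.4)
        cov0 = np.cov(generate_node_timeseries_cohort(base).node_timeseries[0].T)
        cov1 = np.cov(generate_node_timeseries_cohort(colored).node_timeseries[0].T)
        assert np.abs(cov0 - cov1).max() < 0.08


class TestMotion:
    def test_no_spikes_means_subthreshold_fd(self):
        spec = CohortSpec(n_em=3, n_cm=3, motion_spike_rate=0.0, seed=1)
        traces, spikes = generate_motion_traces(spec)
        for tr in traces:
            assert framewise_displacement(tr).max() < 0.5
        assert all(len(s) == 0 for s in spikes)

    def test_scrubbing_removes_exactly_planted_spikes(self):
        spec = CohortSpec(n_em=3, n_cm=3, n_volumes=100,
                          motion_spike_rate=0.08, seed=42)
        traces, spikes = generate_motion_traces(spec)
        cfg = PreprocConfig(discard_initial_s=0.0)
        for tr, planted in zip(traces, spikes):
            series = np.arange(spec.n_volumes)
            retained, _, _ = trim_and_scrub(series, tr, cfg, spec.tr_s)
            removed = sorted(set(range(spec.n_volumes)) - set(retained))
            assert removed == sorted(planted)

    def test_spike_count_matches_truth(self):
        spec = CohortSpec(n_em=3, n_cm=3, n_volumes=100,
                          motion_spike_rate=0.1, seed=8)
        traces, spikes = generate_motion_traces(spec)
        for tr, planted in zip(traces, spikes):
            fd = framewise_displacement(tr)
            assert (fd > 0.5).sum() == len(planted)


class TestClinical:
    def test_cm_headache_days_at_least_15(self):
        table = generate_clinical_table(CohortSpec(seed=2))
        cm = table[table.group == "CM"]
        assert (cm.headache_days >= 15).all()
        em = table[table.group == "EM"]
        assert (em.headache_days < 15).all()

    def test_reproducible_given_seed(self):
        spec = CohortSpec(seed=13)
        assert generate_clinical_table(spec).equals(generate_clinical_table(spec))

    def test_binary_cutoffs_consistent_with_scores(self):
        table = generate_clinical_table(CohortSpec(seed=4))
        assert ((table.phq9 >= 8) == table.depression.astype(bool)).all()
        assert ((table.hads_a >= 8) == table.anxiety.astype(bool)).all()


class TestVolumes:
    def test_noiseless_volumes_are_exact_map_mixtures(self):
        spec = CohortSpec(n_em=2, n_cm=2, n_nodes=3, n_volumes=20,
                          n_voxels_per_axis=9, noise_sd=0.0, seed=6)
        c = generate_4d_dataset(spec)
        maps = c.truth["maps"]
        flat = c.volumes[0].reshape(-1, spec.n_volumes).T
        assert np.allclose(flat, c.node_timeseries[0] @ maps)

    def test_maps_are_disjoint(self):
        spec = CohortSpec(n_em=2, n_cm=2, n_nodes=5, n_voxels_per_axis=12,
                          n_volumes=10, seed=6)
        maps = generate_4d_dataset(spec).truth["maps"]
        support = (maps > 0).astype(int)
        assert support.sum(axis=0).max() == 1

    def test_too_many_blobs_rejected(self):
        spec = CohortSpec(n_em=2, n_cm=2, n_nodes=64, n_voxels_per_axis=6,
                          n_volumes=10)
        with pytest.raises(ValueError, match="disjoint blobs"):
            generate_4d_dataset(spec)

    def test_zero_components_gives_pure_noise(self):
        spec = CohortSpec(n_em=2, n_cm=2, n_nodes=0, n_voxels_per_axis=8,
                          n_volumes=30, noise_sd=1.0, seed=3)
        c = generate_4d_dataset(spec)
        assert c.volumes.shape == (4, 8, 8, 8, 30)
        assert abs(c.volumes.mean()) < 0.05
        assert c.truth["maps"].shape == (0, 512)


def test_coupled_series_attains_planted_correlation(rng):
    x = rng.standard_normal(5000)
    y = coupled_series(x, 0.5, rng)
    assert abs(np.corrcoef(x, y)[0, 1] - 0.5) < 0.05
    with pytest.raises(ValueError):
        coupled_series(x, 1.0, rng)
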