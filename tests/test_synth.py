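"""Synthetic cohort generator: tract lengths, FA, signals, planted effects."""

import numpy as np
import pytest

from scfc.fc import THETA, aecc_pair
from scfc.sc import classify_edges, quartile_thresholds, sparsity, RangeThresholds
from scfc.stats import classify_cognitive_status
from scfc.coupling import within_subject_coupling
from scfc.synth import (
    CohortConfig,
    generate_cohort,
    generate_envelope_correlated_series,
    generate_structural_connectome,
    generate_tract_lengths,
    nearest_correlation_psd,
)


def cfg(**kw):
    base = dict(n_hc=4, n_cp=4, n_ci=3, n_nodes=12, n_epochs=2, epoch_samples=2048, seed=9)
    base.update(kw)
    return CohortConfig(**base)


class TestTractLengths:
    def test_range_and_symmetry(self):
        c = cfg(n_nodes=78, length_range=(10.0, 250.0))
        m = generate_tract_lengths(c, np.random.default_rng(0))
        iu = np.triu_indices(78, 1)
        assert np.all((m[iu] >= 10.0) & (m[iu] <= 250.0))
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_deterministic_under_seed(self):
        c = cfg()
        a = generate_tract_lengths(c, np.random.default_rng(5))
        b = generate_tract_lengths(c, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_pooled_quartiles_match_quantile_oracle(self):
        c = cfg(n_nodes=40)
        m = generate_tract_lengths(c, np.random.default_rng(1))
        iu = np.triu_indices(40, 1)
        vals = np.sort(m[iu])
        for p in (0.25, 0.75):
            h = (vals.size - 1) * p
            lo = int(h)
            oracle = vals[lo] + (h - lo) * (vals[min(lo + 1, vals.size - 1)] - vals[lo])
            assert np.quantile(m[iu], p) == pytest.approx(oracle, abs=1e-12)

    def test_right_skewed_distribution(self):
        c = cfg(n_nodes=78)
        m = generate_tract_lengths(c, np.random.default_rng(2))
        iu = np.triu_indices(78, 1)
        from scipy.stats import skew

        assert skew(m[iu]) > 0.2

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="length_range"):
            cfg(length_range=(250.0, 10.0))


class TestStructuralConnectome:
    def test_noise_free_fa_decreasing_in_length(self):
        c = cfg(fa_noise_sd=0.0, fa_group_deficit_long=0.0, absent_fraction=0.0)
        lengths = generate_tract_lengths(c, np.random.default_rng(3))
        fa = generate_structural_connectome(lengths, "HC", c, np.random.default_rng(4))
        iu = np.triu_indices(c.n_nodes, 1)
        order = np.argsort(lengths[iu])
        fa_sorted = fa[iu][order]
        unclipped = (fa_sorted > 0) & (fa_sorted < 1)
        diffs = np.diff(fa_sorted[unclipped])
        assert np.all(diffs <= 1e-12)

    def test_ci_long_range_deficit_recovered_at_scale(self):
        """Mean long-range FA gap CI vs HC approximates the planted 0.03."""
        c = cfg(n_nodes=30, fa_group_deficit_long=0.03, absent_fraction=0.0)
        rng = np.random.default_rng(11)
        lengths = generate_tract_lengths(c, rng)
        iu = np.triu_indices(30, 1)
        long_edges = lengths[iu] > np.quantile(lengths[iu], 0.75)
        gaps = []
        for _ in range(200):
            fa_hc = generate_structural_connectome(lengths, "HC", c, rng)
            fa_ci = generate_structural_connectome(lengths, "CI", c, rng)
            gaps.append(fa_hc[iu][long_edges].mean() - fa_ci[iu][long_edges].mean())
        assert np.mean(gaps) == pytest.approx(0.03, abs=0.005)

    def test_all_absent_gives_full_sparsity(self):
        from scfc.sc import StructuralConnectome

        c = cfg(absent_fraction=1.0)
        lengths = generate_tract_lengths(c, np.random.default_rng(0))
        fa = generate_structural_connectome(lengths, "HC", c, np.random.default_rng(1))
        sc = StructuralConnectome(fa=fa, lengths=lengths, node_labels=c.node_labels())
        assert sparsity(sc) == 1.0

    def test_fa_clipped_to_unit_interval(self):
        c = cfg(fa_noise_sd=0.5)
        lengths = generate_tract_lengths(c, np.random.default_rng(0))
        fa = generate_structural_connectome(lengths, "CI", c, np.random.default_rng(1))
        assert np.all((fa >= 0) & (fa <= 1))


class TestEnvelopeCorrelatedSeries:
    def test_identity_target_rescaled_aecc_near_half(self):
        c = cfg(n_nodes=3, n_epochs=4, epoch_samples=16384)
        ts = generate_envelope_correlated_series(
            np.eye(3), THETA, c, np.random.default_rng(5)
        )
        a = aecc_pair(ts.data[0], ts.data[1], THETA, c.sampling_rate)
        assert (a + 1) / 2 == pytest.approx(0.5, abs=0.08)

    def test_ordering_preserved_against_latent_oracle(self):
        c = cfg(n_nodes=3, n_epochs=4, epoch_samples=16384)
        target = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.3], [0.0, 0.3, 1.0]])
        target = nearest_correlation_psd(target)
        ts, env = generate_envelope_correlated_series(
            target, THETA, c, np.random.default_rng(6), return_envelopes=True
        )
        # latent-envelope oracle: sample correlations of the known envelopes
        lat_strong = np.corrcoef(env[0], env[1])[0, 1]
        lat_weak = np.corrcoef(env[1], env[2])[0, 1]
        assert lat_strong > lat_weak
        est_strong = aecc_pair(ts.data[0], ts.data[1], THETA, c.sampling_rate)
        est_weak = aecc_pair(ts.data[1], ts.data[2], THETA, c.sampling_rate)
        assert est_strong > est_weak

    def test_deterministic_under_seed(self):
        c = cfg(n_nodes=2)
        t1 = generate_envelope_correlated_series(np.eye(2), THETA, c, np.random.default_rng(3))
        t2 = generate_envelope_correlated_series(np.eye(2), THETA, c, np.random.default_rng(3))
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_non_psd_target_rejected_with_name(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="not positive semidefinite"):
            generate_envelope_correlated_series(
                bad, THETA, cfg(n_nodes=3), np.random.default_rng(0), label="bad_matrix"
            )


class TestGenerateCohort:
    def test_group_sizes_match_study_layout(self):
        c = CohortConfig(n_hc=40, n_cp=46, n_ci=33, n_nodes=10, seed=0)
        cohort = generate_cohort(c, mode="fc")
        labels = [r.subject.group for r in cohort.records]
        assert len(labels) == 119
        assert labels.count("HC") == 40
        assert labels.count("CP") == 46
        assert labels.count("CI") == 33

    def test_noise_free_linear_coupling_is_exact(self):
        c = cfg(
            noise_sd=0.0,
            fa_noise_sd=0.0,
            fc_subject_sd=0.0,
            fa_subject_sd=0.0,
            absent_fraction=0.0,
        )
        cohort = generate_cohort(c, mode="fc")
        rec = cohort.records[0]
        iu = np.triu_indices(c.n_nodes, 1)
        fa = rec.connectome.fa[iu]
        fc = rec.fc["theta"].values[iu]
        res = within_subject_coupling(fa, fc, rec.subject.id)
        assert abs(res.r) == pytest.approx(1.0, abs=1e-12)

    def test_ci_subjects_satisfy_impairment_rule(self, small_cohort):
        for rec in small_cohort.records:
            status = classify_cognitive_status(rec.subject.domain_z)
            if rec.subject.group == "CI":
                assert status == "CI"
            else:  # CP and HC must not satisfy the impairment rule
                assert status == "CP"

    def test_byte_identical_under_same_seed(self):
        c = cfg()
        a = generate_cohort(c, mode="both")
        b = generate_cohort(c, mode="both")
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.connectome.fa, rb.connectome.fa)
            np.testing.assert_array_equal(ra.connectome.lengths, rb.connectome.lengths)
            np.testing.assert_array_equal(ra.timeseries.data, rb.timeseries.data)
            np.testing.assert_array_equal(ra.subject.domain_z, rb.subject.domain_z)
            for band in ra.fc:
                np.testing.assert_array_equal(ra.fc[band].values, rb.fc[band].values)

    def test_matrix_invariants(self, small_cohort):
        for rec in small_cohort.records:
            fa, lengths = rec.connectome.fa, rec.connectome.lengths
            np.testing.assert_allclose(fa, fa.T)
            assert np.all((fa >= 0) & (fa <= 1))
            np.testing.assert_array_equal(np.diag(fa), 0.0)
            np.testing.assert_allclose(lengths, lengths.T)
            assert np.all(lengths[fa > 0] > 0)

    def test_zero_group_warns_not_errors(self):
        with pytest.warns(RuntimeWarning, match="n_ci is 0"):
            cohort = generate_cohort(cfg(n_ci=0), mode="fc")
        assert all(r.subject.group != "CI" for r in cohort.records)

    def test_shared_length_template_with_small_jitter(self):
        c = cfg(length_jitter_sd=2.0)
        cohort = generate_cohort(c, mode="fc")
        t = cohort.length_template
        iu = np.triu_indices(c.n_nodes, 1)
        for rec in cohort.records:
            dev = rec.connectome.lengths[iu] - t[iu]
            assert np.std(dev) < 3 * c.length_jitter_sd

    def test_planted_group_ordering_recovered(self):
        """CI > HC in mean long-range coupling in most replicates."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            c = CohortConfig(n_hc=8, n_cp=0, n_ci=8, n_nodes=40, seed=100 + rep)
            with pytest.warns(RuntimeWarning):
                cohort = generate_cohort(c, mode="fc")
            thr = quartile_thresholds([r.connectome for r in cohort.by_group("HC")])
            means = {}
            for grp in ("HC", "CI"):
                vals = []
                for rec in cohort.by_group(grp):
                    mask = classify_edges(rec.connectome, thr)
                    iu = np.triu_indices(c.n_nodes, 1)
                    fa = rec.connectome.fa[iu][mask.long_mask]
                    fc = rec.fc["theta"].values[iu][mask.long_mask]
                    vals.append(within_subject_coupling(fa, fc, rec.subject.id).r)
                means[grp] = np.mean(vals)
            wins += means["CI"] > means["HC"]
        assert wins >= 0.8 * n_rep
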