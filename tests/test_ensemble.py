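"""Ensemble construction, aggregation, fingerprints, interpretation."""

import warnings

import numpy as np
import pytest

import chronogauge as cg
from chronogauge.ensemble import (
    FingerprintThresholds,
    fingerprint_labels,
    group_feature_genes,
)


class TestBuild:
    def test_count_and_provenance(self, tiny_ensemble):
        assert len(tiny_ensemble.sub_predictors_) == 3
        assert [sp.seed for sp in tiny_ensemble.sub_predictors_] == [100, 101, 102]
        # distinct bootstraps give distinct feature sets
        sets = [tuple(fs.gene_ids) for fs in tiny_ensemble.feature_sets_]
        assert len(set(sets)) > 1

    def test_same_base_seed_reproduces_feature_sets(self, training_sim):
        m, truth = training_sim
        prior = cg.filter_circadian(truth)
        kwargs = dict(n_runs=2, sfs_budget=4, tuning_trials=1, base_seed=55,
                      sfs_epochs=20, final_epochs=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cg.ChronoGaugeEnsemble(**kwargs).fit(m, prior)
            b = cg.ChronoGaugeEnsemble(**kwargs).fit(m, prior)
        assert [fs.gene_ids for fs in a.feature_sets_] == [fs.gene_ids for fs in b.feature_sets_]

    def test_unique_gene_curve_monotone(self, tiny_ensemble):
        curve = tiny_ensemble.unique_gene_curve()
        assert np.all(np.diff(curve) >= 0)


class TestPredict:
    def test_single_sample_capability(self, tiny_ensemble, heldout_sim):
        test, _ = heldout_sim
        one = test.subset_samples([test.sample_ids[0]])
        ests = tiny_ensemble.predict_samples(one)
        assert len(ests) == 1
        assert 0 <= ests[0].mean_ct < 1440
        assert len(ests[0].per_sub_estimates) == 3

    def test_mean_is_circular_mean_of_subs(self, tiny_ensemble, heldout_sim):
        test, _ = heldout_sim
        est = tiny_ensemble.predict_samples(test)[0]
        assert est.mean_ct == pytest.approx(cg.circular_mean(est.per_sub_estimates))

    def test_mean_invariant_to_sub_order(self):
        ests = np.array([300.0, 420.0, 360.0])
        assert cg.circular_mean(ests) == pytest.approx(cg.circular_mean(ests[::-1]))

    def test_split_votes_average_to_midpoint(self):
        # 50 sub-predictors at 5 h and 50 at 7 h -> 6 h
        votes = np.array([300.0] * 50 + [420.0] * 50)
        assert cg.circular_mean(votes) == pytest.approx(360.0, abs=1e-6)

    def test_missing_rnaseq_feature_imputed(self, tiny_ensemble, heldout_sim):
        test, _ = heldout_sim
        used = tiny_ensemble.sub_predictors_[0].feature_ids[0]
        reduced = test.subset_genes([g for g in test.gene_ids if g != used])
        ests = tiny_ensemble.predict_samples(reduced)
        assert len(ests) == test.n_samples


class TestFingerprint:
    def test_threshold_60(self):
        labels = fingerprint_labels([75.0, -75.0, 30.0], FingerprintThresholds(60.0))
        assert labels == ["advanced", "delayed", "accurate"]

    def test_threshold_90_all_accurate(self):
        labels = fingerprint_labels([75.0, -75.0, 30.0], FingerprintThresholds(90.0))
        assert labels == ["accurate", "accurate", "accurate"]

    def test_boundary_counts_as_accurate(self):
        assert fingerprint_labels([60.0, -60.0, 0.0], FingerprintThresholds(60.0)) == \
            ["accurate"] * 3

    def test_attached_to_estimates_when_truth_known(self, tiny_ensemble, heldout_sim):
        test, _ = heldout_sim
        truth = test.times_min()
        ests = tiny_ensemble.predict_samples(test, truth_min=truth)
        assert all(e.fingerprint is not None for e in ests)
        for e in ests:
            np.testing.assert_allclose(
                e.per_sub_errors,
                cg.signed_circular_error(e.per_sub_estimates, truth[test.sample_ids.index(e.sample_id)]),
            )


class TestInterpretation:
    def test_feature_frequency_conservation(self, tiny_ensemble, training_sim):
        _, truth = training_sim
        freq = tiny_ensemble.feature_frequency(cg.filter_circadian(truth))
        total_slots = sum(len(set(fs.gene_ids)) for fs in tiny_ensemble.feature_sets_)
        assert freq["count"].sum() == total_slots
        assert (freq["count"].diff().dropna() <= 0).all()

    def test_group_genes_wt_filter(self, tiny_ensemble):
        fp = ["accurate", "advanced", "delayed"]
        wt = ["accurate", "accurate", "delayed"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = group_feature_genes(fp, tiny_ensemble, wt_fingerprint=wt)
        # sub 2 excluded by the WT filter
        sub2 = set(tiny_ensemble.sub_predictors_[2].feature_ids)
        only_sub2 = sub2 - set(tiny_ensemble.sub_predictors_[0].feature_ids) \
            - set(tiny_ensemble.sub_predictors_[1].feature_ids)
        assert not (set(groups["delayed"]) & only_sub2)

    def test_all_accurate_gives_empty_other_groups(self, tiny_ensemble):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = group_feature_genes(["accurate"] * 3, tiny_ensemble)
        assert groups["advanced"] == [] and groups["delayed"] == []

    def test_groups_may_overlap(self):
        # one gene sitting in two sub-predictors with different labels
        from types import SimpleNamespace

        stub = SimpleNamespace(sub_predictors_=[
            SimpleNamespace(feature_ids=["gA", "gB"]),
            SimpleNamespace(feature_ids=["gA", "gC"]),
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = group_feature_genes(["accurate", "advanced"], stub)
        assert "gA" in groups["accurate"] and "gA" in groups["advanced"]
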