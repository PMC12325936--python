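"""MolecularTimetable and the PLS sine/cosine ensemble baselines."""

import warnings

import numpy as np
import pytest

import chronogauge as cg
from chronogauge.baselines import (
    MolecularTimetable,
    PLSCyclicRegressor,
    WithinStudyNormalizationError,
    plsr_ensemble_fit,
)


@pytest.fixture(scope="module")
def noiseless_course():
    cfg = cg.SimConfig(n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0,
                       seed=3,
                       experiments=[cg.ExperimentDesign(12, 2.0, 0.0, "LL",
                                                        "sinusoid", 0.0)])
    return cg.simulate(cfg)


class TestMolecularTimetable:
    def test_noiseless_genes_kept_with_r_one(self, noiseless_course):
        train, truth = noiseless_course
        mtt = MolecularTimetable().fit(train)
        rhythmic = [g for g in mtt.genes_.index if g.startswith("RG")]
        assert len(rhythmic) == 150
        assert (mtt.genes_.loc[rhythmic, "cosine_fit_r"] > 0.999).all()
        err = np.abs(cg.signed_circular_error(
            mtt.genes_.loc[rhythmic, "peak_phase_h"] * 60.0,
            truth.table.loc[rhythmic, "phase_h"] * 60.0,
        )) / 60.0
        assert err.max() < 0.1

    def test_noise_genes_dropped(self, noiseless_course):
        train, _ = noiseless_course
        mtt = MolecularTimetable().fit(train)
        assert not any(g.startswith("NG") for g in mtt.genes_.index)

    def test_impossible_threshold_errors(self, noiseless_course):
        train, _ = noiseless_course
        with pytest.raises(ValueError, match="threshold"):
            MolecularTimetable(r_threshold=1.0 + 1e-9).fit(train)

    def test_two_sample_noiseless_recovery(self, noiseless_course):
        train, _ = noiseless_course
        mtt = MolecularTimetable().fit(train)
        cfg = cg.SimConfig(n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0,
                           seed=3, noise_seed=99,
                           experiments=[cg.ExperimentDesign(2, 12.0, 0.0, "LL",
                                                            "sinusoid", 0.0)])
        test, _ = cg.simulate(cfg)
        err = np.abs(cg.signed_circular_error(mtt.predict(test), test.times_min()))
        assert err.max() < 20.0

    def test_single_sample_infeasible(self, noiseless_course):
        train, _ = noiseless_course
        mtt = MolecularTimetable().fit(train)
        one = train.subset_samples([train.sample_ids[0]])
        with pytest.raises(WithinStudyNormalizationError):
            mtt.predict(one)

    def test_phase_shift_equivariance(self, noiseless_course):
        train, _ = noiseless_course
        mtt = MolecularTimetable().fit(train)
        cfg = cg.SimConfig(n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0,
                           seed=3, noise_seed=99,
                           experiments=[cg.ExperimentDesign(2, 12.0, 0.0, "LL",
                                                            "sinusoid", 0.0)])
        test, _ = cg.simulate(cfg)
        base = mtt.predict(test)
        shifted = MolecularTimetable()
        shifted.genes_ = mtt.genes_.copy()
        shifted.genes_["peak_phase_h"] = np.mod(shifted.genes_["peak_phase_h"] + 2.0, 24.0)
        moved = shifted.predict(test)
        delta = cg.signed_circular_error(moved, base)
        assert np.allclose(delta, 120.0, atol=1.0)

    def test_affine_rescaling_invariance(self, noiseless_course):
        train, _ = noiseless_course
        mtt = MolecularTimetable().fit(train)
        cfg = cg.SimConfig(n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0,
                           seed=3, noise_seed=99,
                           experiments=[cg.ExperimentDesign(3, 8.0, 0.0, "LL",
                                                            "sinusoid", 0.0)])
        test, _ = cg.simulate(cfg)
        base = mtt.predict(test)
        rng = np.random.default_rng(0)
        scaled = test.values.mul(rng.uniform(0.5, 3.0, len(test.gene_ids)), axis=0) \
            .add(rng.uniform(-2, 2, len(test.gene_ids)), axis=0)
        from chronogauge.io_scaling import ExpressionMatrix

        test2 = ExpressionMatrix(scaled, test.samples.copy())
        assert np.array_equal(mtt.predict(test2), base)


class TestPLSRegressor:
    def test_latent_factor_bounds(self):
        rng = np.random.default_rng(0)
        y = np.tile(np.arange(8) * 180.0, 2)
        X = np.column_stack([np.sin(2 * np.pi * y / 1440), np.cos(2 * np.pi * y / 1440),
                             rng.normal(0, 1, 16)])
        est = PLSCyclicRegressor(n_components="auto").fit(X, y)
        assert 1 <= est.n_components_ <= min(10, X.shape[1], len(y) - 1)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 1440, 30)
        X = np.column_stack([np.sin(2 * np.pi * y / 1440), np.cos(2 * np.pi * y / 1440),
                             rng.normal(0, 1, 30)])
        a = PLSCyclicRegressor(seed=4).fit(X, y).predict(X)
        b = PLSCyclicRegressor(seed=4).fit(X, y).predict(X)
        assert np.array_equal(a, b)


class TestPLSREnsemble:
    def test_noiseless_heldout_accuracy_and_determinism(self):
        m, truth = cg.make_training_like(seed=2, noise_sd=0.1)
        test, _ = cg.make_test_like(seed=2, noise_sd=0.1)
        prior = cg.filter_circadian(truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = plsr_ensemble_fit(m, prior, n_runs=3, seed=30, sfs_budget=30)
            e2 = plsr_ensemble_fit(m, prior, n_runs=3, seed=30, sfs_budget=30)
        assert [a.gene_ids for a in e1.feature_sets_] == \
            [b.gene_ids for b in e2.feature_sets_]
        pred = e1.predict(test)
        s = cg.summarize_errors(pred, test.times_min())
        assert s.mdae_min < 60.0
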