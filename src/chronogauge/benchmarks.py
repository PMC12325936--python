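"""Reference experiments on synthetic study-condition data.

These functions run the full pipeline at desk scale and return the
headline numbers (recovery rates, held-out errors, null calibrations).
They are used by the validation suite and the reproduction script; all
randomness is keyed from a single seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import synthetic
from .baselines import MolecularTimetable
from .ensemble import ChronoGaugeEnsemble
from .evaluation import summarize_errors
from .io_scaling import apply_scaler, fit_scaler
from .nn import Hyperparams
from .rhythmicity import RhythmicityTable, cosinor_prior, filter_circadian
from .sfs import run_sfs
from .timecodec import mean_absolute_circular_error, signed_circular_error


def planted_feature_fixture(seed: int = 5):
    """Six sinusoids (one phase per 4-h bin) among 300 background genes.

    The prior marks every gene significant (background genes get Q drawn
    below 0.05 with random phases), so the selector must separate signal
    from noise on predictive merit, not on the prior.
    """
    cfg = synthetic.SimConfig(
        n_rhythmic=6, n_noise=300, noise_sd=0.35, background_sd=1.0,
        amplitude_range=(1.5, 2.5), seed=seed,
        experiments=[
            synthetic.ExperimentDesign(14, 2.0, 0.0, "LL", "sinusoid", 0.5),
            synthetic.ExperimentDesign(14, 2.0, 1.0, "LL", "sinusoid", 0.5),
            synthetic.ExperimentDesign(14, 2.0, 0.5, "LL", "sinusoid", 0.5),
            synthetic.ExperimentDesign(14, 2.0, 1.5, "LL", "sinusoid", 0.5),
        ],
    )
    m, truth = synthetic.simulate(cfg)
    planted = [g for g in truth.gene_ids if g.startswith("RG")]
    rng = np.random.default_rng(seed)
    pri = truth.table.drop(columns=["phase_bin"]).copy()
    noise = [g for g in truth.gene_ids if g.startswith("NG")]
    pri.loc[noise, "q_value"] = rng.uniform(1e-4, 0.049, len(noise))
    pri.loc[noise, "phase_h"] = rng.uniform(0.0, 24.0, len(noise))
    prior = filter_circadian(RhythmicityTable(pri))
    return m, prior, planted


def planted_recovery(seed: int = 5, budget: int = 60) -> dict:
    """Fraction of the six planted genes recovered by one SFS run."""
    m, prior, planted = planted_feature_fixture(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = apply_scaler(m, fit_scaler(m))
        hp = Hyperparams(epochs=600, learning_rate=0.03, batch_size=999,
                         l2_factor=1e-3, seed=seed, n_restarts=3)
        fs = run_sfs(z, prior, budget=budget, seed=seed, hp=hp,
                     bootstrap_frac=1.0, top_n=5)
    recovered = len(set(fs.gene_ids) & set(planted))
    return {"recovered": recovered, "n_planted": len(planted),
            "feature_set": fs.gene_ids, "cv_mae": fs.cv_mae}


def ensemble_benchmark(seed: int = 1, n_runs: int = 10) -> dict:
    """Scaled-down ensemble on 4-experiment data (noise sd = 0.3 A).

    Trains ``n_runs`` sub-predictors, evaluates held-out samples that
    share the gene truth but not the noise draws, and contrasts with a
    label-permutation null.
    """
    m, truth = synthetic.make_training_like(seed=seed, noise_sd=0.3)
    test, _ = synthetic.make_test_like(seed=seed, noise_sd=0.3)
    prior = filter_circadian(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens = ChronoGaugeEnsemble(
            n_runs=n_runs, sfs_budget=60, tuning_trials=3, base_seed=seed + 9,
            sfs_epochs=100, final_epochs=300,
        ).fit(m, prior)
        pred = ens.predict(test)
    y = test.times_min()
    s = summarize_errors(pred, y)
    rng = np.random.default_rng(seed)
    null = float(np.mean([
        mean_absolute_circular_error(pred, rng.permutation(y)) for _ in range(50)
    ]))
    return {"heldout_mdae_min": s.mdae_min, "heldout_mae_min": s.mae_min,
            "null_mae_min": null, "n_test": s.n,
            "n_sub_predictors": len(ens.sub_predictors_), "ensemble": ens,
            "test": test}


def mtt_benchmark(seed: int = 3) -> dict:
    """Molecular timetable on a noiseless course + a 2-sample test study."""
    cfg = synthetic.SimConfig(
        n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0, seed=seed,
        experiments=[synthetic.ExperimentDesign(12, 2.0, 0.0, "LL", "sinusoid", 0.0)],
    )
    train, _ = synthetic.simulate(cfg)
    mtt = MolecularTimetable().fit(train)
    cfg2 = synthetic.SimConfig(
        n_rhythmic=150, n_noise=30, noise_sd=0.0, background_sd=1.0, seed=seed,
        noise_seed=seed + 99,
        experiments=[synthetic.ExperimentDesign(2, 12.0, 0.0, "LL", "sinusoid", 0.0)],
    )
    test, _ = synthetic.simulate(cfg2)
    err = np.abs(signed_circular_error(mtt.predict(test), test.times_min()))
    return {"max_abs_error_min": float(err.max()),
            "n_time_indicating_genes": len(mtt.genes_)}


def cosinor_null_fpr(seed: int = 7, n_genes: int = 2000) -> float:
    """Fraction of pure-noise genes flagged at Q < 0.05 by cosinor + BH."""
    cfg = synthetic.SimConfig(
        n_rhythmic=0, n_noise=n_genes, noise_sd=0.3, seed=seed,
        experiments=[synthetic.ExperimentDesign(12, 2.0, 0.0, "LL", "sinusoid", 0.0)],
    )
    m, _ = synthetic.simulate(cfg)
    prior = cosinor_prior(m)
    return float((prior.table["q_value"] < 0.05).mean())
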