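"""Bagging-like ensemble of circadian-time sub-predictors.

Each of ``n_runs`` runs draws its own gene bootstrap, performs the
phase-balanced sequential feature selection, tunes the network's
learning rate, batch size and L2 factor by random search scored with
fivefold-CV MAE, and finally trains one sub-predictor on all training
samples.  Test-time estimates from the sub-predictors are aggregated
with a circular mean; when the truth is known, the vector of per-sub
signed errors forms a "circadian fingerprint" partitioned into
accurate / advanced / delayed groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_scaling import (
    ExpressionMatrix,
    Scaler,
    apply_scaler,
    fit_scaler,
    independent_scale,
)
from .nn import CyclicMLPRegressor, Hyperparams, cv_mae, time_stratified_folds
from .rhythmicity import RhythmicityTable, filter_circadian
from .sfs import FeatureSet, run_sfs
from .timecodec import circular_mean, signed_circular_error

#: random-search sampling spaces for the tuner
SEARCH_SPACE = {
    "learning_rate": (1e-4, 1e-2),  # log-uniform
    "batch_size": (4, 8, 16, 28),
    "l2_factor": (1e-6, 1e-2),  # log-uniform
}


@dataclass
class SubPredictor:
    """A trained network bound to one feature set."""

    feature_ids: list
    model: object
    hyperparams: dict
    cv_mae: float
    seed: int

    def predict_minutes(self, scaled: ExpressionMatrix) -> np.ndarray:
        return self.model.predict(scaled.X(self.feature_ids))


@dataclass
class FingerprintThresholds:
    """Symmetric accurate/advanced/delayed boundary in minutes."""

    accurate_abs_max: float = 60.0

    def __post_init__(self):
        if self.accurate_abs_max <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class EnsembleEstimate:
    """Per-sample ensemble output."""

    sample_id: str
    per_sub_estimates: np.ndarray  # minutes, one per sub-predictor
    mean_ct: float  # circular mean, minutes
    per_sub_errors: np.ndarray | None = None
    fingerprint: list | None = None


def fingerprint_labels(errors_min, th: FingerprintThresholds) -> list:
    """Label per-sub signed errors as accurate / advanced / delayed.

    Strict inequalities: |e| < th is accurate, e > +th advanced,
    e < -th delayed; the boundary |e| = th counts as accurate.
    """
    labels = []
    for e in np.asarray(errors_min, dtype=float):
        if e > th.accurate_abs_max:
            labels.append("advanced")
        elif e < -th.accurate_abs_max:
            labels.append("delayed")
        else:
            labels.append("accurate")
    return labels


def _sample_hyperparams(rng, seed) -> Hyperparams:
    lo, hi = SEARCH_SPACE["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    bs = int(rng.choice(SEARCH_SPACE["batch_size"]))
    lo, hi = SEARCH_SPACE["l2_factor"]
    l2 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return Hyperparams(learning_rate=lr, batch_size=bs, l2_factor=l2, seed=seed)


class ChronoGaugeEnsemble(BaseEstimator):
    """Ensemble circadian-time estimator for bulk transcriptomes.

    Parameters
    ----------
    n_runs : int
        Number of SFS runs / sub-predictors (100 at study scale).
    sfs_budget : int
        CV-cost evaluations allowed per SFS run.
    tuning_trials : int
        Random-search trials per sub-predictor.
    base_seed : int
        Run ``i`` uses seed ``base_seed + i`` throughout.
    platform : str
        ``rnaseq`` (training-scaler policy, missing genes imputed as
        TPM 0) or a microarray tag (independent z-scaling at test time).
    """

    def __init__(self, n_runs=100, sfs_budget=60, tuning_trials=20, base_seed=0,
                 bootstrap_frac=0.5, top_n=25, sfs_epochs=100, final_epochs=300,
                 hidden_sizes=(32, 16, 8), platform="rnaseq", cv_k=5):
        self.n_runs = n_runs
        self.sfs_budget = sfs_budget
        self.tuning_trials = tuning_trials
        self.base_seed = base_seed
        self.bootstrap_frac = bootstrap_frac
        self.top_n = top_n
        self.sfs_epochs = sfs_epochs
        self.final_epochs = final_epochs
        self.hidden_sizes = hidden_sizes
        self.platform = platform
        self.cv_k = cv_k

    # hook so the PLSR ensemble can reuse the whole pipeline
    def _final_factory(self, hp: Hyperparams):
        def make():
            return CyclicMLPRegressor(
                hidden_sizes=self.hidden_sizes, learning_rate=hp.learning_rate,
                batch_size=hp.batch_size, l2_factor=hp.l2_factor,
                epochs=self.final_epochs, seed=hp.seed, n_restarts=2,
            )
        return make

    def _sfs_hyperparams(self, seed) -> Hyperparams:
        return Hyperparams(hidden_sizes=self.hidden_sizes, epochs=self.sfs_epochs,
                           seed=seed)

    def _sfs_factory(self, seed):
        """Estimator factory handed to the SFS; None means the default MLP."""
        return None

    def _tune(self, X, y, seed, folds) -> tuple[Hyperparams, float]:
        rng = np.random.default_rng(seed + 50_000)
        best_hp, best_score = None, np.inf
        for _ in range(max(1, self.tuning_trials)):
            hp = _sample_hyperparams(rng, seed)
            score = cv_mae(X, y, self._final_factory(hp), folds=folds)
            if score < best_score:
                best_hp, best_score = hp, score
        return best_hp, best_score

    def fit(self, m: ExpressionMatrix, prior: RhythmicityTable):
        """Build the ensemble from a training matrix and a rhythmicity prior."""
        prior = filter_circadian(prior)
        keep = [g for g in prior.gene_ids if g in m.values.index]
        prior = prior.subset(keep)
        self.scaler_: Scaler = fit_scaler(m, platform=self.platform)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = apply_scaler(m, self.scaler_)
        y = scaled.times_min()
        self.train_matrix_ = m
        self.sub_predictors_: list[SubPredictor] = []
        self.feature_sets_: list[FeatureSet] = []
        self.failed_runs_: list[int] = []
        for i in range(self.n_runs):
            seed = self.base_seed + i
            try:
                fs = run_sfs(
                    scaled, prior, budget=self.sfs_budget, seed=seed,
                    hp=self._sfs_hyperparams(seed),
                    estimator_factory=self._sfs_factory(seed),
                    bootstrap_frac=self.bootstrap_frac, top_n=self.top_n,
                    cv_k=self.cv_k,
                )
                X = scaled.X(fs.gene_ids)
                folds = time_stratified_folds(y, k=min(self.cv_k, len(np.unique(y))),
                                              seed=seed)
                hp, score = self._tune(X, y, seed, folds)
                model = self._final_factory(hp)().fit(X, y)
                self.feature_sets_.append(fs)
                self.sub_predictors_.append(
                    SubPredictor(
                        feature_ids=list(fs.gene_ids), model=model,
                        hyperparams={
                            "learning_rate": hp.learning_rate,
                            "batch_size": hp.batch_size,
                            "l2_factor": hp.l2_factor,
                        },
                        cv_mae=score, seed=seed,
                    )
                )
            except Exception as exc:  # failed runs are skipped, not retried
                warnings.warn(f"SFS run {i} (seed {seed}) failed: {exc}")
                self.failed_runs_.append(i)
        if not self.sub_predictors_:
            raise RuntimeError("all ensemble runs failed")
        return self

    # -- prediction --------------------------------------------------------

    def _scale_test(self, m: ExpressionMatrix) -> ExpressionMatrix:
        if self.platform == "rnaseq":
            return apply_scaler(m, self.scaler_, missing_policy="impute_zero")
        # microarray / cross-species: independent z-scaling; every
        # feature must exist (otherwise retrain on a reduced space)
        needed = sorted({g for sp in self.sub_predictors_ for g in sp.feature_ids})
        missing = [g for g in needed if g not in m.values.index]
        if missing:
            raise KeyError(
                f"platform {self.platform!r} matrix lacks features {missing[:5]}...; "
                "use retrain_with_features on the intersected space"
            )
        return independent_scale(m)

    def predict_samples(self, m: ExpressionMatrix, truth_min=None,
                        thresholds: FingerprintThresholds | None = None,
                        prescaled: bool = False) -> list[EnsembleEstimate]:
        """Per-sample ensemble estimates (optionally with fingerprints)."""
        scaled = m if prescaled else self._scale_test(m)
        per_sub = np.stack(
            [sp.predict_minutes(scaled) for sp in self.sub_predictors_], axis=0
        )  # (n_subs, n_samples)
        thresholds = thresholds or FingerprintThresholds()
        out = []
        for j, sid in enumerate(scaled.sample_ids):
            ests = per_sub[:, j]
            est = EnsembleEstimate(
                sample_id=sid, per_sub_estimates=ests,
                mean_ct=circular_mean(ests),
            )
            if truth_min is not None:
                err = signed_circular_error(ests, truth_min[j])
                est.per_sub_errors = err
                est.fingerprint = fingerprint_labels(err, thresholds)
            out.append(est)
        return out

    def predict(self, m: ExpressionMatrix, prescaled: bool = False) -> np.ndarray:
        """Circular-mean CT estimate per sample, minutes on [0, 1440)."""
        ests = self.predict_samples(m, prescaled=prescaled)
        return np.array([e.mean_ct for e in ests])

    # -- interpretation ----------------------------------------------------

    def feature_frequency(self, prior: RhythmicityTable) -> pd.DataFrame:
        """Selection count of each gene over runs, grouped by phase bin."""
        counts: dict = {}
        for fs in self.feature_sets_:
            for g in set(fs.gene_ids):
                counts[g] = counts.get(g, 0) + 1
        bin_of = prior.phase_bin_of()
        df = pd.DataFrame(
            {
                "gene_id": list(counts),
                "count": list(counts.values()),
                "phase_bin": [int(bin_of.get(g, -1)) for g in counts],
            }
        )
        return df.sort_values(["count", "gene_id"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)

    def unique_gene_curve(self) -> np.ndarray:
        """Cumulative unique-feature count over runs in rank order."""
        seen: set = set()
        curve = []
        for fs in self.feature_sets_:
            seen.update(fs.gene_ids)
            curve.append(len(seen))
        return np.array(curve)

    def retrain_with_features(self, feature_lists, min_features: int = 3) -> "ChronoGaugeEnsemble":
        """Clone with new per-sub feature lists, retrained on the training data.

        Used for per-platform reduction (probeset intersection) and
        cross-species remapping.  Lists shrinking below ``min_features``
        drop their sub-predictor with a warning.
        """
        import copy

        new = copy.copy(self)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = apply_scaler(self.train_matrix_, self.scaler_)
        y = scaled.times_min()
        subs, sets = [], []
        for sp, fs, feats in zip(self.sub_predictors_, self.feature_sets_, feature_lists):
            feats = [g for g in feats if g in scaled.values.index]
            if len(feats) < min_features:
                warnings.warn(f"sub-predictor seed {sp.seed}: feature set degenerate, dropped")
                continue
            hp = Hyperparams(seed=sp.seed, **sp.hyperparams)
            model = self._final_factory(hp)().fit(scaled.X(feats), y)
            subs.append(SubPredictor(list(feats), model, dict(sp.hyperparams),
                                     np.nan, sp.seed))
            nfs = FeatureSet(list(feats), np.nan, fs.bin_counts, fs.run_seed, [])
            sets.append(nfs)
        if not subs:
            raise RuntimeError("all feature sets degenerate after reduction")
        new.sub_predictors_ = subs
        new.feature_sets_ = sets
        return new


def group_feature_genes(fingerprint: list, e: ChronoGaugeEnsemble,
                        wt_fingerprint: list | None = None) -> dict:
    """Union of feature genes per fingerprint group for one sample.

    For mutants, ``wt_fingerprint`` restricts attention to sub-predictors
    that were accurate in the matched wild-type sample.  Groups may
    overlap (a gene can sit in several sub-predictors).
    """
    groups = {"accurate": set(), "advanced": set(), "delayed": set()}
    for j, label in enumerate(fingerprint):
        if wt_fingerprint is not None and wt_fingerprint[j] != "accurate":
            continue
        groups[label].update(e.sub_predictors_[j].feature_ids)
    empty = [k for k, v in groups.items() if not v]
    if empty:
        warnings.warn(f"empty fingerprint group(s): {empty}")
    return {k: sorted(v) for k, v in groups.items()}


def write_estimates(estimates: list[EnsembleEstimate], path, per_sub: bool = False) -> None:
    rows = []
    for est in estimates:
        row = {"sample_id": est.sample_id, "ct_hours": est.mean_ct / 60.0}
        if per_sub:
            for j, v in enumerate(est.per_sub_estimates):
                row[f"sub_{j:03d}_hours"] = v / 60.0
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
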