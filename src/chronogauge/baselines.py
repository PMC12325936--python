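"""Self-implemented comparison models.

* :class:`MolecularTimetable` — the classical molecular-timetable
  method: fit a 24-h cosine to each gene's within-study-normalised
  training expression, keep "time-indicating" genes whose cosine fit
  reaches a Pearson r threshold (default 0.89), and estimate a test
  sample's time as the grid argmin of the squared deviation between the
  sample's z-scores and the gene cosines.  Because the method z-scores
  the *test* study per gene, it needs at least two samples (ideally
  ~12 h apart) and cannot run on a single-timepoint study.

* :class:`PLSCyclicRegressor` / :func:`plsr_ensemble_fit` — a partial
  least squares regression on the sine/cosine time encoding, with the
  number of latent factors chosen on [1, 10] by fivefold-CV MAE, run
  through the same sequential-feature-selection ensemble machinery as
  the neural model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .ensemble import ChronoGaugeEnsemble
from .io_scaling import ExpressionMatrix, independent_scale
from .nn import cv_mae, time_stratified_folds
from .rhythmicity import RhythmicityTable
from .timecodec import decode_time, encode_time


class WithinStudyNormalizationError(ValueError):
    """Raised when a test study is too small to z-normalise per gene."""


class MolecularTimetable(BaseEstimator):
    """Cosine molecular-timetable estimator over time-indicating genes.

    Attributes
    ----------
    genes_ : pandas.DataFrame
        Retained genes with ``peak_phase_h``, ``amplitude``, ``mesor``
        and ``cosine_fit_r`` columns.
    """

    def __init__(self, r_threshold: float = 0.89, grid_step_min: float = 1.0):
        self.r_threshold = r_threshold
        self.grid_step_min = grid_step_min

    def fit(self, train: ExpressionMatrix):
        t_h = train.samples["time_h"].to_numpy(dtype=float)
        if len(np.unique(t_h)) < 3:
            raise ValueError("molecular-timetable fitting needs a multi-timepoint course")
        z = independent_scale(train)
        w = 2.0 * np.pi / 24.0
        X = np.column_stack([np.ones_like(t_h), np.cos(w * t_h), np.sin(w * t_h)])
        Y = z.values.to_numpy(dtype=float).T
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ coef
        obs_c = Y - Y.mean(axis=0)
        fit_c = fitted - fitted.mean(axis=0)
        denom = np.sqrt((obs_c**2).sum(axis=0) * (fit_c**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (obs_c * fit_c).sum(axis=0) / denom, 0.0)
        a, b = coef[1], coef[2]
        amplitude = np.hypot(a, b)
        phase_h = np.mod(np.arctan2(b, a) * 24.0 / (2.0 * np.pi), 24.0)
        table = pd.DataFrame(
            {
                "peak_phase_h": phase_h,
                "amplitude": amplitude,
                "mesor": coef[0],
                "cosine_fit_r": r,
            },
            index=pd.Index(train.gene_ids, name="gene_id"),
        )
        kept = table[table["cosine_fit_r"] >= self.r_threshold]
        if kept.empty:
            raise ValueError(
                f"no gene reaches cosine-fit r >= {self.r_threshold}; lower the threshold"
            )
        self.genes_ = kept
        return self

    def predict(self, test: ExpressionMatrix) -> np.ndarray:
        """Estimated time per test sample, minutes on [0, 1440)."""
        check_is_fitted(self, "genes_")
        if test.n_samples < 2:
            raise WithinStudyNormalizationError(
                "molecular timetable requires within-study normalization, which "
                "needs at least 2 samples (ideally ~12 h apart); got 1"
            )
        z = independent_scale(test.subset_genes(
            [g for g in self.genes_.index if g in test.values.index]
        ))
        if z.values.shape[0] == 0:
            raise KeyError("no time-indicating genes present in test matrix")
        phases = self.genes_.loc[z.gene_ids, "peak_phase_h"].to_numpy()
        grid_min = np.arange(0.0, 1440.0, self.grid_step_min)
        # cosine template per (gene, grid time)
        C = np.cos(2.0 * np.pi * (grid_min[None, :] / 60.0 - phases[:, None]) / 24.0)
        Z = z.values.to_numpy(dtype=float)  # genes x samples
        # argmin_t sum_g (z - C)^2 = argmin_t (-2 z.C + sum C^2)
        score = -2.0 * (Z.T @ C) + (C**2).sum(axis=0)[None, :]
        return grid_min[np.argmin(score, axis=1)]


class PLSCyclicRegressor(RegressorMixin, BaseEstimator):
    """PLS regression predicting the (s, c) time encoding.

    ``n_components="auto"`` picks the latent-factor count on [1, 10]
    (capped by features and samples) by fivefold-CV MAE.
    """

    def __init__(self, n_components="auto", max_components: int = 10, seed: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.seed = seed

    def _cap(self, n_samples, n_features) -> int:
        return max(1, min(self.max_components, n_features, n_samples - 1))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        Y = encode_time(y)
        cap = self._cap(*X.shape)
        if self.n_components == "auto":
            folds = time_stratified_folds(y, k=min(5, len(np.unique(np.mod(y, 1440.0)))),
                                          seed=self.seed)
            best_n, best_score = 1, np.inf
            for n in range(1, cap + 1):
                score = cv_mae(
                    X, y, lambda n=n: PLSCyclicRegressor(n_components=n), folds=folds
                )
                if score < best_score:
                    best_n, best_score = n, score
            n_comp = best_n
        else:
            n_comp = min(int(self.n_components), cap)
        self.n_components_ = n_comp
        self.pls_ = PLSRegression(n_components=n_comp, scale=False).fit(X, Y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pls_")
        out = np.asarray(self.pls_.predict(np.asarray(X, dtype=float)))
        norms = np.hypot(out[:, 0], out[:, 1])
        out[norms == 0.0] = (1.0, 0.0)
        return decode_time(out)


class PLSREnsemble(ChronoGaugeEnsemble):
    """The linear-baseline ensemble: same SFS machinery, PLS learner."""

    def _final_factory(self, hp):
        seed = hp.seed

        def make():
            return PLSCyclicRegressor(n_components="auto", seed=seed)

        return make

    def _sfs_factory(self, seed):
        def make():
            return PLSCyclicRegressor(n_components="auto", seed=seed)

        return make

    def _tune(self, X, y, seed, folds):
        # latent-factor choice happens inside the estimator; score once
        from .nn import Hyperparams

        hp = Hyperparams(seed=seed)
        score = cv_mae(X, y, self._final_factory(hp), folds=folds)
        return hp, score


def plsr_ensemble_fit(m: ExpressionMatrix, t: RhythmicityTable, n_runs: int = 100,
                      seed: int = 0, sfs_budget: int = 60, **kwargs) -> PLSREnsemble:
    """Fit the PLS sine/cosine ensemble baseline."""
    ens = PLSREnsemble(n_runs=n_runs, base_seed=seed, sfs_budget=sfs_budget,
                       tuning_trials=1, **kwargs)
    return ens.fit(m, t)


def mtt_fit(train: ExpressionMatrix, r_threshold: float = 0.89) -> MolecularTimetable:
    """Fit the molecular-timetable baseline (thin functional wrapper)."""
    return MolecularTimetable(r_threshold=r_threshold).fit(train)


def mtt_predict(model: MolecularTimetable, test: ExpressionMatrix) -> np.ndarray:
    return model.predict(test)
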