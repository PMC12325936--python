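"""Expression-matrix container, I/O and z-score scaling.

The expression matrix is genes x samples (TPM for RNA-seq, normalised
intensities for microarray) with a per-sample metadata table.  Scaling
is always per gene (row-wise):

* RNA-seq test data is scaled with the *training* statistics; features
  missing from a test set are imputed as TPM 0 first (lowly expressed).
* Microarray and cross-species data are scaled independently with their
  own statistics, which is what lets intensities and TPM share a scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timecodec import _as_minutes

REQUIRED_META_COLUMNS = ("sample_id", "time_h", "experiment_id", "light_regime", "platform")
PLATFORMS = ("rnaseq", "ath1", "aragene")


class ExpressionFormatError(ValueError):
    """Malformed expression matrix or metadata."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with aligned sample metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Index = gene ids, columns = sample ids.
    samples : pandas.DataFrame
        Index = sample ids; columns include ``time_h`` (hours, reduced
        mod 24), ``time_min``, ``experiment_id``, ``light_regime``
        (LL/LD), ``platform`` and optionally ``genotype``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        v, s = self.values, self.samples
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate gene ids: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate sample ids: {dup}")
        missing = [c for c in v.columns if c not in s.index]
        if missing:
            raise ExpressionFormatError(f"samples missing from metadata: {missing}")
        extra = [c for c in s.index if c not in v.columns]
        if extra:
            raise ExpressionFormatError(f"metadata for unknown samples: {extra}")
        if not np.all(np.isfinite(v.to_numpy(dtype=float))):
            raise ExpressionFormatError("expression values must be finite")
        s = s.loc[v.columns].copy()
        if "time_h" in s.columns:
            s["time_h"] = np.mod(pd.to_numeric(s["time_h"]), 24.0)
            s["time_min"] = s["time_h"] * 60.0
        self.samples = s

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def times_min(self) -> np.ndarray:
        """Sample times in minutes on [0, 1440)."""
        return _as_minutes(self.samples["time_min"].to_numpy(dtype=float))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.samples.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)].copy(), self.samples.loc[list(sample_ids)].copy()
        )

    def X(self, gene_ids=None) -> np.ndarray:
        """Samples x genes design matrix (sklearn orientation)."""
        v = self.values if gene_ids is None else self.values.loc[list(gene_ids)]
        return v.to_numpy(dtype=float).T


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """Load a TSV/CSV expression matrix and its sample metadata.

    The matrix has gene ids in the first column and sample ids as the
    header; metadata requires columns
    ``sample_id, time_h, experiment_id, light_regime, platform``.
    """
    mat = _read_table(matrix_path)
    mat = mat.set_index(mat.columns[0])
    meta = _read_table(metadata_path)
    missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ExpressionFormatError(f"metadata missing required columns: {missing_cols}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ExpressionFormatError("duplicate sample_id rows in metadata")
    return ExpressionMatrix(mat, meta)


def write_expression(m: ExpressionMatrix, matrix_path, metadata_path) -> None:
    m.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    meta = m.samples.drop(columns=["time_min"], errors="ignore")
    meta.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


@dataclass
class Scaler:
    """Per-gene mean/sd fitted on a reference (training) matrix."""

    mean: pd.Series
    sd: pd.Series
    platform: str = "rnaseq"
    constant_genes: list = field(default_factory=list)

    @property
    def gene_ids(self) -> list:
        return list(self.mean.index)


def fit_scaler(train: ExpressionMatrix, platform: str = "rnaseq") -> Scaler:
    """Per-gene mean and sample (n-1) standard deviation of the training set."""
    if train.n_samples < 2:
        raise ValueError("scaler requires at least 2 samples")
    mean = train.values.mean(axis=1)
    sd = train.values.std(axis=1, ddof=1)
    constant = sd.index[sd == 0.0].tolist()
    if constant:
        warnings.warn(f"{len(constant)} constant gene(s) have sd=0; they scale to 0")
    return Scaler(mean=mean, sd=sd, platform=platform, constant_genes=constant)


def apply_scaler(m: ExpressionMatrix, sc: Scaler, missing_policy: str = "impute_zero") -> ExpressionMatrix:
    """Scale ``m`` with training statistics, z = (x - mean)/sd per gene.

    ``missing_policy`` controls genes the scaler covers but ``m`` lacks:
    ``"impute_zero"`` (RNA-seq: fill with TPM 0 then scale) or
    ``"error"`` (microarray: absence means the feature space must be
    reduced and the ensemble retrained upstream).
    """
    absent = [g for g in sc.gene_ids if g not in m.values.index]
    vals = m.values.reindex(sc.gene_ids)
    if absent:
        if missing_policy == "impute_zero":
            vals.loc[absent] = 0.0
        else:
            raise KeyError(
                f"{len(absent)} scaler gene(s) absent from matrix (e.g. {absent[:5]}); "
                "reduce the feature space and retrain for this platform"
            )
    sd = sc.sd.replace(0.0, np.nan)
    z = vals.sub(sc.mean, axis=0).div(sd, axis=0).fillna(0.0)
    return ExpressionMatrix(z, m.samples.copy())


def independent_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene with the matrix's own statistics.

    Used for microarray and cross-species data, which are standardised
    independently of the training set.  Constant genes map to 0.
    """
    if m.n_samples < 2:
        raise ValueError("independent scaling requires at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = m.values.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
    return ExpressionMatrix(z, m.samples.copy())


def average_replicates(m: ExpressionMatrix, group_keys=("experiment_id", "time_h", "genotype")) -> ExpressionMatrix:
    """Arithmetic mean of expression over replicate groups.

    Groups are defined by ``group_keys`` (keys absent from the metadata
    are ignored).  Metadata columns that are constant within a group are
    kept; a conflict in a non-key, non-constant column raises.
    """
    keys = [k for k in group_keys if k in m.samples.columns]
    if not keys:
        raise ValueError("no grouping keys present in metadata")
    groups = m.samples.groupby(keys, sort=True, dropna=False).groups
    new_vals, new_meta = {}, []
    for gkey, idx in groups.items():
        idx = list(idx)
        sub = m.samples.loc[idx]
        for col in sub.columns:
            if col in ("time_min",):
                continue
            if sub[col].nunique(dropna=False) > 1 and col not in keys:
                raise ValueError(f"conflicting metadata in column {col!r} within group {gkey}")
        new_id = idx[0] if len(idx) == 1 else "avg_" + "_".join(str(k) for k in np.atleast_1d(gkey))
        new_vals[new_id] = m.values[idx].mean(axis=1)
        rec = sub.iloc[0].copy()
        rec.name = new_id
        new_meta.append(rec)
    values = pd.DataFrame(new_vals)
    meta = pd.DataFrame(new_meta)
    return ExpressionMatrix(values, meta)
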