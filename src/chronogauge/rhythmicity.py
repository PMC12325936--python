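"""Circadian rhythmicity priors: loading, filtering and phase binning.

The selector consumes a per-gene prior of rhythmicity significance
(Q-value) and peak phase, normally produced externally by
MetaCycle/meta2d on a continuous-light time course.  Genes with
Q < 0.05 are considered circadian and are partitioned into six 4-hour
phase bins [0,4), [4,8), ... [20,24).  A cosinor (harmonic regression)
fallback produces a compatible prior directly from a raw time course
when no meta2d output exists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_scaling import ExpressionMatrix

N_PHASE_BINS = 6
BIN_WIDTH_H = 4.0

#: MetaCycle meta2d CSV dialect -> internal column names
META2D_COLUMNS = {
    "gene_id": ("CycID", "gene_id", "geneid", "ID"),
    "q_value": ("meta2d_BH.Q", "meta2d_BH_Q", "q_value", "Q"),
    "phase_h": ("meta2d_phase", "phase_h", "phase"),
    "period_h": ("meta2d_period", "period_h", "period"),
}


def assign_phase_bins(phase_h) -> np.ndarray:
    """Bin peak phases into the six half-open 4-h intervals.

    Phases are reduced modulo 24 first, so 24.0 lands in bin 0 and the
    boundary 4.0 in bin 1 (half-open [4k, 4k+4) convention, which
    guarantees a partition).
    """
    ph = np.mod(np.asarray(phase_h, dtype=float), 24.0)
    return np.floor(ph / BIN_WIDTH_H).astype(int)


class RhythmicityTable:
    """Per-gene circadian prior: Q-value, phase (h), period (h), phase bin."""

    def __init__(self, table: pd.DataFrame):
        required = {"q_value", "phase_h", "period_h"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"prior table missing columns: {sorted(missing)}")
        t = table.copy()
        t["phase_h"] = np.mod(t["phase_h"].astype(float), 24.0)
        t["phase_bin"] = assign_phase_bins(t["phase_h"])
        if t.index.duplicated().any():
            raise ValueError("duplicate gene ids in prior table")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    def phase_bin_of(self) -> pd.Series:
        return self.table["phase_bin"]

    def bin_members(self, b: int) -> list:
        return list(self.table.index[self.table["phase_bin"] == b])

    def subset(self, gene_ids) -> "RhythmicityTable":
        return RhythmicityTable(self.table.loc[list(gene_ids)])


def load_prior(path, column_map=None) -> RhythmicityTable:
    """Read a MetaCycle-meta2d-style CSV prior.

    ``column_map`` may override the auto-detected column names, e.g.
    ``{"q_value": "myQ"}``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    resolved = {}
    for internal, candidates in META2D_COLUMNS.items():
        if column_map and internal in column_map:
            cand = (column_map[internal],)
        else:
            cand = candidates
        col = next((c for c in cand if c in df.columns), None)
        if col is None:
            raise ValueError(f"prior file lacks a column for {internal!r} (tried {cand})")
        resolved[internal] = col
    out = df[[resolved[k] for k in ("gene_id", "q_value", "phase_h", "period_h")]].copy()
    out.columns = ["gene_id", "q_value", "phase_h", "period_h"]
    return RhythmicityTable(out.set_index("gene_id"))


def filter_circadian(t: RhythmicityTable, q_max: float = 0.05) -> RhythmicityTable:
    """Retain genes with strictly Q < q_max (circadian-regulated set)."""
    keep = t.table["q_value"] < q_max
    if not keep.any():
        warnings.warn(f"no genes pass Q < {q_max}")
    return RhythmicityTable(t.table.loc[keep])


def cosinor_prior(m: ExpressionMatrix, period_h: float = 24.0) -> RhythmicityTable:
    """Harmonic-regression prior from a raw time course.

    Fits x(t) = M + a*cos(wt) + b*sin(wt) per gene by least squares,
    tests the joint harmonic terms with an F-test and converts the
    p-values to Q-values by Benjamini-Hochberg.  Phase is the peak time
    of the fitted cosine in hours.
    """
    t_h = m.samples["time_h"].to_numpy(dtype=float)
    if len(np.unique(t_h)) < 6:
        raise ValueError("cosinor prior requires at least 6 distinct timepoints")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t_h), np.cos(w * t_h), np.sin(w * t_h)])
    Y = m.values.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_num, df_den = 2, len(t_h) - 3
    if df_den <= 0:
        raise ValueError("not enough samples for the harmonic F-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    f = np.where(np.isfinite(f), f, np.inf)
    # constant genes: rss0 == rss1 == 0 -> define as non-rhythmic
    constant = rss0 <= 1e-300
    p = stats.f.sf(f, df_num, df_den)
    p = np.where(constant, 1.0, p)
    p = np.where(np.isfinite(p), p, 0.0)
    q = multipletests(p, method="fdr_bh")[1]
    a, b = coef[1], coef[2]
    amplitude = np.hypot(a, b)
    phase_h = np.mod(np.arctan2(b, a) / w, period_h)
    out = pd.DataFrame(
        {
            "q_value": q,
            "phase_h": phase_h,
            "period_h": period_h,
            "amplitude": amplitude,
            "mesor": coef[0],
            "p_value": p,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    return RhythmicityTable(out)
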