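"""Cross-species application through ortholog feature remapping.

Feature sets are defined on reference (*A. thaliana*) gene ids.  For a
focal species, orthologs are collapsed onto reference features: many
focal genes mapping to one reference feature are averaged on the TPM
scale; reference features with no ortholog are dropped from every
feature set and the sub-predictors are retrained on the original
training data restricted to the surviving features.  Focal expression
is z-scaled independently of the training set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import ChronoGaugeEnsemble
from .io_scaling import ExpressionMatrix


class OrthologMap:
    """Two-column mapping: focal-species gene -> reference feature."""

    def __init__(self, records: pd.DataFrame):
        if not {"focal_id", "reference_id"} <= set(records.columns):
            raise ValueError("ortholog map needs focal_id and reference_id columns")
        rec = records[["focal_id", "reference_id"]].astype(str)
        if (rec["focal_id"].str.len() == 0).any() or (rec["reference_id"].str.len() == 0).any():
            raise ValueError("empty ids in ortholog map")
        self.records = rec.drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["focal_id", "reference_id"],
                         dtype=str, comment="#")
        return cls(df)

    @classmethod
    def identity(cls, gene_ids) -> "OrthologMap":
        return cls(pd.DataFrame({"focal_id": list(gene_ids), "reference_id": list(gene_ids)}))

    def reference_features(self) -> list:
        return sorted(self.records["reference_id"].unique())


def collapse_orthologs(m_focal: ExpressionMatrix, omap: OrthologMap,
                       drop_unmapped: bool = True) -> ExpressionMatrix:
    """One row per reference feature = mean TPM of its focal orthologs.

    Focal genes absent from the map are dropped (default) or raise when
    ``drop_unmapped`` is False.  Reference features with no focal
    ortholog present are absent from the output.
    """
    mapped = omap.records[omap.records["focal_id"].isin(m_focal.values.index)]
    if mapped.empty:
        raise ValueError("no focal genes intersect the ortholog map")
    if not drop_unmapped:
        unmapped = set(m_focal.values.index) - set(omap.records["focal_id"])
        if unmapped:
            raise KeyError(f"unmapped focal genes: {sorted(unmapped)[:5]}...")
    rows = {}
    for ref, grp in mapped.groupby("reference_id", sort=True):
        rows[ref] = m_focal.values.loc[grp["focal_id"].tolist()].mean(axis=0)
    values = pd.DataFrame(rows).T
    values.index.name = "gene_id"
    return ExpressionMatrix(values, m_focal.samples.copy())


def remap_ensemble(e: ChronoGaugeEnsemble, omap: OrthologMap,
                   train: ExpressionMatrix | None = None) -> ChronoGaugeEnsemble:
    """Retrain the ensemble on the ortholog-mappable feature subspace.

    Each feature set is intersected with the reference features that
    have at least one focal ortholog; sub-predictors whose sets shrink
    below 3 genes are dropped with a warning.  Remapped sets are always
    subsets of the originals.
    """
    if train is not None:
        e.train_matrix_ = train
    mappable = set(omap.reference_features())
    new_lists = [
        [g for g in sp.feature_ids if g in mappable] for sp in e.sub_predictors_
    ]
    return e.retrain_with_features(new_lists)


def predict_cross_species(e: ChronoGaugeEnsemble, m_focal: ExpressionMatrix,
                          omap: OrthologMap) -> np.ndarray:
    """Collapse orthologs, z-scale independently, and predict (minutes)."""
    from .io_scaling import independent_scale

    collapsed = collapse_orthologs(m_focal, omap)
    remapped = remap_ensemble(e, OrthologMap.identity(collapsed.gene_ids))
    scaled = independent_scale(collapsed)
    return remapped.predict(scaled, prescaled=True)
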