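"""Marker selection, novelty annotation and classifier-based validation.

Top identity genes per cell type are taken directly from a (batch-averaged)
score table.  Novelty is assigned from an externally produced
gene -> publication-count table (any hit = known, zero hits = novel).
Validation uses a correlation-distance kNN classifier and random-forest
permutation importance on the marker subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.neighbors import KNeighborsClassifier

from ._exceptions import FormatError, UsageError
from .io import ExpressionMatrix

DET_FRAC_DEFAULT = 0.1


@dataclass
class MarkerSet:
    """Per-cell-type ordered marker lists with scores and novelty labels."""

    markers: dict[str, pd.DataFrame]  # per type: gene, score [, novelty]
    top_n: int
    novelty: dict[str, str] = field(default_factory=dict)

    def genes(self, cell_type: str | None = None) -> list[str]:
        if cell_type is not None:
            return self.markers[cell_type]["gene"].tolist()
        out: list[str] = []
        for df in self.markers.values():
            out.extend(df["gene"])
        return sorted(set(out))


def select_markers(reference_scores: pd.DataFrame,
                   top_n: int = 50) -> MarkerSet:
    """Top *top_n* genes per cell type by descending identity score.

    Ties are broken lexicographically by gene identifier, which makes the
    selection deterministic.
    """
    if top_n < 1:
        raise UsageError("top_n must be >= 1")
    if top_n > reference_scores.shape[0]:
        warnings.warn(f"top_n={top_n} exceeds {reference_scores.shape[0]} "
                      "genes; truncated")
        top_n = reference_scores.shape[0]
    out = {}
    for ct in reference_scores.columns:
        df = (reference_scores[ct]
              .rename("score").rename_axis("gene").reset_index()
              .sort_values(["score", "gene"], ascending=[False, True],
                           kind="mergesort")
              .head(top_n).reset_index(drop=True))
        out[ct] = df
    return MarkerSet(markers=out, top_n=top_n)


def annotate_novelty(ms: MarkerSet,
                     query_counts: Mapping[str, float]) -> MarkerSet:
    """Label markers known / novel / unannotated from publication counts."""
    counts = pd.Series(query_counts, dtype=float)
    if (counts.dropna() < 0).any():
        raise FormatError("negative publication counts")
    novelty = {}
    new_markers = {}
    for ct, df in ms.markers.items():
        labels = []
        for g in df["gene"]:
            if g not in counts.index or pd.isna(counts[g]):
                labels.append("unannotated")
            elif counts[g] > 0:
                labels.append("known")
            else:
                labels.append("novel")
        df = df.copy()
        df["novelty"] = labels
        new_markers[ct] = df
        novelty.update(dict(zip(df["gene"], labels)))
    return MarkerSet(markers=new_markers, top_n=ms.top_n, novelty=novelty)


@dataclass
class SpecificityTable:
    """Expressing-cell proportions per type and batch-level detection."""

    cell_proportion: pd.DataFrame  # gene x cell type, in [0, 1]
    batch_presence: pd.DataFrame  # gene x cell type, fraction of batches


def expression_specificity(m: ExpressionMatrix, ann: pd.DataFrame,
                           genes: Sequence[str],
                           det_frac: float = DET_FRAC_DEFAULT
                           ) -> SpecificityTable:
    """Fraction of expressing cells per type, plus batch-level detection.

    A gene counts as detected in a (dataset, batch, type) when it is
    expressed in more than *det_frac* of that type's cells; batch_presence
    is the fraction of batches (containing the type) where it is detected.
    """
    genes = list(genes)
    known = [g for g in genes if g in m.genes]
    missing = [g for g in genes if g not in m.genes]
    if missing:
        warnings.warn(f"{len(missing)} genes not in the matrix; reported "
                      "as null")
    ann = ann.set_index("cell_id").loc[m.cells.to_numpy()]
    sub = m.subset_genes(known)
    X = (sub.values > 0).astype(np.int8).tocsc()
    types = sorted(ann["cell_type"].unique())
    prop = pd.DataFrame(np.nan, index=genes, columns=types)
    batch_det: dict[str, pd.DataFrame] = {}
    labels = ann["cell_type"].to_numpy()
    batch_key = (ann["dataset"].astype(str) + "|" +
                 ann["batch"].astype(str)).to_numpy()
    for ct in types:
        mask = labels == ct
        prop.loc[known, ct] = np.asarray(
            X[:, mask].mean(axis=1)).ravel()
        dets = []
        for bk in np.unique(batch_key[mask]):
            bmask = mask & (batch_key == bk)
            dets.append(np.asarray(X[:, bmask].mean(axis=1)).ravel()
                        > det_frac)
        batch_det[ct] = pd.Series(np.mean(dets, axis=0), index=known)
    presence = pd.DataFrame(np.nan, index=genes, columns=types)
    for ct, s in batch_det.items():
        presence.loc[known, ct] = s
    return SpecificityTable(cell_proportion=prop, batch_presence=presence)


def knn_validate(train: tuple[ExpressionMatrix, Sequence[str]],
                 test: tuple[ExpressionMatrix, Sequence[str]],
                 genes: Sequence[str],
                 k: int = 5) -> pd.Series:
    """Correlation-distance kNN cell-type classification accuracy.

    Trains on the gene subset of one (log-normalized) dataset, predicts
    another, and reports per-cell-type accuracy plus ``overall``.
    """
    if k < 1 or k % 2 == 0:
        raise UsageError("k must be a positive odd integer")
    m_tr, y_tr = train
    m_te, y_te = test
    shared = [g for g in genes
              if g in m_tr.genes and g in m_te.genes]
    if not shared:
        raise UsageError("gene subset empty after intersecting universes")
    Xtr = np.asarray(m_tr.subset_genes(shared).values.todense()).T
    Xte = np.asarray(m_te.subset_genes(shared).values.todense()).T
    clf = KNeighborsClassifier(n_neighbors=k, metric="correlation",
                               algorithm="brute")
    clf.fit(Xtr, np.asarray(y_tr))
    pred = clf.predict(Xte)
    y_te = np.asarray(y_te)
    out = {}
    for ct in np.unique(y_te):
        mask = y_te == ct
        out[ct] = float((pred[mask] == ct).mean())
    out["overall"] = float((pred == y_te).mean())
    return pd.Series(out, name="accuracy")


def rf_importance(m: ExpressionMatrix, ann: pd.DataFrame,
                  genes: Sequence[str], n_trees: int = 500,
                  seed: int | None = 0,
                  n_repeats: int = 5) -> pd.Series:
    """Permutation importance of genes from a random-forest classifier.

    Importances are floored at zero; the result is deterministic for a
    fixed seed.
    """
    ann = ann.set_index("cell_id").loc[m.cells.to_numpy()]
    y = ann["cell_type"].to_numpy()
    if len(np.unique(y)) < 2:
        raise UsageError("single-class input: importance undefined")
    shared = [g for g in genes if g in m.genes]
    if not shared:
        raise UsageError("no requested genes in the matrix")
    X = np.asarray(m.subset_genes(shared).values.todense()).T
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=n_repeats,
                                 random_state=seed, n_jobs=1)
    vals = np.maximum(imp.importances_mean, 0.0)
    return pd.Series(vals, index=shared, name="importance")
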