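"""Six-metric benchmarking of organoid datasets against tissue references.

Each organoid unit — one (protocol, dataset, batch) group of cells — is
scored with the same differential-stability statistic as the references and
then measured on six axes:

1. ``ci_mature``   mean per-cell-type Pearson r of the unit's identity
                   scores against the mature reference;
2. ``ci_fetal``    the same against the fetal reference;
3. ``maturation``  signed correlation of the unit's similarity trajectory
                   across age-ordered reference profiles with age rank
                   (positive = adult-like, negative = fetal-like);
4. ``coverage``    fraction of the major retinal cell types present;
5. ``proportion``  1 - total-variation distance between the unit's and the
                   mature reference's cell-type composition;
6. ``offtarget``   fraction of cells a nearest-centroid-with-rejection
                   classifier calls intermediate or unassigned.

Metrics 1, 2, 4 and 5 are min-max scaled across units; maturation is kept
signed and off-target is a raw proportion.  The combined score averages the
six after orienting each so that higher = more faithful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._exceptions import UsageError
from .identity import (IdentityScoreMatrix, ReferenceAtlas, score_batches)
from .io import CANONICAL_TYPES, ExpressionMatrix, log_normalize
from .markers import select_markers
from .robustness import _pearson_cols

S_MIN_DEFAULT = 0.3
S_MARGIN_DEFAULT = 0.05
MIN_CELLS_PRESENT = 10
MIN_PROP_PRESENT = 0.005
METRICS = ("ci_mature", "ci_fetal", "maturation", "coverage",
           "proportion", "offtarget")


# ---------------------------------------------------------------------------
# Per-metric computations
# ---------------------------------------------------------------------------

def metric_cell_identity(org_scores: IdentityScoreMatrix,
                         ref: ReferenceAtlas
                         ) -> tuple[pd.Series, float]:
    """Per-cell-type Pearson r against the reference mean scores, and mean."""
    shared_t = [ct for ct in org_scores.cell_types
                if ct in ref.mean_scores.columns]
    if not shared_t:
        warnings.warn("no cell types shared with the reference")
        return pd.Series(dtype=float), float("nan")
    shared_g = org_scores.genes.intersection(ref.mean_scores.index)
    if len(shared_g) < 3:
        raise UsageError("fewer than 3 shared genes with the reference")
    a = org_scores.scores.loc[shared_g, shared_t].to_numpy(float)
    b = ref.mean_scores.loc[shared_g, shared_t].to_numpy(float)
    r = np.diag(_pearson_cols(a, b))
    per_type = pd.Series(r, index=shared_t, name="r")
    return per_type, float(np.nanmean(r))


def metric_maturation(org_scores: IdentityScoreMatrix,
                      ref_age_profiles: Mapping[str, Sequence[tuple[float,
                                                                    pd.Series]]]
                      ) -> tuple[pd.Series, float]:
    """Signed correlation of the similarity trajectory with age rank.

    For each cell type with >= 4 age-ordered reference profiles, the unit's
    score column is correlated with each profile; the metric is the Pearson
    correlation of those similarities with the profiles' age ranks.
    """
    out = {}
    for ct in org_scores.cell_types:
        profiles = ref_age_profiles.get(ct, [])
        if len(profiles) < 4:
            continue
        profiles = sorted(profiles, key=lambda t: t[0])
        sims = []
        for _, vec in profiles:
            shared = org_scores.genes.intersection(vec.index)
            a = org_scores.scores.loc[shared, ct].to_numpy(float)
            b = vec.loc[shared].to_numpy(float)
            sims.append(float(_pearson_cols(a[:, None], b[:, None])[0, 0]))
        ranks = np.arange(1, len(sims) + 1, dtype=float)
        sims = np.asarray(sims)
        if np.std(sims) == 0:
            out[ct] = 0.0
        else:
            out[ct] = float(np.corrcoef(sims, ranks)[0, 1])
    per_type = pd.Series(out, name="maturation")
    mean = float(per_type.mean()) if len(per_type) else float("nan")
    return per_type, mean


def metric_coverage(ann: pd.DataFrame,
                    expected: Sequence[str] = CANONICAL_TYPES,
                    min_cells: int = MIN_CELLS_PRESENT,
                    min_prop: float = MIN_PROP_PRESENT) -> float:
    """Fraction of expected cell types present in the data.

    A type counts as present when it has at least *min_cells* cells AND at
    least *min_prop* of all cells.
    """
    counts = ann["cell_type"].value_counts()
    n = len(ann)
    present = sum(1 for ct in expected
                  if counts.get(ct, 0) >= min_cells
                  and counts.get(ct, 0) / max(n, 1) >= min_prop)
    return present / len(expected)


def metric_proportion(ann: pd.DataFrame, ref: ReferenceAtlas,
                      expected: Sequence[str] | None = None,
                      method: str = "tv") -> float:
    """Similarity of cell-type composition to the reference.

    Default is 1 - total-variation distance over the expected type set
    (types missing on either side contribute probability 0); the
    alternative ``method="pearson"`` correlates the two proportion vectors.
    """
    if expected is None:
        expected = sorted(set(ref.proportions.index) | set(CANONICAL_TYPES))
    counts = ann.loc[ann["cell_type"].isin(expected),
                     "cell_type"].value_counts()
    if counts.sum() == 0:
        return 0.0
    p = counts.reindex(expected).fillna(0.0) / counts.sum()
    q = ref.proportions.reindex(expected).fillna(0.0)
    q = q / q.sum() if q.sum() > 0 else q
    if method == "tv":
        return float(1.0 - 0.5 * np.abs(p - q).sum())
    if method == "pearson":
        r = np.corrcoef(p, q)[0, 1]
        return float((r + 1) / 2)
    raise UsageError(f"unknown proportion method {method!r}")


# ---------------------------------------------------------------------------
# Nearest-centroid classification with rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionClassification:
    """Per-cell label (type, 'intermediate' or 'unassigned') + similarities."""

    labels: pd.Series
    similarities: pd.DataFrame
    s_min: float
    s_margin: float

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


class NearestCentroidRejector(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier with rejection of low/ambiguous cells.

    Similarity is the Pearson correlation of a cell's expression with each
    class centroid over the selected gene subset.  A cell is ``unassigned``
    when its best similarity falls below ``s_min`` and ``intermediate``
    when the margin to the runner-up is below ``s_margin``.
    """

    def __init__(self, s_min: float = S_MIN_DEFAULT,
                 s_margin: float = S_MARGIN_DEFAULT):
        self.s_min = s_min
        self.s_margin = s_margin

    def fit(self, X, y):
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise UsageError("need >= 2 reference classes")
        self.centroids_ = np.vstack(
            [X[y == ct].mean(axis=0) for ct in self.classes_])
        dead = self.centroids_.std(axis=1) == 0
        if dead.any():
            warnings.warn(
                f"zero-variance centroids excluded: "
                f"{self.classes_[dead].tolist()}")
        self.valid_ = ~dead
        return self

    def similarity(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        sims = _pearson_cols(X.T, self.centroids_.T)
        sims[:, ~self.valid_] = np.nan
        return sims

    def predict(self, X) -> np.ndarray:
        sims = self.similarity(X)
        out = np.empty(sims.shape[0], dtype=object)
        for i, row in enumerate(sims):
            ok = ~np.isnan(row)
            if not ok.any():
                out[i] = "unassigned"
                continue
            order = np.argsort(row[ok])[::-1]
            idx = np.flatnonzero(ok)[order]
            best = row[idx[0]]
            if best < self.s_min:
                out[i] = "unassigned"
            elif len(idx) > 1 and best - row[idx[1]] < self.s_margin:
                out[i] = "intermediate"
            else:
                out[i] = self.classes_[idx[0]]
        return out


def classify_with_rejection(m: ExpressionMatrix,
                            ref_train: tuple[ExpressionMatrix, Sequence[str]]
                            | pd.DataFrame,
                            genes: Sequence[str] | None = None,
                            s_min: float = S_MIN_DEFAULT,
                            s_margin: float = S_MARGIN_DEFAULT
                            ) -> RejectionClassification:
    """Assign cells to reference centroids, rejecting uncertain cells.

    *ref_train* is either ``(lognorm ExpressionMatrix, labels)`` or a
    precomputed gene x type centroid table.  *genes* defaults to all genes
    shared between query and reference.
    """
    if isinstance(ref_train, pd.DataFrame):
        centroids = ref_train
    else:
        ref_m, labels = ref_train
        labels = np.asarray(labels)
        X = np.asarray(ref_m.values.todense())
        cols = {ct: X[:, labels == ct].mean(axis=1)
                for ct in np.unique(labels)}
        centroids = pd.DataFrame(cols, index=ref_m.genes)
    if genes is None:
        genes = [g for g in centroids.index if g in m.genes]
    else:
        genes = [g for g in genes if g in m.genes and g in centroids.index]
    if len(genes) < 3:
        raise UsageError("fewer than 3 usable genes for classification")
    est = NearestCentroidRejector(s_min=s_min, s_margin=s_margin)
    # fit from centroids directly: synthesise one observation per class
    est.classes_ = np.asarray(centroids.columns)
    est.centroids_ = centroids.loc[genes].to_numpy(float).T
    dead = est.centroids_.std(axis=1) == 0
    if dead.any():
        warnings.warn(f"zero-variance centroids excluded: "
                      f"{est.classes_[dead].tolist()}")
    est.valid_ = ~dead
    Xq = np.asarray(m.subset_genes(genes).values.todense()).T
    labels_out = pd.Series(est.predict(Xq), index=m.cells, name="label")
    sims = pd.DataFrame(est.similarity(Xq), index=m.cells,
                        columns=est.classes_)
    return RejectionClassification(labels=labels_out, similarities=sims,
                                   s_min=s_min, s_margin=s_margin)


def metric_offtarget(c: RejectionClassification) -> float:
    """Fraction of cells classified intermediate or unassigned."""
    n = len(c.labels)
    if n == 0:
        raise UsageError("empty classification")
    bad = c.labels.isin(["intermediate", "unassigned"]).sum()
    return float(bad / n)


# ---------------------------------------------------------------------------
# Benchmark orchestration
# ---------------------------------------------------------------------------

@dataclass
class FidelityReport:
    """Raw and scaled six-metric values per unit, combined score and rank."""

    raw: pd.DataFrame  # units x metrics (+ protocol, dataset, batch)
    scaled: pd.DataFrame
    combined: pd.Series
    rank: pd.Series
    ci_breakdown: dict[str, pd.Series] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        metrics = self.raw.copy()
        for c in self.scaled.columns:
            metrics[f"{c}_scaled"] = self.scaled[c]
        metrics = metrics.reset_index(names="unit")
        ranking = pd.DataFrame({
            "unit": self.combined.index,
            "combined_score": self.combined.to_numpy(),
            "rank": self.rank.to_numpy(),
        }).sort_values("rank")
        return metrics, ranking

    def to_dict(self) -> dict:
        return {
            "raw": self.raw.to_dict(orient="index"),
            "scaled": self.scaled.to_dict(orient="index"),
            "combined": self.combined.to_dict(),
            "rank": {k: int(v) for k, v in self.rank.items()},
            "ci_breakdown": {u: s.to_dict()
                             for u, s in self.ci_breakdown.items()},
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FidelityReport":
        raw = pd.DataFrame.from_dict(d["raw"], orient="index")
        scaled = pd.DataFrame.from_dict(d["scaled"], orient="index")
        scaled = scaled.reindex(raw.index)
        return cls(
            raw=raw,
            scaled=scaled,
            combined=pd.Series(d["combined"]).reindex(raw.index),
            rank=pd.Series(d["rank"]).reindex(raw.index).astype(int),
            ci_breakdown={u: pd.Series(s)
                          for u, s in d.get("ci_breakdown", {}).items()},
            config=d.get("config", {}),
        )


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi - lo == 0:
        return pd.Series(1.0, index=col.index)
    return (col - lo) / (hi - lo)


def benchmark(units: Sequence[tuple[str, ExpressionMatrix, pd.DataFrame]],
              refs: Mapping[str, ReferenceAtlas],
              ref_train: tuple[ExpressionMatrix, Sequence[str]],
              marker_top_n: int = 50,
              min_cells: int = 20,
              s_min: float = S_MIN_DEFAULT,
              s_margin: float = S_MARGIN_DEFAULT) -> FidelityReport:
    """Score organoid units on the six fidelity metrics and rank them.

    *units* is a list of ``(protocol, counts-or-lognorm matrix,
    annotation)``; each (protocol, dataset, batch) group inside a unit is
    scored separately.  *refs* must contain ``mature`` and ``fetal``
    atlases (``fetal`` provides the age-ordered profiles).  *ref_train*
    supplies log-normalized tissue expression with labels for the
    off-target classifier; its centroids are computed on the union of the
    top *marker_top_n* mature-reference markers per type.
    """
    if not units:
        raise UsageError("no units to benchmark")
    if "mature" not in refs or "fetal" not in refs:
        raise UsageError("refs must contain 'mature' and 'fetal'")
    marker_genes = select_markers(refs["mature"].mean_scores,
                                  top_n=marker_top_n).genes()
    rows = {}
    breakdown = {}
    for protocol, m, ann in units:
        lognorm = m if m.layer == "lognorm" else log_normalize(m)
        ann = ann.set_index("cell_id").loc[
            lognorm.cells.to_numpy()].reset_index()
        for (ds, b), grp in ann.groupby(["dataset", "batch"], sort=True):
            unit_id = f"{protocol}|{ds}|{b}"
            sub = lognorm.subset_cells(grp["cell_id"])
            ism = score_batches(sub, grp, min_cells=min_cells,
                                normalize=False)[0]
            ci_m_types, ci_m = metric_cell_identity(ism, refs["mature"])
            _, ci_f = metric_cell_identity(ism, refs["fetal"])
            _, mat = metric_maturation(ism, refs["fetal"].age_profiles)
            cov = metric_coverage(grp)
            prop = metric_proportion(grp, refs["mature"])
            rc = classify_with_rejection(sub, ref_train, genes=marker_genes,
                                         s_min=s_min, s_margin=s_margin)
            off = metric_offtarget(rc)
            rows[unit_id] = {"protocol": protocol, "dataset": ds,
                             "batch": b, "ci_mature": ci_m,
                             "ci_fetal": ci_f, "maturation": mat,
                             "coverage": cov, "proportion": prop,
                             "offtarget": off}
            breakdown[unit_id] = ci_m_types
    raw = pd.DataFrame.from_dict(rows, orient="index")
    scale_cols = ["ci_mature", "ci_fetal", "coverage", "proportion"]
    if len(raw) >= 2:
        scaled = raw[scale_cols].apply(_minmax)
    else:
        warnings.warn("single unit: min-max scaling skipped")
        scaled = raw[scale_cols].copy()
    oriented = pd.concat([
        scaled["ci_mature"], scaled["ci_fetal"],
        (raw["maturation"].fillna(0.0) + 1) / 2,
        scaled["coverage"], scaled["proportion"],
        1.0 - raw["offtarget"],
    ], axis=1)
    combined = oriented.mean(axis=1)
    order = (pd.DataFrame({"c": combined, "ci": raw["ci_mature"]})
             .sort_values(["c", "ci"], ascending=False, kind="mergesort"))
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index,
                     name="rank").reindex(raw.index)
    return FidelityReport(raw=raw, scaled=scaled, combined=combined,
                          rank=rank, ci_breakdown=breakdown,
                          config={"marker_top_n": marker_top_n,
                                  "min_cells": min_cells,
                                  "s_min": s_min, "s_margin": s_margin})
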