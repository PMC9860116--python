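"""Differential-stability cell-identity scoring and reference construction.

The central statistic is a rank-based, Cepo-style differential-stability
score.  For one batch, two stability summaries are computed per gene within
each cell type: the fraction of cells with nonzero expression (``nz``) and
the coefficient of variation of the log-normalized values (``cv``; a stable
identity gene is consistently *on*, so high ``nz`` and low ``cv`` mark
identity).  Within each cell type the genes are rank-normalized on ``nz``
and on ``-cv`` (ascending fractional ranks, ties averaged, divided by the
gene count ``G`` so ranks lie in ``(0, 1]``), the two rank vectors are
averaged, and the score of gene ``g`` in type ``k`` is the mean difference
of this averaged rank against every other cell type::

    score(g, k) = (1 / (K - 1)) * sum_{k' != k} (m(g, k) - m(g, k'))

with ``m = (rank_nz + rank_negcv) / 2``.  By construction, for every gene
the scores sum to zero across cell types and lie strictly inside (-1, 1).

Scores are computed per (dataset, batch) and averaged across batches to
build mature / fetal reference atlases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from ._exceptions import UsageError
from .io import ExpressionMatrix, log_normalize

logger = logging.getLogger(__name__)

MIN_CELLS_DEFAULT = 20


# ---------------------------------------------------------------------------
# Stability statistics and identity scores
# ---------------------------------------------------------------------------

@dataclass
class StabilityStats:
    """Per-gene, per-cell-type stability summaries for one batch.

    ``nz``: fraction of cells of the type with nonzero expression, in [0,1].
    ``cv``: population coefficient of variation (sd/mean) of the
    log-normalized values, ``+inf`` when the mean is zero.
    """

    nz: pd.DataFrame
    cv: pd.DataFrame
    n_cells: pd.Series


@dataclass
class IdentityScoreMatrix:
    """Gene x cell-type differential-stability scores for one batch."""

    scores: pd.DataFrame
    dataset: str = ""
    batch: str = ""

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.columns

    @property
    def genes(self) -> pd.Index:
        return self.scores.index


def stability_stats(m: ExpressionMatrix, ann: pd.DataFrame,
                    min_cells: int = MIN_CELLS_DEFAULT) -> StabilityStats:
    """Compute nonzero fraction and CV per gene per cell type.

    *m* must be log-normalized and restricted to a single (dataset, batch);
    cell types with fewer than *min_cells* cells are dropped.
    """
    if m.layer != "lognorm":
        raise UsageError("stability_stats expects a log-normalized matrix")
    ann = ann.set_index("cell_id").loc[m.cells.to_numpy()]
    labels = ann["cell_type"].to_numpy()
    X = m.values.tocsc()
    nz_cols, cv_cols, counts = {}, {}, {}
    for ct in pd.unique(labels):
        mask = labels == ct
        n = int(mask.sum())
        if n < min_cells:
            continue
        sub = X[:, mask]
        s1 = np.asarray(sub.sum(axis=1)).ravel()
        s2 = np.asarray(sub.multiply(sub).sum(axis=1)).ravel()
        mean = s1 / n
        var = np.maximum(s2 / n - mean ** 2, 0.0)  # population variance
        # guard against catastrophic cancellation for (near-)constant
        # genes so that ties survive positive rescaling of the values
        var[var < mean ** 2 * 1e-12] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, np.sqrt(var) / mean, np.inf)
        nz_cols[ct] = sub.getnnz(axis=1) / n
        cv_cols[ct] = cv
        counts[ct] = n
    if len(nz_cols) < 2:
        raise UsageError(
            f"only {len(nz_cols)} cell types with >= {min_cells} cells; "
            "differential score undefined")
    nz = pd.DataFrame(nz_cols, index=m.genes)
    cv = pd.DataFrame(cv_cols, index=m.genes)
    return StabilityStats(nz=nz, cv=cv,
                          n_cells=pd.Series(counts, name="n_cells"))


def _signif(x: np.ndarray, digits: int = 10) -> np.ndarray:
    """Round to significant digits so mathematical ties rank as ties."""
    out = np.array(x, dtype=float, copy=True)
    finite = np.isfinite(out) & (out != 0)
    mag = 10.0 ** (digits - 1 -
                   np.floor(np.log10(np.abs(out[finite]))))
    out[finite] = np.round(out[finite] * mag) / mag
    return out


def _fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks per column, ties averaged, in (0, 1]."""
    values = _signif(values)
    g = values.shape[0]
    return np.column_stack(
        [rankdata(values[:, j], method="average") for j in
         range(values.shape[1])]) / g


def identity_scores(s: StabilityStats, dataset: str = "",
                    batch: str = "") -> IdentityScoreMatrix:
    """Turn stability statistics into differential-stability scores."""
    K = s.nz.shape[1]
    G = s.nz.shape[0]
    if K < 2:
        raise UsageError("need at least 2 cell types")
    if G < 2:
        raise UsageError("need at least 2 genes")
    r1 = _fractional_ranks(s.nz.to_numpy())
    r2 = _fractional_ranks(-s.cv.to_numpy())
    m = (r1 + r2) / 2.0
    # score(g,k) = (1/(K-1)) * sum_{k'!=k} (m_k - m_k') = K/(K-1)*(m_k - mean)
    scores = (K / (K - 1)) * (m - m.mean(axis=1, keepdims=True))
    df = pd.DataFrame(scores, index=s.nz.index, columns=s.nz.columns)
    return IdentityScoreMatrix(scores=df, dataset=dataset, batch=batch)


def score_batches(m: ExpressionMatrix, ann: pd.DataFrame,
                  min_cells: int = MIN_CELLS_DEFAULT,
                  normalize: bool = True) -> list[IdentityScoreMatrix]:
    """Score every (dataset, batch) in *m* separately.

    Counts are log-normalized first when *normalize* is true.
    """
    ann = ann.set_index("cell_id").loc[m.cells.to_numpy()].reset_index()
    out = []
    for (ds, b), grp in ann.groupby(["dataset", "batch"], sort=True):
        sub = m.subset_cells(grp["cell_id"])
        if normalize and sub.layer == "counts":
            sub = log_normalize(sub)
        stats = stability_stats(sub, grp, min_cells=min_cells)
        out.append(identity_scores(stats, dataset=str(ds), batch=str(b)))
    return out


class DifferentialStabilityScorer(BaseEstimator):
    """Sklearn-style transformer for the differential-stability score.

    ``fit(X, y)`` takes a cells x genes log-normalized matrix and per-cell
    labels; the fitted ``scores_`` attribute holds the genes x cell-type
    score table.  ``transform`` projects cells onto the score space
    (cells x cell types), useful inside sklearn pipelines.
    """

    def __init__(self, min_cells: int = MIN_CELLS_DEFAULT):
        self.min_cells = min_cells

    def fit(self, X, y):
        X = sp.csr_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise UsageError("X rows and y length differ")
        genes = getattr(self, "feature_names_in_", None)
        if genes is None:
            genes = pd.Index([f"g{i}" for i in range(X.shape[1])])
        cells = pd.Index([f"c{i}" for i in range(X.shape[0])])
        m = ExpressionMatrix(X.T.tocsr(), genes, cells, layer="lognorm")
        ann = pd.DataFrame({"cell_id": cells, "cell_type": y})
        self.stats_ = stability_stats(m, ann, min_cells=self.min_cells)
        ism = identity_scores(self.stats_)
        self.scores_ = ism.scores
        self.classes_ = ism.cell_types.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scores_")
        X = sp.csr_matrix(X)
        return np.asarray(X @ self.scores_.to_numpy())

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# Batch averaging and reference atlases
# ---------------------------------------------------------------------------

def average_scores(batch_scores: Sequence[IdentityScoreMatrix]) -> pd.DataFrame:
    """Unweighted per-(gene, type) mean of scores over batches.

    Genes are intersected across batches; a cell type absent from a batch
    does not contribute to that type's mean (divisor = number of batches
    containing the type).
    """
    if not batch_scores:
        raise UsageError("no batches to average")
    genes = batch_scores[0].genes
    for bs in batch_scores[1:]:
        genes = genes.intersection(bs.genes)
    if len(genes) == 0:
        raise UsageError("empty intersection of gene universes")
    genes = genes.sort_values()
    types = sorted({ct for bs in batch_scores for ct in bs.cell_types})
    total = pd.DataFrame(0.0, index=genes, columns=types)
    count = pd.Series(0, index=types, dtype=int)
    for bs in batch_scores:
        for ct in bs.cell_types:
            total[ct] += bs.scores.loc[genes, ct]
            count[ct] += 1
    return total / count


@dataclass
class ReferenceAtlas:
    """Batch-averaged scores, proportions and age-ordered profiles."""

    group: str
    mean_scores: pd.DataFrame
    proportions: pd.Series
    age_profiles: dict[str, list[tuple[float, pd.Series]]] = field(
        default_factory=dict)


REFERENCE_GROUPS = ("mature", "fetal", "fetal_early", "fetal_late")
AGE_SPLIT_DPC_DEFAULT = 100.0
_GROUP_SOURCE = {"mature": "tissue_mature", "fetal": "tissue_fetal",
                 "fetal_early": "tissue_fetal", "fetal_late": "tissue_fetal"}


def build_reference(batches: Iterable[tuple[ExpressionMatrix, pd.DataFrame]],
                    group: str,
                    age_split_dpc: float = AGE_SPLIT_DPC_DEFAULT,
                    min_cells: int = MIN_CELLS_DEFAULT) -> ReferenceAtlas:
    """Build a reference atlas from tissue batches.

    ``fetal_early`` keeps samples with batch mean age <= *age_split_dpc*
    days post-conception; ``fetal_late`` keeps the remainder.  Age profiles
    (per-type, age-ordered per-batch score vectors) are recorded for fetal
    groups.
    """
    if group not in REFERENCE_GROUPS:
        raise UsageError(f"unknown reference group {group!r}")
    want = _GROUP_SOURCE[group]
    scored: list[tuple[IdentityScoreMatrix, float | None, pd.Series]] = []
    for m, ann in batches:
        bad = set(ann["source"]) - {want}
        if bad:
            raise UsageError(
                f"group {group!r} given cells with source {sorted(bad)}")
        for ism in _score_with_meta(m, ann, min_cells):
            scored.append(ism)
    if group in ("fetal_early", "fetal_late"):
        keep = [(s, a, p) for s, a, p in scored
                if a is not None and
                ((a <= age_split_dpc) == (group == "fetal_early"))]
        if not keep:
            raise UsageError(f"no samples on the {group!r} side of "
                             f"age {age_split_dpc} dpc")
        scored = keep
    if not scored:
        raise UsageError("no batches supplied")
    mean_scores = average_scores([s for s, _, _ in scored])
    pooled = pd.concat([p for _, _, p in scored]).groupby(level=0).sum()
    proportions = pooled / pooled.sum()
    age_profiles: dict[str, list[tuple[float, pd.Series]]] = {}
    aged = [(s, a) for s, a, _ in scored if a is not None]
    aged.sort(key=lambda t: t[1])
    for ct in mean_scores.columns:
        prof = [(float(a), s.scores.loc[mean_scores.index, ct])
                for s, a in aged if ct in s.cell_types]
        if prof:
            age_profiles[ct] = prof
    return ReferenceAtlas(group=group, mean_scores=mean_scores,
                          proportions=proportions,
                          age_profiles=age_profiles)


def _score_with_meta(m, ann, min_cells):
    ann_idx = ann.set_index("cell_id").loc[m.cells.to_numpy()].reset_index()
    for (ds, b), grp in ann_idx.groupby(["dataset", "batch"], sort=True):
        sub = m.subset_cells(grp["cell_id"])
        if sub.layer == "counts":
            sub = log_normalize(sub)
        stats = stability_stats(sub, grp, min_cells=min_cells)
        ism = identity_scores(stats, dataset=str(ds), batch=str(b))
        age = None
        if "age_dpc" in grp.columns and grp["age_dpc"].notna().any():
            age = float(grp["age_dpc"].mean())
        props = grp["cell_type"].value_counts()
        yield ism, age, props


# ---------------------------------------------------------------------------
# Annotation confidence (semi-supervised re-classification ensemble)
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceVector:
    """Per-cell probability that the original label is correct."""

    probability: pd.Series
    band: pd.Series

    BAND_VERY_HIGH = 0.9
    BAND_HIGH = 0.7


def _bands(prob: pd.Series) -> pd.Series:
    band = pd.Series("low", index=prob.index, dtype=object)
    band[prob > ConfidenceVector.BAND_HIGH] = "high"
    band[prob > ConfidenceVector.BAND_VERY_HIGH] = "very_high"
    band[prob.isna()] = None
    return band


class AnnotationConfidenceEnsemble(BaseEstimator):
    """Ensemble re-classification estimate of annotation confidence.

    Repeatedly splits cells into a stratified train/held-out partition,
    trains a nearest-centroid classifier in PCA space on the training part
    and predicts the held-out part; a cell's confidence is the fraction of
    rounds, among those in which it was held out, that predicted its
    original label.  Cell types with fewer than 3 cells are excluded from
    training and their cells receive a null probability.
    """

    def __init__(self, n_rounds: int = 50, train_frac: float = 0.8,
                 n_pcs: int = 20, random_state: int | None = 0):
        self.n_rounds = n_rounds
        self.train_frac = train_frac
        self.n_pcs = n_pcs
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_rounds < 1:
            raise UsageError("n_rounds must be >= 1")
        if not 0 < self.train_frac < 1:
            raise UsageError("train_frac must be in (0, 1)")
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        y = np.asarray(y)
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        counts = pd.Series(y).value_counts()
        trainable = counts[counts >= 3].index
        excluded = ~pd.Series(y).isin(trainable).to_numpy()
        if len(trainable) < 2:
            raise UsageError("need >= 2 trainable cell types")
        n_pcs = min(self.n_pcs, n - 1, X.shape[1])
        Z = PCA(n_components=n_pcs, svd_solver="full").fit_transform(
            X - X.mean(axis=0))
        held = np.zeros(n)
        agree = np.zeros(n)
        classes = np.asarray(sorted(trainable))
        for _ in range(self.n_rounds):
            train_mask = np.zeros(n, bool)
            for ct in classes:
                idx = np.flatnonzero((y == ct) & ~excluded)
                k = max(1, int(round(self.train_frac * len(idx))))
                k = min(k, len(idx) - 1) if len(idx) > 1 else len(idx)
                train_mask[rng.choice(idx, size=k, replace=False)] = True
            test_mask = ~train_mask & ~excluded
            if not test_mask.any():
                continue
            cents = np.vstack([Z[train_mask & (y == ct)].mean(axis=0)
                               for ct in classes])
            d = ((Z[test_mask, None, :] - cents[None, :, :]) ** 2).sum(-1)
            pred = classes[np.argmin(d, axis=1)]
            held[test_mask] += 1
            agree[test_mask] += pred == y[test_mask]
        with np.errstate(invalid="ignore"):
            prob = np.where(held > 0, agree / np.maximum(held, 1), 1.0)
        never = (held == 0) & ~excluded
        if never.any():
            warnings.warn(f"{int(never.sum())} cells never held out; "
                          "assigned probability 1")
        prob = prob.astype(float)
        prob[excluded] = np.nan
        self.probability_ = prob
        self.classes_ = classes
        return self


def annotation_confidence(m: ExpressionMatrix, ann: pd.DataFrame,
                          n_rounds: int = 50, train_frac: float = 0.8,
                          seed: int | None = 0,
                          n_pcs: int = 20) -> ConfidenceVector:
    """Per-cell probability that the annotated label is correct."""
    if m.layer != "lognorm":
        raise UsageError("annotation_confidence expects lognorm values")
    ann = ann.set_index("cell_id").loc[m.cells.to_numpy()]
    est = AnnotationConfidenceEnsemble(n_rounds=n_rounds,
                                       train_frac=train_frac,
                                       n_pcs=n_pcs, random_state=seed)
    est.fit(m.values.T, ann["cell_type"].to_numpy())
    prob = pd.Series(est.probability_, index=m.cells, name="probability")
    return ConfidenceVector(probability=prob, band=_bands(prob))


def filter_by_confidence(ann: pd.DataFrame, conf: ConfidenceVector,
                         threshold: float = 0.9) -> pd.DataFrame:
    """Keep cells whose confidence strictly exceeds *threshold*."""
    if not 0 <= threshold <= 1:
        raise UsageError("threshold must be in [0, 1]")
    prob = ann["cell_id"].map(conf.probability)
    keep = prob.notna() & (prob > threshold)
    out = ann[keep.to_numpy()].copy()
    if out.empty:
        warnings.warn("no cells pass the confidence threshold")
    for ds, grp in ann.groupby("dataset"):
        frac = keep[grp.index].mean() if len(grp) else 0.0
        logger.info("dataset %s: retained %.1f%% of cells", ds, 100 * frac)
    return out
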