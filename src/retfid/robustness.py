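"""Reproducibility diagnostics for identity scores across batches.

Three assessments: (1) correlation structure of per-batch score profiles,
(2) stability of batch-averaged scores under random batch subsampling, and
(3) apportioning score-profile variance to experimental factors (a
principal-variance-component analysis, PVCA) plus clustering concordance
against known labelings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from ._exceptions import UsageError
from .identity import IdentityScoreMatrix, average_scores

DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


def _pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between each column of a and each column of b."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a.T @ b) / np.outer(sa, sb)
    r[:, sb == 0] = np.nan
    r[sa == 0, :] = np.nan
    return r


def score_similarity(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Cell-type-pair Pearson matrix between two score tables.

    Columns with zero variance yield null correlations with a warning.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise UsageError(f"only {len(shared)} shared genes; need >= 3")
    r = _pearson_cols(a.loc[shared].to_numpy(float),
                      b.loc[shared].to_numpy(float))
    if np.isnan(r).any():
        warnings.warn("constant score column: correlation undefined (null)")
    return pd.DataFrame(r, index=a.columns, columns=b.columns)


@dataclass
class StabilityCurve:
    """Mean per-cell-type correlation to full-data scores vs subsample size."""

    fractions: tuple[float, ...]
    mean_correlation: pd.DataFrame  # fractions x cell types
    n_reps: int
    seed: int | None


def subsample_stability(batch_scores: Sequence[IdentityScoreMatrix],
                        fractions: Sequence[float] = DEFAULT_FRACTIONS,
                        n_reps: int = 20,
                        seed: int | None = 0) -> StabilityCurve:
    """Correlation of subsampled-batch average scores against the full average.

    Per repetition, ``ceil(f * B)`` batches are drawn without replacement,
    their scores averaged, and each cell type's averaged score vector is
    correlated (Pearson) with the full-batch average.
    """
    B = len(batch_scores)
    if B < 2:
        raise UsageError("need >= 2 batches")
    rng = np.random.default_rng(seed)
    full = average_scores(list(batch_scores))
    rows = {}
    for f in fractions:
        k = ceil(f * B)
        if k < 1:
            warnings.warn(f"fraction {f} selects no batches; skipped")
            continue
        reps = np.zeros((n_reps, full.shape[1]))
        for r in range(n_reps):
            if k == B:  # the subsample is the full set
                reps[r] = 1.0
                continue
            idx = np.sort(rng.choice(B, size=k, replace=False))
            sub = average_scores([batch_scores[i] for i in idx])
            sub = sub.reindex(index=full.index, columns=full.columns)
            reps[r] = np.diag(_pearson_cols(sub.to_numpy(),
                                            full.to_numpy()))
        rows[f] = reps.mean(axis=0)
    curve = pd.DataFrame(rows, index=full.columns).T
    curve.index.name = "fraction"
    return StabilityCurve(fractions=tuple(rows), mean_correlation=curve,
                          n_reps=n_reps, seed=seed)


@dataclass
class PvcaResult:
    """Weighted variance proportions per factor plus residual (sum to 1)."""

    proportions: pd.Series
    n_pcs: int


def _oneway_varcomp(y: np.ndarray, groups: np.ndarray) -> float | None:
    """One-way random-effects variance component, method of moments.

    Returns None when the factor is confounded 1:1 with samples (no
    within-group degrees of freedom).
    """
    levels, inv = np.unique(groups, return_inverse=True)
    a, N = len(levels), len(y)
    if a < 2 or N - a < 1:
        return None
    n_i = np.bincount(inv).astype(float)
    means = np.bincount(inv, weights=y) / n_i
    grand = y.mean()
    msb = float((n_i * (means - grand) ** 2).sum() / (a - 1))
    msw = float(((y - means[inv]) ** 2).sum() / (N - a))
    n0 = (N - (n_i ** 2).sum() / N) / (a - 1)
    return max(0.0, (msb - msw) / n0)


def pvca(profiles: pd.DataFrame, factors: pd.DataFrame,
         n_pcs: int | None = None,
         var_threshold: float = 0.6) -> PvcaResult:
    """Proportion of score-profile variance attributable to each factor.

    PCA on the centered sample x gene profiles; per retained PC, a one-way
    random-effects variance component is estimated for each factor
    (method of moments), the residual absorbs the remainder, proportions
    are normalized per PC and finally averaged with eigenvalue-share
    weights.
    """
    X = profiles.to_numpy(float)
    X = X - X.mean(axis=0)
    # economy SVD; PC scores = U * S
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    ev = S ** 2
    if ev.sum() == 0:
        raise UsageError("profiles have zero variance")
    share = ev / ev.sum()
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(share), var_threshold) + 1)
    n_pcs = max(1, min(n_pcs, len(ev)))
    scores = U[:, :n_pcs] * S[:n_pcs]
    names = list(factors.columns)
    props = pd.DataFrame(0.0, index=range(n_pcs), columns=names + ["residual"])
    for j in range(n_pcs):
        y = scores[:, j]
        s2_total = float(np.var(y, ddof=1))
        comps = {}
        for f in names:
            vc = _oneway_varcomp(y, factors[f].to_numpy())
            if vc is None:
                warnings.warn(f"factor {f!r} confounded with samples; "
                              "absorbed by residual")
                vc = 0.0
            comps[f] = vc
        resid = max(0.0, s2_total - sum(comps.values()))
        comps["residual"] = resid if (resid or any(comps.values())) else 1.0
        tot = sum(comps.values())
        for k, v in comps.items():
            props.loc[j, k] = v / tot
    w = share[:n_pcs] / share[:n_pcs].sum()
    overall = props.mul(w, axis=0).sum()
    overall /= overall.sum()
    return PvcaResult(proportions=overall, n_pcs=n_pcs)


def clustering_concordance(profiles: pd.DataFrame,
                           label_sets: Mapping[str, Sequence],
                           n_genes: int = 500,
                           method: str = "average") -> pd.Series:
    """Adjusted Rand index of a hierarchical clustering vs each labeling.

    Samples are clustered on the top *n_genes* by variance with
    average-linkage on 1 - Pearson distance; for each label set, the tree
    is cut at k = number of label levels and the ARI reported.
    """
    if len(label_sets) < 1:
        raise UsageError("need at least one label set")
    var = profiles.var(axis=0)
    top = var.sort_values(ascending=False).index[:n_genes]
    X = profiles[top].to_numpy(float)
    corr = np.corrcoef(X)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method=method)
    out = {}
    for name, labels in label_sets.items():
        labels = np.asarray(labels)
        k = len(np.unique(labels))
        if k < 2:
            out[name] = np.nan
            continue
        pred = fcluster(Z, t=k, criterion="maxclust")
        out[name] = adjusted_rand_score(labels, pred)
    return pd.Series(out, name="ARI")
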