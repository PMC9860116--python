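"""Maturation-associated gene discovery.

Per cell type, the identity score of each gene across age-annotated samples
is correlated with developmental age (days post-conception, min-max scaled
to [0, 1]).  P values come from the exact t-distribution of the sample
correlation under the null, are Benjamini-Hochberg adjusted within each
cell type, and genes are binned into significance categories:
highly_significant (FDR < 0.01), significant (0.01 <= FDR <= 0.05),
insignificant (FDR > 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import UsageError
from .identity import IdentityScoreMatrix

CATEGORIES = ("highly_significant", "significant", "insignificant")


@dataclass
class MaturationTable:
    """Long table: per (gene, cell_type) correlation with age and FDR."""

    table: pd.DataFrame  # columns: gene, cell_type, r, p_value, fdr,
    #                               category, direction
    method: str = "pearson"

    def r_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="cell_type", values="r")


def _categorize(fdr: np.ndarray) -> np.ndarray:
    cat = np.full(len(fdr), "insignificant", dtype=object)
    cat[fdr <= 0.05] = "significant"
    cat[fdr < 0.01] = "highly_significant"
    cat[np.isnan(fdr)] = None
    return cat


def age_association(
        sample_scores: Sequence[tuple[IdentityScoreMatrix, float]],
        method: str = "pearson",
        global_fdr: bool = False) -> MaturationTable:
    """Correlate per-sample identity scores with scaled developmental age.

    *sample_scores* pairs each per-batch score matrix with the sample's age
    in days post-conception.  Cell types present in fewer than 4 samples
    with distinct ages are skipped with a warning.  Genes with constant
    scores across samples get a null correlation and are excluded from the
    BH adjustment.
    """
    if method not in ("pearson", "spearman"):
        raise UsageError(f"unknown method {method!r}")
    ages = np.asarray([a for _, a in sample_scores], float)
    if len(ages) and np.ptp(ages) > 0:
        scaled = (ages - ages.min()) / np.ptp(ages)
    else:
        scaled = np.zeros_like(ages)
    types = sorted({ct for s, _ in sample_scores for ct in s.cell_types})
    rows = []
    for ct in types:
        idx = [i for i, (s, _) in enumerate(sample_scores)
               if ct in s.cell_types]
        if len(idx) < 4 or len(np.unique(ages[idx])) < 4:
            warnings.warn(f"cell type {ct!r}: fewer than 4 samples with "
                          "distinct ages; skipped")
            continue
        genes = sample_scores[idx[0]][0].genes
        for i in idx[1:]:
            genes = genes.intersection(sample_scores[i][0].genes)
        mat = np.column_stack([sample_scores[i][0].scores.loc[genes, ct]
                               for i in idx])  # genes x samples
        a = scaled[idx]
        if method == "spearman":
            mat = np.apply_along_axis(stats.rankdata, 1, mat)
            a = stats.rankdata(a)
        n = len(idx)
        ac = a - a.mean()
        mc = mat - mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((mc ** 2).sum(axis=1)) * np.sqrt((ac ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (mc @ ac) / denom
        constant = np.ptp(mat, axis=1) == 0
        r[constant | (denom == 0)] = np.nan
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(r)] = np.nan
        fdr = np.full(len(p), np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df = pd.DataFrame({
            "gene": genes, "cell_type": ct, "r": r, "p_value": p,
            "fdr": fdr,
            "direction": np.where(r >= 0, "positive", "negative"),
        })
        df.loc[np.isnan(r), "direction"] = None
        rows.append(df)
    if not rows:
        raise UsageError("no cell type has >= 4 age-annotated samples")
    table = pd.concat(rows, ignore_index=True)
    if global_fdr:
        ok = table["p_value"].notna()
        table.loc[ok, "fdr"] = multipletests(
            table.loc[ok, "p_value"], method="fdr_bh")[1]
    table["category"] = _categorize(table["fdr"].to_numpy(float))
    return MaturationTable(table=table, method=method)


def significance_summary(t: MaturationTable) -> pd.DataFrame:
    """Per-cell-type proportions of the three significance categories."""
    tab = t.table[t.table["category"].notna()]
    if tab.empty:
        raise UsageError("empty maturation table")
    out = (tab.groupby("cell_type")["category"]
              .value_counts(normalize=True)
              .unstack(fill_value=0.0))
    for c in CATEGORIES:
        if c not in out.columns:
            out[c] = 0.0
    return out[list(CATEGORIES)]


def gene_set_overlap(t: MaturationTable,
                     direction: str = "positive") -> pd.DataFrame:
    """Counts of significant genes (FDR < 0.05) per exact cell-type combo.

    Each gene is counted once, in the cell of the exact set of cell types
    in which it is significant with the requested direction; counts over
    all combinations therefore sum to the number of significant genes.
    """
    if direction not in ("positive", "negative"):
        raise UsageError("direction must be 'positive' or 'negative'")
    sig = t.table[(t.table["fdr"] < 0.05) &
                  (t.table["direction"] == direction)]
    combos = (sig.groupby("gene")["cell_type"]
                 .apply(lambda s: tuple(sorted(s))))
    counts = combos.value_counts()
    total = int(counts.sum())
    types = sorted(t.table["cell_type"].unique())
    rows = []
    for size in range(1, len(types) + 1):
        for combo in combinations(types, size):
            c = int(counts.get(combo, 0))
            rows.append({"cell_types": "+".join(combo), "n_types": size,
                         "count": c,
                         "percent": 100.0 * c / total if total else 0.0})
    return pd.DataFrame(rows)


def maturation_profile_similarity(t: MaturationTable) -> pd.DataFrame:
    """Pearson correlation of per-gene age-association profiles across types.

    Entries with fewer than 3 genes having non-null correlations in both
    cell types are null.
    """
    rmat = t.r_matrix()
    types = rmat.columns
    out = pd.DataFrame(np.nan, index=types, columns=types)
    for a in types:
        for b in types:
            va, vb = rmat[a], rmat[b]
            ok = va.notna() & vb.notna()
            if ok.sum() < 3:
                continue
            out.loc[a, b] = float(np.corrcoef(va[ok], vb[ok])[0, 1])
    return out
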