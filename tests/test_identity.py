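"""The differential-stability statistic, its invariants and oracle.

The brute-force oracle materializes every pairwise rank difference rather
than using the closed-form centering identity of the implementation.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

import retfid as rf
from retfid._exceptions import UsageError

from conftest import tiny_lognorm


def brute_force_scores(nz: pd.DataFrame, cv: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: explicit sum over all pairwise rank differences."""
    G, K = nz.shape
    r1 = nz.apply(lambda col: rankdata(col, method="average") / G, axis=0)
    r2 = (-cv).apply(lambda col: rankdata(col, method="average") / G, axis=0)
    out = pd.DataFrame(0.0, index=nz.index, columns=nz.columns)
    for k in nz.columns:
        acc = np.zeros(G)
        for k2 in nz.columns:
            if k2 == k:
                continue
            acc += ((r1[k] - r1[k2]) + (r2[k] - r2[k2])) / 2.0
        out[k] = acc / (K - 1)
    return out


class TestStabilityStats:
    @pytest.mark.parametrize("vals,exp_nz,exp_cv", [
        ((2.0, 2.0), 1.0, 0.0),       # constant expression
        ((0.0, 0.0), 0.0, np.inf),    # silent gene
        ((1.0, 3.0), 1.0, 0.5),       # sd=1 (population), mean=2
    ])
    def test_closed_forms(self, vals, exp_nz, exp_cv):
        m, ann = tiny_lognorm([[*vals, 1, 1], [1, 1, 1, 1]],
                              ["A", "A", "B", "B"])
        s = rf.stability_stats(m, ann, min_cells=1)
        assert s.nz.loc["g1", "A"] == exp_nz
        assert s.cv.loc["g1", "A"] == pytest.approx(exp_cv)

    def test_min_cells_drops_type(self):
        m, ann = tiny_lognorm(np.ones((2, 5)), ["A", "A", "B", "B", "C"])
        s = rf.stability_stats(m, ann, min_cells=2)
        assert set(s.nz.columns) == {"A", "B"}

    def test_single_type_rejected(self):
        m, ann = tiny_lognorm(np.ones((2, 4)), ["A"] * 4)
        with pytest.raises(UsageError, match="cell types"):
            rf.stability_stats(m, ann, min_cells=1)


class TestIdentityScores:
    def test_worked_example(self, worked_example):
        m, ann = worked_example
        scores = rf.identity_scores(
            rf.stability_stats(m, ann, min_cells=1)).scores
        assert scores.loc["g1", "A"] == pytest.approx(0.5)
        assert scores.loc["g1", "B"] == pytest.approx(-0.5)
        assert scores.loc["g2", "A"] == pytest.approx(-0.5)
        assert scores.loc["g2", "B"] == pytest.approx(0.5)
        assert scores.loc["g3", "A"] == pytest.approx(0.0)
        assert scores.loc["g3", "B"] == pytest.approx(0.0)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            G = rng.integers(2, 11)
            K = rng.integers(2, 5)
            nz = pd.DataFrame(rng.random((G, K)),
                              columns=[f"t{k}" for k in range(K)])
            cv = pd.DataFrame(rng.exponential(1.0, (G, K)),
                              columns=nz.columns)
            cv[nz == 0] = np.inf
            stats = rf.StabilityStats(nz=nz, cv=cv,
                                      n_cells=pd.Series(10, nz.columns))
            got = rf.identity_scores(stats).scores
            want = brute_force_scores(nz, cv)
            assert np.allclose(got, want, atol=1e-12)

    def test_per_gene_sum_zero_and_bounded(self, batch_scores):
        for ism in batch_scores:
            sums = ism.scores.sum(axis=1)
            assert np.abs(sums).max() < 1e-9
            assert (ism.scores.abs() < 1).all().all()

    def test_two_type_antisymmetry(self):
        rng = np.random.default_rng(0)
        m, ann = tiny_lognorm(rng.poisson(2.0, (30, 40)).astype(float),
                              ["A"] * 20 + ["B"] * 20)
        s = rf.identity_scores(rf.stability_stats(m, ann, min_cells=1)).scores
        assert np.allclose(s["A"], -s["B"])

    def test_identical_distributions_score_zero(self):
        m, ann = tiny_lognorm(np.tile([[2.0], [1.0], [0.0]], (1, 6)),
                              ["A"] * 3 + ["B"] * 3)
        s = rf.identity_scores(rf.stability_stats(m, ann, min_cells=1)).scores
        assert np.allclose(s, 0.0)

    def test_scale_invariance(self):
        """nz and cv are invariant to positive scaling, hence so are scores."""
        rng = np.random.default_rng(3)
        vals = rng.poisson(1.5, (20, 30)).astype(float)
        labels = ["A"] * 15 + ["B"] * 15
        m1, ann = tiny_lognorm(vals, labels)
        m2, _ = tiny_lognorm(vals * 7.3, labels)
        s1 = rf.identity_scores(rf.stability_stats(m1, ann, 1)).scores
        s2 = rf.identity_scores(rf.stability_stats(m2, ann, 1)).scores
        assert np.allclose(s1, s2)

    def test_label_permutation_within_type(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(1.5, (10, 20)).astype(float)
        m1, ann1 = tiny_lognorm(vals, ["A"] * 10 + ["B"] * 10)
        perm = np.r_[rng.permutation(10), 10 + rng.permutation(10)]
        m2, ann2 = tiny_lognorm(vals[:, perm], ["A"] * 10 + ["B"] * 10)
        s1 = rf.identity_scores(rf.stability_stats(m1, ann1, 1)).scores
        s2 = rf.identity_scores(rf.stability_stats(m2, ann2, 1)).scores
        assert np.allclose(s1, s2)


class TestScorerEstimator:
    def test_fit_matches_function_api(self, worked_example):
        m, ann = worked_example
        est = rf.DifferentialStabilityScorer(min_cells=1)
        est.fit(m.values.T, ann["cell_type"].to_numpy())
        direct = rf.identity_scores(
            rf.stability_stats(m, ann, min_cells=1)).scores
        assert np.allclose(est.scores_.to_numpy(), direct.to_numpy())
        assert est.transform(m.values.T).shape == (4, 2)

    def test_get_set_params_roundtrip(self):
        est = rf.DifferentialStabilityScorer(min_cells=7)
        assert est.get_params() == {"min_cells": 7}
        est.set_params(min_cells=3)
        assert est.min_cells == 3


class TestAverageScores:
    def _ism(self, scores, batch="b"):
        return rf.IdentityScoreMatrix(scores=scores, dataset="d", batch=batch)

    def test_single_batch_identity(self, batch_scores):
        one = rf.average_scores(batch_scores[:1])
        want = batch_scores[0].scores
        pd.testing.assert_frame_equal(one, want[one.columns])

    def test_symmetric_cancellation(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                         index=list("abcde"), columns=["A", "B"])
        out = rf.average_scores([self._ism(x), self._ism(-x)])
        assert np.allclose(out, 0.0)

    def test_type_missing_from_one_batch(self):
        x = pd.DataFrame({"A": [1.0, 2], "B": [3.0, 4]}, index=["a", "b"])
        y = pd.DataFrame({"A": [5.0, 6]}, index=["a", "b"])
        out = rf.average_scores([self._ism(x), self._ism(y)])
        assert np.allclose(out["B"], x["B"])  # divisor = 1 for type B
        assert np.allclose(out["A"], (x["A"] + y["A"]) / 2)

    def test_commutes_with_reordering(self, batch_scores):
        fwd = rf.average_scores(batch_scores)
        rev = rf.average_scores(batch_scores[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_disjoint_gene_universes_rejected(self):
        x = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["a"])
        y = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["b"])
        with pytest.raises(UsageError, match="intersection"):
            rf.average_scores([self._ism(x), self._ism(y)])


class TestBuildReference:
    def _batch(self, counts_by_type, batch, age=None):
        rng = np.random.default_rng(hash(batch) % 2 ** 31)
        labels = sum(([t] * n for t, n in counts_by_type.items()), [])
        vals = rng.poisson(2.0, (30, len(labels))).astype(float)
        cells = [f"{batch}_{i}" for i in range(len(labels))]
        m = rf.ExpressionMatrix(sp.csr_matrix(vals),
                                [f"g{i}" for i in range(30)], cells,
                                layer="counts")
        ann = pd.DataFrame({
            "cell_id": cells, "cell_type": labels, "dataset": "d",
            "batch": batch,
            "source": "tissue_fetal" if age else "tissue_mature",
            "age_dpc": age})
        return m, ann

    def test_pooled_proportions(self):
        b1 = self._batch({"A": 60, "B": 40}, "b1")
        b2 = self._batch({"A": 40, "B": 60}, "b2")
        ref = rf.build_reference([b1, b2], group="mature", min_cells=5)
        assert ref.proportions["A"] == pytest.approx(0.5)
        assert ref.proportions.sum() == pytest.approx(1.0)

    def test_age_split_default_100(self):
        batches = [self._batch({"A": 30, "B": 30}, f"b{a}", age=a)
                   for a in (59, 82, 125)]
        early = rf.build_reference(batches, group="fetal_early", min_cells=5)
        late = rf.build_reference(batches, group="fetal_late", min_cells=5)
        ages_of = lambda ref: {a for _, profs in ref.age_profiles.items()
                               for a, _ in profs}
        assert ages_of(early) == {59.0, 82.0}
        assert ages_of(late) == {125.0}

    def test_wrong_source_rejected(self):
        m, ann = self._batch({"A": 30, "B": 30}, "b1")
        ann["source"] = "organoid"
        with pytest.raises(UsageError, match="source"):
            rf.build_reference([(m, ann)], group="mature")

    def test_age_profiles_sorted(self, fetal_reference):
        for profs in fetal_reference.age_profiles.values():
            ages = [a for a, _ in profs]
            assert ages == sorted(ages)


class TestAnnotationConfidence:
    @pytest.fixture(scope="class")
    def gaussian_two_type(self):
        rng = np.random.default_rng(0)
        n, g = 200, 50
        mu = np.zeros((2, g))
        mu[1, :10] = 3.0
        X = np.abs(np.vstack([rng.normal(mu[i], 1.0, (n // 2, g))
                              for i in range(2)]))
        return tiny_lognorm(X.T, ["A"] * (n // 2) + ["B"] * (n // 2))

    def test_separated_types_high_confidence(self, gaussian_two_type):
        m, ann = gaussian_two_type
        conf = rf.annotation_confidence(m, ann, n_rounds=20, seed=0)
        assert conf.probability.mean() >= 0.95
        assert (conf.band == "very_high").mean() >= 0.9

    def test_swapped_labels_detected(self, gaussian_two_type):
        m, ann = gaussian_two_type
        rng = np.random.default_rng(1)
        idx = rng.choice(len(ann), len(ann) // 10, replace=False)
        ann2 = ann.copy()
        ann2.loc[idx, "cell_type"] = ann2.loc[idx, "cell_type"].map(
            {"A": "B", "B": "A"})
        conf = rf.annotation_confidence(m, ann2, n_rounds=20, seed=0)
        swapped = conf.probability.iloc[idx].mean()
        rest = conf.probability.drop(conf.probability.index[idx]).mean()
        assert swapped < rest

    def test_zero_rounds_rejected(self, gaussian_two_type):
        m, ann = gaussian_two_type
        with pytest.raises(UsageError, match="n_rounds"):
            rf.annotation_confidence(m, ann, n_rounds=0)

    def test_tiny_type_gets_null(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(1, 1, (20, 43)))
        m, ann = tiny_lognorm(X, ["A"] * 20 + ["B"] * 21 + ["C"] * 2)
        conf = rf.annotation_confidence(m, ann, n_rounds=10, seed=0)
        is_c = (ann["cell_type"] == "C").to_numpy()
        assert conf.probability[is_c].isna().all()
        assert conf.probability[~is_c].notna().all()


class TestFilterByConfidence:
    def _conf(self, probs):
        s = pd.Series(probs, index=[f"c{i}" for i in range(len(probs))])
        return rf.ConfidenceVector(probability=s, band=s * 0)

    def _ann(self, n):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                             "cell_type": "rod", "dataset": "d",
                             "batch": "b", "source": "tissue_mature"})

    def test_strict_inequality_at_threshold(self):
        out = rf.filter_by_confidence(self._ann(3),
                                      self._conf([0.95, 0.9, 0.2]),
                                      threshold=0.9)
        assert list(out["cell_id"]) == ["c0"]

    def test_threshold_zero_keeps_nonnull(self):
        out = rf.filter_by_confidence(self._ann(3),
                                      self._conf([0.5, 0.0, np.nan]),
                                      threshold=0.0)
        assert list(out["cell_id"]) == ["c0"]

    def test_all_null_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no cells"):
            out = rf.filter_by_confidence(self._ann(2),
                                          self._conf([np.nan, np.nan]))
        assert out.empty
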