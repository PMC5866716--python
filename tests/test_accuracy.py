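"""Confusion matrices, agreement statistics, McNemar tests and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2
from sklearn.metrics import cohen_kappa_score

from wetlandchange.accuracy import (
    AccuracyReport,
    ConfusionMatrix,
    class_accuracies,
    confusion_from_labels,
    confusion_matrix,
    kappa,
    mcnemar,
    overall_accuracy,
    pairwise_mcnemar,
    screen_classifiers,
)
from wetlandchange.raster import Grid, HabitatMap
from wetlandchange.sampling import LabeledSamples


def _cm(counts, ids=None):
    counts = np.asarray(counts)
    ids = ids or list(range(1, len(counts) + 1))
    return ConfusionMatrix(counts, ids, {c: str(c) for c in ids})


def _val_samples(y, rows=None, cols=None):
    n = len(y)
    rows = np.asarray(rows if rows is not None else np.zeros(n, int))
    cols = np.asarray(cols if cols is not None else np.arange(n))
    return LabeledSamples(np.zeros((n, 1)), np.asarray(y),
                          np.array(["validation"] * n), rows, cols,
                          np.arange(n), ["f0"])


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([1, 1, 2, 3, 3, 3])
        samples = _val_samples(y)
        hmap = HabitatMap(y.reshape(1, -1), {1: "a", 2: "b", 3: "c"},
                          Grid(1, 6))
        cm = confusion_matrix(hmap, samples)
        assert np.trace(cm.counts) == 6
        assert cm.counts.sum() - np.trace(cm.counts) == 0

    def test_matches_explicit_per_pixel_tally(self):
        ref = [1, 1, 2, 2, 3, 3]
        pred = [1, 2, 2, 2, 1, 3]
        cm = confusion_from_labels(pred, ref, [1, 2, 3])
        # hand tally: rows = predicted, columns = reference
        expected = np.array([[1, 0, 1],
                             [1, 2, 0],
                             [0, 0, 1]])
        np.testing.assert_array_equal(cm.counts, expected)

    def test_reference_label_outside_legend_raises(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_from_labels([1, 1], [1, 9], [1, 2])

    def test_empty_validation_set_raises(self):
        samples = _val_samples([1])
        samples.role[:] = "training"
        hmap = HabitatMap(np.array([[1]]), {1: "a"}, Grid(1, 1))
        with pytest.raises(ValueError, match="empty"):
            confusion_matrix(hmap, samples)

    def test_marginals_conserve_total(self, rng):
        counts = rng.integers(0, 30, (5, 5))
        cm = _cm(counts)
        n = cm.total
        assert cm.counts.sum(axis=0).sum() == n
        assert cm.counts.sum(axis=1).sum() == n


class TestAgreementStatistics:
    def test_overall_accuracy_trivial_cases(self):
        assert overall_accuracy(_cm(np.diag([3, 4, 5]))) == 1.0
        assert overall_accuracy(_cm([[0, 2], [3, 0]])) == 0.0

    def test_kappa_trivial_cases(self):
        assert kappa(_cm(np.diag([7, 9]))) == pytest.approx(1.0)
        assert kappa(_cm([[1, 1], [1, 1]])) == pytest.approx(0.0)

    def test_kappa_undefined_when_chance_agreement_is_one(self):
        assert np.isnan(kappa(_cm([[5, 0], [0, 0]])))

    def test_statistics_match_direct_formulas(self, rng):
        """100 random matrices vs independent formula evaluation."""
        for _ in range(100):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 25, (k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = _cm(counts)
            n = counts.sum()
            assert overall_accuracy(cm) == pytest.approx(np.trace(counts) / n)
            p_o = np.trace(counts) / n
            p_e = sum(counts[i, :].sum() * counts[:, i].sum()
                      for i in range(k)) / n**2
            if p_e < 1:
                assert kappa(cm) == pytest.approx((p_o - p_e) / (1 - p_e))
            pra, ura = class_accuracies(cm)
            for i, cid in enumerate(cm.class_ids):
                col = counts[:, i].sum()
                row = counts[i, :].sum()
                if col > 0:
                    assert pra[cid] == pytest.approx(counts[i, i] / col)
                else:
                    assert np.isnan(pra[cid])
                if row > 0:
                    assert ura[cid] == pytest.approx(counts[i, i] / row)
                else:
                    assert np.isnan(ura[cid])

    def test_kappa_agrees_with_sklearn(self, rng):
        """Independent oracle: rebuild label vectors, use cohen_kappa_score."""
        for _ in range(20):
            counts = rng.integers(0, 10, (4, 4))
            counts[0, 0] += 1
            pred, ref = [], []
            for i in range(4):
                for j in range(4):
                    pred += [i] * counts[i, j]
                    ref += [j] * counts[i, j]
            cm = _cm(counts)
            expected = cohen_kappa_score(ref, pred)
            assert kappa(cm) == pytest.approx(expected, abs=1e-12)

    def test_class_accuracies_hand_computed(self):
        cm = _cm([[8, 2], [0, 10]])
        pra, ura = class_accuracies(cm)
        assert ura[1] == pytest.approx(0.8) and ura[2] == pytest.approx(1.0)
        assert pra[1] == pytest.approx(1.0) and pra[2] == pytest.approx(10 / 12)


class TestMcNemar:
    def test_identical_classifiers_give_p_one(self):
        ref = np.array([1, 2, 1, 2])
        pred = np.array([1, 2, 2, 2])
        res = mcnemar(pred, pred, ref)
        assert res.b == res.c == 0
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_known_discordant_counts(self):
        """b=10, c=0 with continuity: chi2 = (10-1)^2/10 = 8.1."""
        ref = np.zeros(20, int)
        a = np.zeros(20, int)          # always correct
        b = np.zeros(20, int)
        b[:10] = 1                     # wrong on ten pixels
        res = mcnemar(a, b, ref, continuity=True)
        assert (res.b, res.c) == (10, 0)
        assert res.statistic == pytest.approx(8.1)
        assert res.p_value == pytest.approx(chi2.sf(8.1, 1))

    def test_swapping_classifiers_preserves_statistic(self, rng):
        ref = rng.integers(0, 3, 50)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        r1, r2 = mcnemar(a, b, ref), mcnemar(b, a, ref)
        assert (r1.b, r1.c) == (r2.c, r2.b)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_relabeling_invariance(self, rng):
        ref = rng.integers(0, 3, 60)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        relabel = {0: 10, 1: 20, 2: 30}
        f = np.vectorize(relabel.get)
        r1 = mcnemar(a, b, ref)
        r2 = mcnemar(f(a), f(b), f(ref))
        assert (r1.b, r1.c, r1.statistic, r1.p_value) == \
               (r2.b, r2.c, r2.statistic, r2.p_value)

    @pytest.mark.parametrize("continuity", [True, False])
    def test_matches_statsmodels_for_all_small_counts(self, continuity):
        """All (b, c) with b + c <= 50 vs an independent implementation."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for total in range(1, 51):
            for b in range(total + 1):
                c = total - b
                ref = np.zeros(b + c + 1, int)
                a = np.zeros_like(ref)
                bb = np.zeros_like(ref)
                a[:c] = 1          # A wrong, B correct on c pixels
                bb[c:c + b] = 1    # B wrong, A correct on b pixels
                res = mcnemar(a, bb, ref, continuity=continuity)
                assert (res.b, res.c) == (b, c)
                table = [[0, b], [c, 0]]
                sm = sm_mcnemar(table, exact=False, correction=continuity)
                assert res.statistic == pytest.approx(float(sm.statistic))
                assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mcnemar([1, 2], [1], [1, 2])


class TestScreening:
    def _pvals(self, ids, sig_pairs, p_sig=0.001):
        p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
        for a, b in sig_pairs:
            p.loc[a, b] = p.loc[b, a] = p_sig
        return p

    def test_no_significant_differences_retains_all(self):
        ids = ["a", "b", "c"]
        kept = screen_classifiers({"a": 0.9, "b": 0.85, "c": 0.8},
                                  self._pvals(ids, []))
        assert kept == ids

    def test_significantly_worse_algorithm_excluded(self):
        ids = ["a1", "a2", "a3"]
        reports = {"a1": 0.9, "a2": 0.9, "a3": 0.7}
        kept = screen_classifiers(reports, self._pvals(ids, [("a1", "a3")]))
        assert kept == ["a1", "a2"]

    def test_published_exclusion_pattern(self):
        """Constructed inputs where exactly pls+avNNet (and for the second
        date also gbm+svmRadial) are dropped."""
        ids = ["amdai", "avNNet", "gbm", "knn", "mda", "pls", "rf",
               "svmLinear", "svmPoly", "svmRadial"]
        oa = {a: 0.93 for a in ids}
        oa["pls"], oa["avNNet"] = 0.80, 0.82
        p1 = self._pvals(ids, [("pls", "amdai"), ("avNNet", "amdai")], 0.005)
        kept1 = screen_classifiers(oa, p1)
        assert sorted(set(ids) - set(kept1)) == ["avNNet", "pls"]

        oa2 = dict(oa)
        oa2["gbm"], oa2["svmRadial"] = 0.85, 0.86
        p2 = self._pvals(ids, [("pls", "amdai"), ("avNNet", "amdai"),
                               ("gbm", "svmLinear"), ("svmRadial", "svmLinear")],
                         0.02)
        kept2 = screen_classifiers(oa2, p2)
        assert sorted(set(ids) - set(kept2)) == ["avNNet", "gbm", "pls",
                                                 "svmRadial"]

    def test_top_accuracy_algorithm_never_excluded(self, rng):
        for _ in range(50):
            ids = [f"a{i}" for i in range(5)]
            oa = {a: float(rng.uniform(0.5, 1.0)) for a in ids}
            raw = rng.uniform(0, 1, (5, 5))
            pm = np.triu(raw, 1)
            pm = pm + pm.T + np.eye(5)
            kept = screen_classifiers(oa, pd.DataFrame(pm, index=ids, columns=ids))
            assert max(oa, key=oa.get) in kept

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            screen_classifiers({"a": 0.9}, pd.DataFrame([[1.0]], index=["a"],
                                                        columns=["a"]), alpha=1.5)

    def test_asymmetric_pvals_rejected(self):
        p = pd.DataFrame([[1.0, 0.1], [0.9, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            screen_classifiers({"a": 0.9, "b": 0.8}, p)


def test_pairwise_mcnemar_matrix_properties(rng):
    ref = rng.integers(0, 4, 80)
    preds = {f"alg{i}": rng.integers(0, 4, 80) for i in range(4)}
    p = pairwise_mcnemar(preds, ref)
    assert np.allclose(np.diag(p.to_numpy()), 1.0)
    assert np.allclose(p.to_numpy(), p.to_numpy().T)
    assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()
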