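"""Congruence matrix, ML modularity comparison, merge rule, covariance ratio."""

import numpy as np
import pandas as pd
import pytest

from morphosig.data import ValidationError
from morphosig.modularity import (CorrelationModularity, ModularityResults,
                                  ModuleHypothesis, congruence_matrix,
                                  covariance_ratio, default_hypothesis_set,
                                  merge_modules)


def factor_coords(n, k, labels, rho_within, rho_between, seed):
    """Landmark deviations with a per-module factor plus a global factor:
    coherent per-landmark motion so the congruence targets are analytic."""
    rng = np.random.default_rng(seed)
    mods = sorted(set(labels))
    total = 1.0
    sg2 = rho_between * total
    sf2 = rho_within - rho_between
    noise2 = (1.0 - rho_within) * total / 3.0
    X = np.zeros((n, k, 3))
    g = rng.standard_normal(n)
    dirs = {m: _unit(rng.standard_normal(3)) for m in mods}
    gdir = _unit(rng.standard_normal(3))
    for m in mods:
        f = rng.standard_normal(n)
        idx = [i for i, l in enumerate(labels) if l == m]
        X[:, idx, :] += np.sqrt(sf2) * f[:, None, None] * dirs[m]
    X += np.sqrt(sg2) * g[:, None, None] * gdir
    X += np.sqrt(noise2) * rng.standard_normal(X.shape)
    return X


def _unit(v):
    return v / np.linalg.norm(v)


class TestCongruence:
    def test_copied_and_negated_deviations(self):
        rng = np.random.default_rng(0)
        n, k = 30, 5
        X = rng.standard_normal((n, k, 3))
        X[:, 1, :] = X[:, 0, :]
        X[:, 2, :] = -X[:, 0, :]
        R = congruence_matrix(X)
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert R[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.all(np.diag(R) == 1.0)
        np.testing.assert_allclose(R, R.T, atol=1e-14)

    def test_independent_landmarks_have_small_congruence(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((1000, 2, 3))
            if abs(congruence_matrix(X)[0, 1]) < 0.1:
                hits += 1
        assert hits >= 29

    def test_zero_variance_landmark_named(self):
        X = np.random.default_rng(1).standard_normal((10, 3, 3))
        X[:, 2, :] = 7.0
        with pytest.raises(ValidationError, match="lm2"):
            congruence_matrix(X, landmark_ids=["lm0", "lm1", "lm2"])

    def test_invariant_to_global_rotation(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        np.testing.assert_allclose(congruence_matrix(X),
                                   congruence_matrix(X @ Q), atol=1e-10)


class TestEMMLi:
    def _hypotheses(self, k_per=20):
        labels3 = tuple(["A"] * k_per + ["B"] * k_per + ["C"] * k_per)
        labels2 = tuple(["A"] * k_per + ["BC"] * (2 * k_per))
        labels4 = tuple(["A1"] * (k_per // 2) + ["A2"] * (k_per - k_per // 2)
                        + ["B"] * k_per + ["C"] * k_per)
        return (labels3,
                [ModuleHypothesis("three", labels3),
                 ModuleHypothesis("two", labels2),
                 ModuleHypothesis("four", labels4)])

    def test_aicc_weights_sum_to_one(self):
        labels3, hyps = self._hypotheses(6)
        X = factor_coords(20, 18, labels3, 0.6, 0.2, seed=3)
        res = CorrelationModularity(congruence_matrix(X), hyps, 20).fit()
        assert res.table["weight"].sum() == pytest.approx(1.0, abs=1e-10)
        assert ((res.table["weight"] >= 0) & (res.table["weight"] <= 1)).all()

    def test_single_rho_data_prefers_one_module(self):
        k, n = 30, 50
        labels = tuple(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        hyps = [ModuleHypothesis("three", labels)]
        wins = 0
        reps = 40
        for seed in range(reps):
            X = factor_coords(n, k, ("Z",) * k, 0.5, 0.5 - 1e-9, seed=seed)
            res = CorrelationModularity(congruence_matrix(X), hyps, n).fit()
            if res.table.iloc[0]["n_modules"] == 1:
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_planted_three_module_structure_wins(self):
        labels3, hyps = self._hypotheses(20)
        wins = 0
        reps = 40
        for seed in range(reps):
            X = factor_coords(50, 60, labels3, 0.7, 0.2, seed=100 + seed)
            res = CorrelationModularity(congruence_matrix(X), hyps, 50).fit()
            if res.table.iloc[0]["hypothesis"] == "three":
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_ranking_invariant_to_landmark_reordering(self):
        labels3, hyps = self._hypotheses(6)
        X = factor_coords(25, 18, labels3, 0.7, 0.2, seed=5)
        R = congruence_matrix(X)
        rng = np.random.default_rng(6)
        perm = rng.permutation(18)
        hyps_p = [ModuleHypothesis(h.name, tuple(np.asarray(h.labels,
                                                            object)[perm]))
                  for h in hyps]
        r1 = CorrelationModularity(R, hyps, 25).fit()
        r2 = CorrelationModularity(R[np.ix_(perm, perm)], hyps_p, 25).fit()
        assert list(r1.table.index) == list(r2.table.index)
        np.testing.assert_allclose(r1.table["AICc"], r2.table["AICc"],
                                   atol=1e-9)

    def test_small_sample_size_rejected(self):
        with pytest.raises(ValidationError, match="exceed 3"):
            CorrelationModularity(np.eye(4), [], 3)


class TestMergeRule:
    def _result_with_rho(self, within, between, labels):
        hyp = ModuleHypothesis("h", labels)
        model = CorrelationModularity(np.eye(len(labels)), [hyp], 10)
        rho = {f"within.{m}": v for m, v in within.items()}
        rho.update({f"between.{a}|{b}": v for (a, b), v in between.items()})
        table = pd.DataFrame([{"model": "h.separate", "hypothesis": "h",
                               "between": "separate",
                               "n_modules": hyp.n_modules, "n_params": 1,
                               "logL": 0.0, "AICc": 0.0, "weight": 1.0}]
                             ).set_index("model")
        return ModularityResults(model=model, table=table,
                                 rho={"h.separate": rho})

    def test_between_within_threshold_triggers_merge(self):
        labels = ("A",) * 3 + ("B",) * 3
        res = self._result_with_rho({"A": 0.8, "B": 0.6}, {("A", "B"): 0.55},
                                    labels)
        merged = merge_modules(res, threshold=0.1)
        assert merged.n_modules == 1  # 0.55 >= 0.6 - 0.1

    def test_low_between_correlation_keeps_modules(self):
        labels = ("A",) * 3 + ("B",) * 3
        res = self._result_with_rho({"A": 0.8, "B": 0.6}, {("A", "B"): 0.3},
                                    labels)
        assert merge_modules(res, threshold=0.1).n_modules == 2

    def test_chained_merging_is_transitive(self):
        labels = ("A",) * 2 + ("B",) * 2 + ("C",) * 2 + ("D",) * 2
        res = self._result_with_rho(
            {"A": 0.6, "B": 0.6, "C": 0.6, "D": 0.6},
            {("A", "B"): 0.58, ("B", "C"): 0.57, ("A", "C"): 0.1,
             ("A", "D"): 0.1, ("B", "D"): 0.1, ("C", "D"): 0.1},
            labels)
        merged = merge_modules(res, threshold=0.1)
        assert merged.n_modules == 2
        lab = np.asarray(merged.labels, object)
        assert len(set(lab[:6])) == 1          # A, B, C united
        assert len(set(lab[6:])) == 1


class TestCovarianceRatio:
    def test_block_diagonal_data_has_zero_cr(self):
        rng = np.random.default_rng(7)
        n, k = 40, 8
        labels = ["A"] * 4 + ["B"] * 4
        X = np.zeros((n, k, 3))
        # exact zero between-block covariance by construction
        fa = rng.standard_normal(n)
        fb = rng.standard_normal(n)
        fa -= fa.mean()
        fb -= fb.mean()
        fb -= (fb @ fa) / (fa @ fa) * fa       # exactly uncorrelated factors
        X[:, :4, :] = fa[:, None, None] * rng.standard_normal((4, 3))
        X[:, 4:, :] = fb[:, None, None] * rng.standard_normal((4, 3))
        cr, p, pairs = covariance_ratio(X, labels, n_perm=49, seed=0)
        assert cr == pytest.approx(0.0, abs=1e-10)

    def test_unstructured_data_cr_near_one_not_significant(self):
        near, nonsig = 0, 0
        reps = 30
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((200, 40, 3))
            cr, p, _ = covariance_ratio(X, labels, n_perm=99, seed=seed)
            near += abs(cr - 1.0) < 0.15
            nonsig += p > 0.05
        assert near >= int(0.9 * reps)
        assert nonsig >= int(0.8 * reps)

    def test_planted_modular_data_detected(self):
        hits = 0
        reps = 30
        labels = ["A"] * 10 + ["B"] * 10
        for seed in range(reps):
            X = factor_coords(50, 20, labels, 0.7, 0.2, seed=300 + seed)
            cr, p, _ = covariance_ratio(X, labels, n_perm=199, seed=seed)
            if cr < 1.0 and p <= 0.01:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_invariant_to_global_rotation(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 8, 3))
        labels = ["A"] * 4 + ["B"] * 4
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        cr1, _, _ = covariance_ratio(X, labels, n_perm=5, seed=0)
        cr2, _, _ = covariance_ratio(X @ Q, labels, n_perm=5, seed=0)
        assert cr1 == pytest.approx(cr2, rel=1e-10)

    def test_tiny_module_rejected(self):
        X = np.random.default_rng(1).standard_normal((10, 4, 3))
        with pytest.raises(ValidationError, match="fewer than 2"):
            covariance_ratio(X, ["A", "A", "A", "B"], n_perm=9)


class TestHypothesisSet:
    def test_default_set_spans_two_to_full(self, small_scheme):
        hyps = default_hypothesis_set(small_scheme)
        sizes = sorted(h.n_modules for h in hyps)
        assert sizes[0] == 2
        assert sizes[-1] == len(small_scheme.module_names)
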