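from dataclasses import replace

import numpy as np
import pytest

from metasurv.cohort_io import CohortCollection, DataError, TrainedSignature
from metasurv.discordance_model import (FitConfig, fit, hinge_loss_subgradient,
                                        joint_loss, lodo_select_lambda,
                                        pooled_loss_subgradient, score,
                                        train_signature)
from metasurv.preprocess import rank_transform_collection
from metasurv.survival_metrics import ComparablePairList, comparable_pairs
from metasurv.synthetic_cohorts import default_config, simulate_collection

from conftest import make_cohort, random_cohort


def naive_loss_gradient(X, w, times, events):
    """Independent oracle: O(m*d) double loop over the pair definitions."""
    n = X.shape[1]
    b = X.T @ w
    loss = 0.0
    grad = np.zeros_like(w)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[j] > times[i]:
                margin = 1.0 + b[i] - b[j]
                if margin > 0:
                    loss += margin
                if b[j] - b[i] < 1.0:
                    grad += X[:, i] - X[:, j]
    return loss, grad


def random_instance(rng, n, d):
    X = rng.standard_normal((d, n))
    times = rng.exponential(1.0, n)
    events = (rng.random(n) > 0.4).astype(int)
    w = rng.standard_normal(d)
    return X, w, times, events


class TestHingeLossSubgradient:
    def test_zero_w_gives_pair_count(self, rng):
        X, _, times, events = random_instance(rng, 20, 4)
        pairs = comparable_pairs(times, events)
        res = hinge_loss_subgradient(X, np.zeros(4), pairs)
        assert res.loss == pytest.approx(pairs.m)

    def test_hand_traced_two_samples(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])  # x1=(1,0), x2=(0,1)
        pairs = ComparablePairList(j=[1], i=[0], n_samples=2)
        res = hinge_loss_subgradient(X, np.zeros(2), pairs)
        assert res.loss == pytest.approx(1.0)
        np.testing.assert_allclose(res.gradient, [1.0, -1.0])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_naive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 50))
        d = int(rng.integers(1, 10))
        X, w, times, events = random_instance(rng, n, d)
        pairs = comparable_pairs(times, events)
        res = hinge_loss_subgradient(X, w, pairs)
        loss, grad = naive_loss_gradient(X, w, times, events)
        assert res.loss == pytest.approx(loss, abs=1e-9)
        np.testing.assert_allclose(res.gradient, grad, atol=1e-9)

    def test_dimension_mismatch(self, rng):
        X = rng.standard_normal((3, 5))
        with pytest.raises(DataError, match="mismatch"):
            hinge_loss_subgradient(X, np.zeros(2),
                                   ComparablePairList(j=[1], i=[0], n_samples=5))


class TestJointLoss:
    def test_k1_equals_single_cohort(self, rng):
        cohort = random_cohort(rng, n=15, p=4)
        col = CohortCollection([cohort])
        w = rng.standard_normal(4)
        pairs = comparable_pairs(cohort.clinical.time, cohort.clinical.event)
        single = hinge_loss_subgradient(cohort.expression.values, w, pairs)
        lam = 0.7
        joint = joint_loss(col, w, lam)
        assert joint.loss == pytest.approx(single.loss + lam * w @ w)
        np.testing.assert_allclose(joint.gradient,
                                   single.gradient + 2 * lam * w)

    def test_k2_additivity(self, rng):
        a = random_cohort(rng, name="a", n=12, p=3)
        b = random_cohort(rng, name="b", n=14, p=3)
        w = rng.standard_normal(3)
        la = joint_loss(CohortCollection([a]), w, 0.0).loss
        lb = joint_loss(CohortCollection([b]), w, 0.0).loss
        lab = joint_loss(CohortCollection([a, b]), w, 0.0).loss
        assert lab == pytest.approx(la + lb)

    def test_per_cohort_time_rescaling_invariant(self, rng):
        a = random_cohort(rng, name="a", n=12, p=3)
        b = random_cohort(rng, name="b", n=14, p=3)
        w = rng.standard_normal(3)
        before = joint_loss(CohortCollection([a, b]), w, 0.3)
        b7 = make_cohort("b", b.expression.values, b.clinical.time * 7,
                         b.clinical.event, genes=b.feature_ids, prefix="b")
        after = joint_loss(CohortCollection([a, b7]), w, 0.3)
        assert after.loss == before.loss
        np.testing.assert_array_equal(after.gradient, before.gradient)

    def test_pooled_loss_not_rescaling_invariant(self, rng):
        a = random_cohort(rng, name="a", n=12, p=3)
        b = random_cohort(rng, name="b", n=14, p=3)
        w = rng.standard_normal(3)
        before = pooled_loss_subgradient(CohortCollection([a, b]), w)
        b7 = make_cohort("b", b.expression.values, b.clinical.time * 7,
                         b.clinical.event, genes=b.feature_ids, prefix="b")
        after = pooled_loss_subgradient(CohortCollection([a, b7]), w)
        assert after.loss != before.loss

    def test_cohort_order_invariant(self, rng):
        a = random_cohort(rng, name="a", n=10, p=3)
        b = random_cohort(rng, name="b", n=11, p=3)
        w = rng.standard_normal(3)
        ab = joint_loss(CohortCollection([a, b]), w, 0.1)
        ba = joint_loss(CohortCollection([b, a]), w, 0.1)
        assert ab.loss == ba.loss
        np.testing.assert_array_equal(ab.gradient, ba.gradient)

    def test_convexity(self, small_collection, rng):
        ranked = rank_transform_collection(small_collection)
        d = len(ranked.gene_universe)
        for _ in range(20):
            w1, w2 = rng.standard_normal(d), rng.standard_normal(d)
            for t in (0.25, 0.5, 0.75):
                mid = joint_loss(ranked, t * w1 + (1 - t) * w2, 0.4).loss
                bound = (t * joint_loss(ranked, w1, 0.4).loss
                         + (1 - t) * joint_loss(ranked, w2, 0.4).loss)
                assert mid <= bound + 1e-9

    def test_finite_difference_gradient(self, small_collection, rng):
        ranked = rank_transform_collection(small_collection)
        d = len(ranked.gene_universe)
        eps = 1e-6
        checked = 0
        while checked < 10:
            w = rng.standard_normal(d)
            v = rng.standard_normal(d)
            v /= np.linalg.norm(v)
            # skip points near hinge kinks
            margins = []
            for c in ranked:
                b = c.expression.values.T @ w
                pairs = comparable_pairs(c.clinical.time, c.clinical.event)
                margins.append(np.abs(b[pairs.j] - b[pairs.i] - 1.0).min())
            if min(margins) < 1e-4:
                continue
            res = joint_loss(ranked, w, 0.2)
            f1 = joint_loss(ranked, w + eps * v, 0.2).loss
            f0 = joint_loss(ranked, w - eps * v, 0.2).loss
            numeric = (f1 - f0) / (2 * eps)
            analytic = res.gradient @ v
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-8)
            checked += 1


class TestFit:
    def test_huge_lambda_shrinks_to_zero(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        sig = fit(ranked, FitConfig(lam=1e8))
        assert np.linalg.norm(sig.coefficients) < 1e-3

    def test_descent_from_zero_init(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        sig = fit(ranked, FitConfig(lam=0.5))
        at_zero = joint_loss(ranked, np.zeros_like(sig.coefficients), 0.5).loss
        final = joint_loss(ranked, sig.coefficients, 0.5).loss
        assert final <= at_zero

    def test_separable_instance_reaches_c1(self, rng):
        # scores of a known w* order every pair with margin
        d, n = 3, 15
        w_star = np.array([2.0, -1.0, 0.5])
        cohorts = []
        for k in range(2):
            X = rng.standard_normal((d, n))
            b = X.T @ w_star
            times = np.argsort(np.argsort(b)).astype(float) + 1.0  # longer b -> later
            cohorts.append(make_cohort(f"c{k}", X, times, np.ones(n, dtype=int)))
        col = CohortCollection(cohorts)
        sig = fit(col, FitConfig(lam=1e-6))
        from metasurv.survival_metrics import concordance_index

        for c in col:
            risk = -(sig.coefficients @ c.expression.values)
            res = concordance_index(risk, c.clinical.time, c.clinical.event)
            assert res.c == 1.0

    def test_deterministic(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        a = fit(ranked, FitConfig(lam=0.1))
        b = fit(ranked, FitConfig(lam=0.1))
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestLodoSelectLambda:
    def test_two_folds_for_k2(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        report = lodo_select_lambda(ranked, [0.1, 1.0])
        assert report.heldout_loss.shape == (2, 2)
        np.testing.assert_allclose(report.cumulated_loss,
                                   report.heldout_loss.sum(axis=1))

    def test_singleton_grid(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        report = lodo_select_lambda(ranked, [0.5])
        assert report.best_lambda == 0.5

    def test_k1_refused(self, rng):
        col = CohortCollection([random_cohort(rng, n=15, p=3)])
        with pytest.raises(DataError, match="at least 2"):
            lodo_select_lambda(col, [0.1, 1.0])

    def test_best_attains_minimum(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        report = lodo_select_lambda(ranked, [0.01, 0.1, 1.0])
        idx = list(report.lambda_grid).index(report.best_lambda)
        assert report.cumulated_loss[idx] == report.cumulated_loss.min()

    def test_regularization_path_norm_non_increasing(self, small_collection):
        ranked = rank_transform_collection(small_collection)
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        norms = [np.linalg.norm(fit(ranked, FitConfig(lam=lam)).coefficients)
                 for lam in grid]
        for a, b in zip(norms, norms[1:]):
            assert b <= a + 1e-6

    def test_noisy_collection_wants_regularization(self):
        # p >> signal: the smallest lambda should rarely win
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            cohorts = [random_cohort(rng, name=f"c{k}", n=25, p=40)
                       for k in range(3)]
            ranked = rank_transform_collection(CohortCollection(cohorts))
            report = lodo_select_lambda(ranked, [1e-4, 1e-2, 1.0, 100.0])
            hits += report.best_lambda > 1e-4
        assert hits >= 8


class TestTrainSignature:
    def test_recovery_on_default_collection(self, default_collection):
        collection, truth = default_collection
        result = train_signature(collection.cohorts)
        selected = set(result.signature.gene_ids)
        true_set = set(truth.prognostic_gene_ids)
        jaccard = len(selected & true_set) / len(selected | true_set)
        assert jaccard >= 0.3

    def test_deterministic_end_to_end(self, rng):
        cohorts = [random_cohort(rng, name=f"c{k}", n=30, p=15)
                   for k in range(2)]
        kwargs = dict(alpha=1.0, lambda_grid=[0.1, 1.0])
        a = train_signature(cohorts, **kwargs)
        b = train_signature(cohorts, **kwargs)
        assert a.signature.gene_ids == b.signature.gene_ids
        np.testing.assert_array_equal(a.signature.coefficients,
                                      b.signature.coefficients)

    def test_alpha_one_selects_all(self, rng):
        cohorts = [random_cohort(rng, name=f"c{k}", n=25, p=10)
                   for k in range(2)]
        result = train_signature(cohorts, alpha=1.0, lambda_grid=[0.5])
        assert len(result.signature.gene_ids) == 10

    def test_single_cohort_needs_explicit_lambda(self, rng):
        cohorts = [random_cohort(rng, n=30, p=5)]
        with pytest.raises(DataError, match="one cohort"):
            train_signature(cohorts, alpha=1.0)
        result = train_signature(cohorts, alpha=1.0, lam=0.5)
        assert result.signature.lam == 0.5
        assert result.cv_report is None

    def test_provenance_recorded(self, rng):
        cohorts = [random_cohort(rng, name=f"c{k}", n=25, p=8)
                   for k in range(2)]
        result = train_signature(cohorts, alpha=1.0, lambda_grid=[0.1, 1.0])
        prov = result.signature.provenance
        assert prov["alpha"] == 1.0
        assert prov["n_common_genes"] == 8
        assert "score_convention" in prov


class TestScore:
    def test_single_gene_reverses_rank_order(self, rng):
        cohort = random_cohort(rng, n=10, p=4)
        sig = TrainedSignature([cohort.feature_ids[0]], np.array([1.0]), lam=0.0)
        risk = score(sig, cohort)
        from metasurv.preprocess import percentile_rank_transform

        ranks = percentile_rank_transform(cohort.expression).values[0]
        np.testing.assert_array_equal(np.argsort(risk), np.argsort(-ranks))

    def test_monotone_distortion_invariance(self, rng):
        cohort = random_cohort(rng, n=12, p=5)
        sig = TrainedSignature(cohort.feature_ids[:3],
                               rng.standard_normal(3), lam=0.0)
        base = score(sig, cohort)
        distorted = make_cohort(cohort.name, np.exp(cohort.expression.values),
                                cohort.clinical.time, cohort.clinical.event,
                                genes=cohort.feature_ids, prefix=cohort.name)
        np.testing.assert_array_equal(score(sig, distorted), base)

    def test_missing_gene_errors(self, rng):
        cohort = random_cohort(rng, n=10, p=3)
        sig = TrainedSignature(["absent"], np.array([1.0]), lam=0.0)
        with pytest.raises(DataError, match="absent"):
            score(sig, cohort)

    def test_constant_sample_errors(self, rng):
        values = rng.standard_normal((4, 6))
        values[:, 2] = 3.14
        cohort = make_cohort("c", values, np.arange(1.0, 7.0),
                             np.ones(6, dtype=int))
        sig = TrainedSignature(cohort.feature_ids[:2], np.ones(2), lam=0.0)
        with pytest.raises(DataError, match="constant"):
            score(sig, cohort)
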