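"""LDA engine: posteriors, entropy, similarity scoring, AD bands."""

import numpy as np
import pytest

from qsarprofiler.base import DescriptorSpec, TrainingRecord, ValidationError
from qsarprofiler.fixtures import FixtureConfig, make_lda_fixture
from qsarprofiler.lda import (
    ClassPrediction,
    LdaClassifier,
    cosine_similarity,
    endpoint_ad_check_lda,
    fit_lda,
    predict_lda,
    shannon_entropy,
    structural_ad_check_lda,
)

SPEC_X = [DescriptorSpec(name="x", source="supplied")]


def _records(values, labels):
    return [
        TrainingRecord(id=f"c{i}", descriptor_values=(float(v),), y=lab)
        for i, (v, lab) in enumerate(zip(values, labels))
    ]


class TestFit:
    def test_symmetric_classes_put_boundary_at_zero(self):
        x = [-6, -5, -4, 4, 5, 6]
        labels = ["neg"] * 3 + ["pos"] * 3
        model = fit_lda(SPEC_X, _records(x, labels))
        pred = predict_lda(model, [0.0])
        assert pred.posteriors["neg"] == pytest.approx(0.5, abs=1e-10)
        assert pred.posteriors["pos"] == pytest.approx(0.5, abs=1e-10)
        assert predict_lda(model, [-0.1]).label == "neg"
        assert predict_lda(model, [0.1]).label == "pos"

    def test_single_member_class_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 members"):
            fit_lda(SPEC_X, _records([-1, 0, 1], ["a", "a", "b"]))

    def test_discriminant_direction_matches_closed_form(self, rng):
        model, _ = make_lda_fixture(FixtureConfig(n=40, p=3, seed=11))
        est = model.estimator
        X = model.training_matrix()
        y = np.array([str(r.y) for r in model.training])
        # independent recomputation: pooled covariance from scratch
        mus = {c: X[y == c].mean(axis=0) for c in est.classes_}
        pooled = np.zeros((3, 3))
        for c in est.classes_:
            D = X[y == c] - mus[c]
            pooled += D.T @ D
        pooled /= len(y) - 2
        oracle = np.linalg.solve(pooled, mus[est.classes_[1]] - mus[est.classes_[0]])
        direction = est.coef_[1] - est.coef_[0]
        assert direction / np.linalg.norm(direction) == pytest.approx(
            oracle / np.linalg.norm(oracle), abs=1e-8
        )

    def test_wide_separation_gives_perfect_training_accuracy(self):
        model, _ = make_lda_fixture(
            FixtureConfig(n=40, p=3, class_separation=10.0, seed=3)
        )
        X = model.training_matrix()
        y = np.array([str(r.y) for r in model.training])
        assert (model.estimator.predict(X) == y).all()

    def test_affine_rescaling_leaves_posteriors_unchanged(self):
        model, queries = make_lda_fixture(FixtureConfig(n=40, p=3, seed=5))
        X = model.training_matrix()
        y = np.array([str(r.y) for r in model.training])
        scale = np.array([100.0, 0.01, 3.0])
        shift = np.array([5.0, -2.0, 0.0])
        est2 = LdaClassifier().fit(X * scale + shift, y)
        q = np.array([q.values for q in queries])
        p1 = model.estimator.predict_proba(q)
        p2 = est2.predict_proba(q * scale + shift)
        assert p1 == pytest.approx(p2, abs=1e-8)


class TestPosteriors:
    def test_query_at_class_mean_is_near_certain(self):
        model, _ = make_lda_fixture(
            FixtureConfig(n=60, p=2, class_separation=10.0, seed=9)
        )
        X = model.training_matrix()
        y = np.array([str(r.y) for r in model.training])
        mu = X[y == "active"].mean(axis=0)
        pred = predict_lda(model, mu)
        assert pred.label == "active"
        assert pred.posteriors["active"] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        model, _ = make_lda_fixture(FixtureConfig(n=40, p=3, seed=2))
        Q = rng.normal(0, 3, size=(1000, 3))
        proba = model.estimator.predict_proba(Q)
        assert proba.sum(axis=1) == pytest.approx(np.ones(1000), abs=1e-10)

    def test_entropy_vanishes_with_growing_separation(self):
        entropies = []
        for sep in (1.0, 5.0, 12.0):
            model, _ = make_lda_fixture(
                FixtureConfig(n=60, p=2, class_separation=sep, seed=4)
            )
            X = model.training_matrix()
            entropies.append(float(np.mean(model.estimator.entropy(X))))
        assert entropies[0] > entropies[1] > entropies[2]
        assert entropies[2] < 1e-4


class TestEntropyAndCosine:
    @pytest.mark.parametrize(
        "posteriors,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 1.0), ((0.25, 0.75), 0.811278)],
    )
    def test_entropy_values_in_bits(self, posteriors, expected):
        assert shannon_entropy(posteriors) == pytest.approx(expected, abs=1e-6)

    def test_entropy_base_is_configurable(self):
        assert shannon_entropy((0.5, 0.5), base=np.e) == pytest.approx(np.log(2))

    def test_cosine_identities(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.974632, abs=1e-6
        )

    def test_cosine_rejects_zero_vector(self):
        with pytest.raises(ValidationError):
            cosine_similarity([0, 0], [1, 1])


class TestStructuralAD:
    def test_centroid_query_passes(self):
        model, _ = make_lda_fixture(FixtureConfig(n=40, p=3, seed=6))
        X = model.training_matrix()
        v = structural_ad_check_lda(model, X.mean(axis=0))
        assert v.in_ad
        assert v.details["similarity"] == pytest.approx(1.0)

    def test_lowest_scoring_training_chemical_fails(self):
        model, _ = make_lda_fixture(FixtureConfig(n=40, p=3, seed=6))
        i = int(np.argmin(model.train_scores))
        v = structural_ad_check_lda(model, model.training[i].descriptor_values)
        assert not v.in_ad

    def test_percentile_direction_default_keeps_most_training_in_ad(self):
        model, _ = make_lda_fixture(FixtureConfig(n=200, p=3, seed=8))
        in_ad = sum(
            structural_ad_check_lda(model, r.descriptor_values).in_ad
            for r in model.training
        )
        assert in_ad / 200 >= 0.94

    def test_literal_percentile_mode_reproduces_verbatim_rule(self):
        cfg = FixtureConfig(n=200, p=3, seed=8)
        lit, _ = make_lda_fixture(cfg)
        lit = fit_lda(lit.specs, lit.training, literal_percentile=True)
        assert lit.sim_cutoff == pytest.approx(
            np.percentile(lit.train_scores, 95.0)
        )
        in_ad = sum(
            structural_ad_check_lda(lit, r.descriptor_values).in_ad
            for r in lit.training
        )
        assert in_ad / 200 <= 0.06

    def test_max_train_similarity_mode(self):
        model, _ = make_lda_fixture(FixtureConfig(n=30, p=3, seed=10))
        alt = fit_lda(model.specs, model.training, similarity_mode="max_train")
        # a training chemical is maximally similar to itself
        score = alt.estimator.similarity_scores(
            np.array([alt.training[0].descriptor_values])
        )[0]
        assert score == pytest.approx(1.0)


class TestEndpointAD:
    @pytest.mark.parametrize(
        "p_event,in_ad", [(0.5, False), (0.9, True), (0.75, True), (0.25, True),
                          (0.7499, False)]
    )
    def test_posterior_band_conventions(self, p_event, in_ad):
        pred = ClassPrediction(
            label="a", posteriors={"a": max(p_event, 1 - p_event),
                                   "b": min(p_event, 1 - p_event)},
            entropy=0.0, similarity=1.0, structural_in_ad=True, endpoint_in_ad=True,
        )
        assert endpoint_ad_check_lda(pred).in_ad is in_ad

    def test_overlapping_classes_are_flagged(self):
        model, _ = make_lda_fixture(
            FixtureConfig(n=40, p=2, class_separation=0.0, seed=12)
        )
        X = model.training_matrix()
        pred = predict_lda(model, X.mean(axis=0))
        assert 0.25 < max(pred.posteriors.values()) < 0.75
        assert not pred.endpoint_in_ad
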