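"""Naïve Bayes classifier: prior, sampling, training, scoring, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from finet.features import FEATURES
from finet.nbc import (
    NBCModel,
    TrainingSet,
    compute_prior,
    evaluate_roc,
    predict_fis,
    sample_negative_pairs,
    score_matrix,
    score_pair,
    train_nbc,
)


def joint_table_posterior(model, vector):
    """Independent oracle: posterior by direct evaluation of the full
    joint probability table (plain products, no logs)."""
    p_pos = model.prior
    p_neg = 1.0 - model.prior
    for f, v in zip(model.feature_names, vector):
        tp, tn = model.theta_pos[f], model.theta_neg[f]
        p_pos *= tp if v else (1.0 - tp)
        p_neg *= tn if v else (1.0 - tn)
    return p_pos / (p_pos + p_neg)


def random_training_set(rng, n_features=None):
    feats = list(FEATURES if n_features is None else FEATURES[:n_features])
    n_pos = int(rng.integers(2, 9))
    n_neg = int(rng.integers(3, 20))
    pos = rng.random((n_pos, len(feats))) < rng.uniform(0.3, 0.9)
    pos[pos.sum(axis=1) == 0, 0] = True  # every positive needs a feature
    neg = rng.random((n_neg, len(feats))) < rng.uniform(0.01, 0.3)
    mk = lambda arr, tag: pd.DataFrame(
        arr,
        columns=feats,
        index=pd.MultiIndex.from_tuples(
            [(f"{tag}{i}a", f"{tag}{i}b") for i in range(len(arr))]
        ),
    )
    return TrainingSet(positives=mk(pos, "p"), negatives=mk(neg, "n"))


class TestPrior:
    def test_two_proteins(self):
        assert compute_prior(1, 2) == 1.0

    def test_four_proteins(self):
        assert compute_prior(3, 4) == 0.5

    def test_paper_scale_arithmetic(self):
        # 45,079 positives over 3,978 proteins -> 5.70e-3 pair density
        assert compute_prior(45079, 3978) == pytest.approx(5.70e-3, rel=5e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_prior(1, 1)
        with pytest.raises(ValueError):
            compute_prior(10, 4)


class TestNegativeSampling:
    def test_no_pair_available(self):
        with pytest.raises(ValueError):
            sample_negative_pairs(["A", "B"], {("A", "B")}, 1, seed=0)

    def test_exhaustive_draw(self):
        got = sample_negative_pairs(["A", "B", "C", "D"], set(), 6, seed=0)
        assert len(got) == 6

    def test_deterministic_under_seed(self):
        uni = [f"P{i}" for i in range(50)]
        a = sample_negative_pairs(uni, set(), 100, seed=7)
        b = sample_negative_pairs(uni, set(), 100, seed=7)
        assert a == b

    def test_positives_excluded(self):
        uni = [f"P{i}" for i in range(10)]
        pos = {("P0", "P1"), ("P2", "P3")}
        got = sample_negative_pairs(uni, pos, 40, seed=1)
        assert not (got & pos)


class TestTraining:
    def test_laplace_counts(self):
        rng = np.random.default_rng(0)
        ts = random_training_set(rng)
        # force feature 0 true in both positives
        ts.positives.iloc[:, 0] = True
        m = train_nbc(ts, prior=0.1)
        n_pos = len(ts.positives)
        assert m.theta_pos[FEATURES[0]] == pytest.approx(
            (n_pos + 1) / (n_pos + 2)
        )

    def test_smoothing_floor(self):
        pos = pd.DataFrame(
            [[True, False], [True, False]],
            columns=["f1", "f2"],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d")]),
        )
        neg = pd.DataFrame(
            [[False, False], [False, False]],
            columns=["f1", "f2"],
            index=pd.MultiIndex.from_tuples([("e", "f"), ("g", "h")]),
        )
        m = train_nbc(TrainingSet(positives=pos, negatives=neg), prior=0.5)
        assert m.theta_pos["f1"] == pytest.approx(3 / 4)
        assert m.theta_pos["f2"] == pytest.approx(1 / 4)
        assert m.theta_neg["f1"] == pytest.approx(1 / 4)

    def test_symmetric_features_equal_theta(self):
        pos = pd.DataFrame(
            [[True, True], [False, False]],
            columns=["f1", "f2"],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("c", "d")]),
        )
        # make both rows have >=1 feature
        pos.iloc[1] = [True, True]
        neg = pos.copy()
        neg.index = pd.MultiIndex.from_tuples([("e", "f"), ("g", "h")])
        m = train_nbc(TrainingSet(positives=pos, negatives=neg), prior=0.3)
        assert m.theta_pos["f1"] == m.theta_pos["f2"]

    def test_overlapping_classes_rejected(self):
        pos = pd.DataFrame(
            [[True]], columns=["f1"],
            index=pd.MultiIndex.from_tuples([("a", "b")]),
        )
        with pytest.raises(ValueError):
            TrainingSet(positives=pos, negatives=pos.copy())


class TestScoring:
    def test_uninformative_features_score_prior(self):
        theta = {f: 0.4 for f in FEATURES}
        m = NBCModel(prior=0.37, theta_pos=dict(theta), theta_neg=dict(theta))
        v = dict.fromkeys(FEATURES, True)
        assert score_pair(m, v) == pytest.approx(0.37, abs=1e-12)

    def test_matches_joint_table_oracle_all_vectors(self):
        """Log-space scoring equals the brute-force joint-table posterior
        on every feature vector, over many random tiny models."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            ts = random_training_set(rng)
            prior = float(rng.uniform(0.01, 0.5))
            m = train_nbc(ts, prior)
            for bits in itertools.product(
                [False, True], repeat=len(FEATURES)
            ):
                expected = joint_table_posterior(m, bits)
                got = score_pair(m, list(bits))
                assert got == pytest.approx(expected, abs=1e-10)

    def test_likelihood_ratio_monotonicity(self):
        rng = np.random.default_rng(3)
        ts = random_training_set(rng)
        ts.positives.iloc[:, :] = True
        ts.negatives.iloc[:, :] = False
        m = train_nbc(ts, prior=0.1)
        v_hi = [True] * len(FEATURES)
        v_lo = list(v_hi)
        v_lo[4] = False
        assert score_pair(m, v_hi) >= score_pair(m, v_lo)


class TestROC:
    def _model(self):
        rng = np.random.default_rng(5)
        return train_nbc(random_training_set(rng), prior=0.05)

    def test_perfect_separation_auc_one(self):
        m = self._model()
        pos = pd.DataFrame(
            [[True] * len(FEATURES)] * 3, columns=list(FEATURES),
            index=pd.MultiIndex.from_tuples(
                [(f"p{i}", f"q{i}") for i in range(3)]
            ),
        )
        neg = pd.DataFrame(
            [[False] * len(FEATURES)] * 3, columns=list(FEATURES),
            index=pd.MultiIndex.from_tuples(
                [(f"r{i}", f"s{i}") for i in range(3)]
            ),
        )
        roc = evaluate_roc(m, pos, neg)
        assert roc.auc == pytest.approx(1.0)

    def test_single_pair_auc(self):
        m = self._model()
        pos = pd.DataFrame(
            [[True] * len(FEATURES)], columns=list(FEATURES),
            index=pd.MultiIndex.from_tuples([("p", "q")]),
        )
        neg = pd.DataFrame(
            [[False] * len(FEATURES)], columns=list(FEATURES),
            index=pd.MultiIndex.from_tuples([("r", "s")]),
        )
        assert evaluate_roc(m, pos, neg).auc == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        m = self._model()
        pos = pd.DataFrame(columns=list(FEATURES))
        with pytest.raises(ValueError):
            evaluate_roc(m, pos, pos)


class TestPrediction:
    def _candidates(self, rows, tag="c"):
        return pd.DataFrame(
            rows,
            columns=list(FEATURES),
            index=pd.MultiIndex.from_tuples(
                [(f"{tag}{i}a", f"{tag}{i}b") for i in range(len(rows))]
            ),
        )

    def test_all_false_never_predicted(self):
        m = NBCModel(
            prior=0.99,
            theta_pos={f: 0.9 for f in FEATURES},
            theta_neg={f: 0.5 for f in FEATURES},
        )
        cands = self._candidates([[False] * len(FEATURES)])
        assert predict_fis(m, cands) == set()

    def test_default_threshold_is_half(self):
        rng = np.random.default_rng(1)
        m = train_nbc(random_training_set(rng), prior=0.05)
        assert m.threshold == 0.50

    def test_threshold_monotone(self):
        rng = np.random.default_rng(2)
        ts = random_training_set(rng)
        cands = self._candidates(
            (rng.random((40, len(FEATURES))) < 0.4).tolist()
        )
        lo = predict_fis(train_nbc(ts, 0.1, threshold=0.2), cands)
        hi = predict_fis(train_nbc(ts, 0.1, threshold=0.8), cands)
        assert hi <= lo

    def test_near_zero_threshold_emits_all_with_feature(self):
        rng = np.random.default_rng(4)
        ts = random_training_set(rng)
        m = train_nbc(ts, 0.1, threshold=1e-12)
        rows = (rng.random((20, len(FEATURES))) < 0.4).tolist()
        cands = self._candidates(rows)
        got = predict_fis(m, cands)
        assert len(got) == int(cands.any(axis=1).sum())


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        m = train_nbc(random_training_set(rng), prior=0.07)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = NBCModel.from_json(path)
        assert back.prior == m.prior
        assert back.theta_pos == m.theta_pos
        assert back.threshold == m.threshold
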