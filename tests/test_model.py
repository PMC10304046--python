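import datetime as dt
import math

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.metrics import precision_recall_fscore_support

from suppnlp import (
    NoteDocument,
    SnippetVectorizer,
    SupplementUseClassifier,
    build_feature_space,
    corpus_observations,
    cross_validate,
    load_model,
    save_model,
    separable_fixture,
    train,
    vectorize,
)
from suppnlp.model import per_class_metrics, snippet_bigrams, weighted_average

D = dt.date(2016, 6, 1)


def obs_from_text(text, lexicon, label=None):
    out = corpus_observations([NoteDocument("P1", D, text)], lexicon)
    for o in out:
        o.label = label
    return out


class TestFeatureSpace:
    def test_bigrams_enumerated_from_tokens(self, lexicon):
        (obs,) = obs_from_text("vitamin d daily", lexicon)
        space = build_feature_space([obs])
        assert set(space.bigram_index) == {("vitamin", "d"), ("d", "daily")}

    def test_duplicate_snippets_do_not_grow_the_space(self, lexicon):
        obs = obs_from_text("taking calcium daily", lexicon)
        once = build_feature_space(obs)
        twice = build_feature_space(obs + obs)
        assert once.bigram_index == twice.bigram_index
        assert once.keyword_index == twice.keyword_index

    def test_bigram_set_equals_brute_force_enumeration(self, lexicon, labeled_obs):
        space = build_feature_space(labeled_obs)
        brute = set()
        for o in labeled_obs:
            folded = [t.casefold() for t in o.tokens]
            for a, b in zip(folded, folded[1:]):
                brute.add((a, b))
        assert set(space.bigram_index) == brute

    def test_column_order_is_lexicographic(self, lexicon, labeled_obs):
        space = build_feature_space(labeled_obs)
        ordered = sorted(space.bigram_index, key=space.bigram_index.get)
        assert ordered == sorted(space.bigram_index)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_feature_space([])


class TestVectorize:
    def test_unseen_snippet_sets_only_keyword_indicator(self, lexicon):
        train_obs = obs_from_text("taking calcium daily", lexicon)
        space = build_feature_space(train_obs)
        (new,) = obs_from_text("calcium level checked again", lexicon)
        v = vectorize(new, space)
        assert v.nnz == 1
        n_bigrams = len(space.bigram_index)
        assert v.indices[0] == n_bigrams + space.keyword_index["calcium"]

    def test_training_observation_sets_its_known_bigrams(self, lexicon, labeled_obs):
        space = build_feature_space(labeled_obs)
        for o in labeled_obs[:20]:
            v = vectorize(o, space)
            known = {bg for bg in snippet_bigrams(o.tokens) if bg in space.bigram_index}
            assert v.nnz == len(known) + 1

    def test_same_snippet_different_keyword_differs_only_in_indicator(self, lexicon):
        obs = obs_from_text("calcium and iron daily", lexicon)
        assert [o.keyword for o in obs] == ["calcium", "iron"]
        space = build_feature_space(obs)
        n_bigrams = len(space.bigram_index)
        v1, v2 = (vectorize(o, space).toarray().ravel() for o in obs)
        assert np.array_equal(v1[:n_bigrams], v2[:n_bigrams])
        assert not np.array_equal(v1[n_bigrams:], v2[n_bigrams:])

    def test_unknown_keyword_routed_to_explicit_level(self, lexicon):
        train_obs = obs_from_text("taking calcium daily", lexicon)
        vec = SnippetVectorizer().fit(train_obs)
        (other,) = obs_from_text("taking melatonin nightly", lexicon)
        v = vec.transform([other])
        n_bigrams = len(vec.feature_space_.bigram_index)
        unknown_col = n_bigrams + vec.feature_space_.keyword_index["<unknown>"]
        assert unknown_col in v.indices


class TestTrain:
    def test_separable_fixture_reaches_training_accuracy_one(self, lexicon):
        obs = separable_fixture(300, seed=5, lexicon=lexicon)
        clf = train(obs)
        y = np.asarray([o.label for o in obs], dtype=object)
        assert (clf.predict(obs) == y).mean() == 1.0

    def test_fixture_is_linearly_separable_by_lp_feasibility(self, lexicon):
        # independent oracle: a feasible (w, b) with y(wx+b) >= 1 exists
        obs = separable_fixture(300, seed=5, lexicon=lexicon)
        X = SnippetVectorizer().fit(obs).transform(obs)
        y = np.where(np.asarray([o.label for o in obs]) == "yes", 1.0, -1.0)
        A = sp.hstack([X, np.ones((X.shape[0], 1))]).tocsr()
        A = -sp.diags(y) @ A
        res = linprog(
            c=np.zeros(A.shape[1]),
            A_ub=A,
            b_ub=-np.ones(A.shape[0]),
            bounds=[(None, None)] * A.shape[1],
            method="highs",
        )
        assert res.status == 0  # feasible

    def test_same_data_same_seed_identical_weights(self, lexicon):
        obs = separable_fixture(200, seed=2, lexicon=lexicon)
        c1, c2 = train(obs, seed=7), train(obs, seed=7)
        assert np.array_equal(c1.coef_, c2.coef_)
        assert c1.intercept_ == c2.intercept_

    def test_single_class_input_rejected(self, lexicon):
        obs = obs_from_text("taking calcium and iron daily", lexicon, label="yes")
        with pytest.raises(ValueError, match="degenerate training set"):
            train(obs)

    def test_model_serialization_round_trips_bit_exactly(self, lexicon, tmp_path):
        obs = separable_fixture(200, seed=2, lexicon=lexicon)
        clf = train(obs)
        path = tmp_path / "model.json"
        save_model(clf, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.coef_, clf.coef_)
        assert loaded.intercept_ == clf.intercept_
        assert loaded.vectorizer_.feature_space_ == clf.vectorizer_.feature_space_
        assert list(loaded.predict(obs)) == list(clf.predict(obs))


class TestMetrics:
    def test_precision_recall_from_confusion_counts(self):
        # TP=3, FP=1, FN=1 for class "yes"
        y_true = ["yes"] * 4 + ["no"] * 3
        y_pred = ["yes", "yes", "yes", "no", "yes", "no", "no"]
        m = per_class_metrics(y_true, y_pred)["yes"]
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_agrees_with_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            y_true = rng.choice(["yes", "no"], size=n)
            y_pred = rng.choice(["yes", "no"], size=n)
            if len(set(y_true)) < 2:
                continue
            ours = per_class_metrics(y_true, y_pred)
            p, r, f, s = precision_recall_fscore_support(
                y_true, y_pred, labels=["no", "yes"], zero_division=np.nan
            )
            for i, cls in enumerate(["no", "yes"]):
                for got, ref in [
                    (ours[cls].precision, p[i]),
                    (ours[cls].recall, r[i]),
                    (ours[cls].f1, f[i]),
                ]:
                    assert (math.isnan(got) and math.isnan(ref)) or got == pytest.approx(ref)
                assert ours[cls].support == s[i]

    def test_weighted_average_lies_between_class_values(self):
        y_true = ["yes"] * 10 + ["no"] * 5
        y_pred = ["yes"] * 8 + ["no"] * 2 + ["no"] * 4 + ["yes"]
        per = per_class_metrics(y_true, y_pred)
        w = weighted_average(per)
        f1s = [m.f1 for m in per.values()]
        assert min(f1s) <= w.f1 <= max(f1s)


class TestCrossValidate:
    def test_report_structure_mirrors_class_rows(self, lexicon):
        obs = separable_fixture(120, seed=3, lexicon=lexicon)
        rep = cross_validate(obs, k=4, seed=0)
        assert set(rep.per_class) == {"yes", "no"}
        d = rep.to_dict()
        assert set(d["classes"]) == {"yes", "no"}
        assert "Weighted Avg." in rep.table()
        folds = np.bincount(rep.fold_assignments)
        assert len(folds) == 4 and folds.max() - folds.min() <= 1

    def test_k_larger_than_n_rejected(self, lexicon):
        obs = separable_fixture(20, seed=3, lexicon=lexicon)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(obs, k=50)

    def test_deterministic_bit_for_bit(self, lexicon):
        obs = separable_fixture(150, seed=4, lexicon=lexicon)
        r1 = cross_validate(obs, k=5, seed=9)
        r2 = cross_validate(obs, k=5, seed=9)
        assert r1.to_dict() == r2.to_dict()

    def test_no_leakage_test_fold_labels_never_touch_training_weights(self, lexicon):
        from sklearn.model_selection import StratifiedKFold

        obs = separable_fixture(120, seed=6, lexicon=lexicon)
        y = np.asarray([o.label for o in obs], dtype=object)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        train_idx, test_idx = next(skf.split(np.zeros(len(y)), y))
        clf = SupplementUseClassifier().fit([obs[i] for i in train_idx])
        # permute the test-fold labels: training-fold weights must not move
        rng = np.random.default_rng(0)
        for i in test_idx:
            obs[i].label = str(rng.choice(["yes", "no"]))
        clf2 = SupplementUseClassifier().fit([obs[i] for i in train_idx])
        assert np.array_equal(clf.coef_, clf2.coef_)
        assert clf.intercept_ == clf2.intercept_
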