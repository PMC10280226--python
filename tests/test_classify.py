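"""Split protocols, tuned base models and the majority-vote hybrid."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ppgcopd as pc
from ppgcopd.classify import DEFAULT_GRIDS, MODEL_KINDS
from ppgcopd.exceptions import ConfigError, SchemaError, SingleClassError
from ppgcopd.features import FeatureMatrix


def _matrix(X, y, sids=None):
    cols = [f"PPG/f{i + 1:02d}_x" for i in range(X.shape[1])]
    if sids is None:
        sids = np.array(["s"] * len(y))
    return FeatureMatrix(data=pd.DataFrame(X, columns=cols),
                         labels=np.asarray(y), subject_ids=np.asarray(sids))


def _blobs(rng, n=400, sep=6.0, d=5):
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, d)) + sep * y[:, None]
    return _matrix(X, y)


def test_split_5050_stratified_and_deterministic(rng):
    m = _blobs(rng, n=100, sep=0.0)
    tr, te = pc.split(m, pc.SplitSpec(seed=3))
    assert len(tr) == len(te) == 50
    assert np.sum(m.labels[tr]) == 25 and np.sum(m.labels[te]) == 25
    assert len(np.intersect1d(tr, te)) == 0
    tr2, te2 = pc.split(m, pc.SplitSpec(seed=3))
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(te, te2)
    tr3, _ = pc.split(m, pc.SplitSpec(seed=4))
    assert not np.array_equal(tr, tr3)


def test_split_odd_counts_differ_by_at_most_one(rng):
    y = np.array([0] * 51 + [1] * 49)
    m = _matrix(rng.standard_normal((100, 3)), y)
    tr, te = pc.split(m, pc.SplitSpec(seed=0))
    for cls in (0, 1):
        n_tr = np.sum(m.labels[tr] == cls)
        n_te = np.sum(m.labels[te] == cls)
        assert abs(n_tr - n_te) <= 1


def test_loso_fold_structure(rng):
    sids = np.repeat([f"s{i}" for i in range(6)], 10)
    y = np.repeat([1, 1, 1, 0, 0, 0], 10)
    m = _matrix(rng.standard_normal((60, 3)), y, sids)
    folds = list(pc.split(m, pc.SplitSpec(mode="leave_one_subject_out")))
    assert [f[0] for f in folds] == [f"s{i}" for i in range(6)]
    test_union = np.concatenate([f[2] for f in folds])
    assert sorted(test_union) == list(range(60))
    for sid, tr, te in folds:
        assert set(m.subject_ids[te]) == {sid}
        assert sid not in set(m.subject_ids[tr])


def test_loso_single_class_training_rejected(rng):
    sids = np.repeat(["a", "b"], 10)
    y = np.repeat([1, 0], 10)
    m = _matrix(rng.standard_normal((20, 3)), y, sids)
    with pytest.raises(SingleClassError):
        list(pc.split(m, pc.SplitSpec(mode="leave_one_subject_out")))


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_separable_blobs_low_cv_loss(rng, kind):
    m = _blobs(rng, n=400, sep=6.0)
    model = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind=kind, seed=0))
    assert model.cv_loss <= 0.02
    labels, scores = model.predict(m.data)
    assert np.mean(labels == m.labels) >= 0.99
    assert scores.min() >= 0.0 and scores.max() <= 1.0


def test_permuted_labels_near_chance_cv_loss():
    losses = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((300, 5))
        y = rng.permutation(np.repeat([0, 1], 150))
        m = _matrix(X, y)
        model = pc.tune_and_fit(m.data, m.labels,
                                pc.ClassifierSpec(kind="knn", seed=seed))
        losses.append(model.cv_loss)
    assert 0.35 <= np.mean(losses) <= 0.6


def test_tuning_deterministic(rng):
    m = _blobs(rng, n=120, sep=1.0)
    a = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="svm", seed=5))
    b = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="svm", seed=5))
    assert a.chosen_hypers == b.chosen_hypers
    la, sa = a.predict(m.data)
    lb, sb = b.predict(m.data)
    np.testing.assert_array_equal(la, lb)
    np.testing.assert_array_equal(sa, sb)


def test_knn_grid_covers_stated_search_space():
    grid = DEFAULT_GRIDS["knn"]
    combos = set()
    for block in grid:
        for k in block["clf__n_neighbors"]:
            for metric in block["clf__metric"]:
                combos.add((k, metric))
    assert combos == {(k, d) for k in (3, 5, 7)
                      for d in ("euclidean", "manhattan", "minkowski")}


def test_zero_variance_feature_dropped(rng):
    m = _blobs(rng, n=80, sep=4.0, d=3)
    m.data["PPG/f99_const"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        model = pc.tune_and_fit(m.data, m.labels,
                                pc.ClassifierSpec(kind="knn", seed=0))
    assert model.dropped_columns == ["PPG/f99_const"]
    labels, _ = model.predict(m.data)  # predicts despite the extra column
    assert labels.shape == (80,)


def test_predict_schema_mismatch(rng):
    m = _blobs(rng, n=60, sep=4.0)
    model = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="knn"))
    bad = m.data.rename(columns={m.data.columns[0]: "other"})
    with pytest.raises(SchemaError):
        model.predict(bad)


def test_knn_vote_fraction_scores(rng):
    m = _blobs(rng, n=60, sep=8.0)
    model = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="knn"))
    _, scores = model.predict(m.data)
    # deep inside each blob every neighbor agrees: scores are 0 or 1
    assert set(np.round(scores[m.labels == 1], 6)) == {1.0}
    assert set(np.round(scores[m.labels == 0], 6)) == {0.0}


def test_majority_vote_exhaustive():
    for combo in itertools.product([0, 1], repeat=3):
        assert pc.majority_vote(combo) == int(sum(combo) >= 2)


class _Stub:
    """Fixed-output stand-in member for vote-fusion tests."""

    def __init__(self, labels, scores):
        self._labels = np.asarray(labels)
        self._scores = np.asarray(scores)

    def predict(self, rows):
        return self._labels, self._scores


def test_hybrid_vote_and_score_fusion():
    rows = pd.DataFrame({"a": [0.0] * 8})
    combos = list(itertools.product([0, 1], repeat=3))
    stubs = [_Stub([c[i] for c in combos], [0.5] * 8) for i in range(3)]
    h = pc.HybridModel.__new__(pc.HybridModel)
    h.members = stubs
    labels, _ = h.predict(rows)
    np.testing.assert_array_equal(labels, [int(sum(c) >= 2) for c in combos])

    h2 = pc.HybridModel.__new__(pc.HybridModel)
    h2.members = [_Stub([1], [0.9]), _Stub([1], [0.8]), _Stub([0], [0.1])]
    labels, scores = h2.predict(pd.DataFrame({"a": [0.0]}))
    assert labels[0] == 1
    assert scores[0] == pytest.approx(0.6)


def test_hybrid_of_identical_members_equals_member(rng):
    m = _blobs(rng, n=100, sep=2.0)
    member = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="knn"))
    h = pc.HybridModel([member, member, member])
    ml, ms = member.predict(m.data)
    hl, hs = h.predict(m.data)
    np.testing.assert_array_equal(hl, ml)
    np.testing.assert_allclose(hs, ms)


def test_hybrid_needs_three_members(rng):
    m = _blobs(rng, n=60, sep=2.0)
    member = pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="knn"))
    with pytest.raises(ConfigError):
        pc.HybridModel([member, member])


def test_single_class_training_rejected(rng):
    X = rng.standard_normal((20, 3))
    m = _matrix(X, np.zeros(20, dtype=int))
    with pytest.raises(SingleClassError):
        pc.tune_and_fit(m.data, m.labels, pc.ClassifierSpec(kind="knn"))
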