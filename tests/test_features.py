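"""The 25 epoch descriptors against an independent naive transcription."""

import numpy as np
import pytest

import ppgcopd as pc
from naive_oracles import naive_features
from ppgcopd.exceptions import DegenerateEpoch, ManifestMismatch, TooShort
from ppgcopd.features import FEATURE_NAMES, all_signal_columns


def idx(short):
    return next(i for i, n in enumerate(FEATURE_NAMES) if n.endswith(short))


def test_hand_values_small_epoch():
    fv = pc.extract_features([1.0, 2.0, 3.0, 4.0]).as_dict()
    assert fv["f15_mean"] == pytest.approx(2.5)
    assert fv["f07_activity"] == pytest.approx(5.0 / 3.0)
    assert fv["f20_std"] == pytest.approx(np.sqrt(5.0 / 3.0))
    assert fv["f18_rms"] == pytest.approx(np.sqrt(7.5))
    assert fv["f16_curve_length"] == pytest.approx(3.0 / 4.0)
    assert fv["f17_energy"] == pytest.approx(7.5)
    assert fv["f22_svd"] == pytest.approx(np.sqrt(30.0))


def test_constant_epoch_collapses_and_flags():
    # 4.25 is exactly representable, so the epoch is exactly constant
    fv = pc.extract_features(np.full(10, 4.25))
    d = fv.as_dict()
    assert d["f25_teager"] == 0.0
    assert d["f16_curve_length"] == 0.0
    assert d["f10_max"] == d["f13_min"] == d["f15_mean"] == d["f11_median"] == 4.25
    # variance-based features are undefined: sanitized to 0 and flagged
    assert d["f01_kurtosis"] == 0.0
    assert fv.flagged[idx("kurtosis")] and fv.flagged[idx("mobility")]
    assert not fv.flagged[idx("mean")]


def test_oracle_equivalence_on_random_epochs(rng):
    """Every feature matches the naive loop transcription to 1e-9 relative
    on 100 random 200-sample epochs (mixed scales and offsets)."""
    for _ in range(100):
        scale = 10.0 ** rng.uniform(-2, 2)
        x = rng.standard_normal(200) * scale + rng.uniform(-1, 1) * scale
        got = pc.extract_features(x).values
        want = np.array(naive_features(list(x)))
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-300)


def test_hjorth_conventions(rng):
    act, mob, comp = pc.hjorth(np.arange(10.0))
    assert mob == 0.0 and comp == 0.0  # ramp: zero-variance first difference
    x = rng.standard_normal(10_000)
    act, mob, comp = pc.hjorth(x)
    assert act == pytest.approx(1.0, rel=0.1)
    with pytest.raises(DegenerateEpoch):
        pc.hjorth(np.ones(10))
    with pytest.raises(TooShort):
        pc.hjorth(np.ones(3))


def test_trimmed_mean_conventions():
    assert pc.trimmed_mean([1, 2, 3, 4, 100], 25) == pytest.approx(3.0)
    x = np.array([5.0, 1.0, 9.0, 2.0, 7.0])
    assert pc.trimmed_mean(x, 0) == pytest.approx(np.mean(x))
    sym = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
    assert pc.trimmed_mean(sym, 25) == pytest.approx(np.mean(sym))
    with pytest.raises(DegenerateEpoch):
        pc.trimmed_mean([1.0, 2.0], 90)


# documented positive-homogeneity degree per feature (x -> a*x, a > 0)
_SCALE_DEGREE_1 = ("iqr", "max", "median", "mad", "min", "mean",
                   "curve_length", "rms", "std_err", "std", "svd",
                   "trim_mean25", "trim_mean50", "geo_mean", "harm_mean")
_SCALE_DEGREE_2 = ("activity", "energy", "teager")
_SCALE_DEGREE_0 = ("kurtosis", "skewness", "cv", "mobility", "complexity")


def test_scale_homogeneity(rng):
    x = rng.standard_normal(200)
    a = 3.7
    base = pc.extract_features(x).as_dict()
    scaled = pc.extract_features(a * x).as_dict()
    for name in FEATURE_NAMES:
        short = name.split("_", 1)[1]
        if short in _SCALE_DEGREE_1:
            assert scaled[name] == pytest.approx(a * base[name], rel=1e-9), name
        elif short in _SCALE_DEGREE_2:
            assert scaled[name] == pytest.approx(a ** 2 * base[name], rel=1e-9), name
        elif short in _SCALE_DEGREE_0:
            assert scaled[name] == pytest.approx(base[name], rel=1e-9), name
        elif short == "shape_factor":  # degree 1/2
            assert scaled[name] == pytest.approx(np.sqrt(a) * base[name],
                                                 rel=1e-9)
        elif short == "cmoment10":
            assert scaled[name] == pytest.approx(a ** 10 * base[name], rel=1e-9)


def test_shift_invariance(rng):
    x = rng.standard_normal(200)
    base = pc.extract_features(x).as_dict()
    shifted = pc.extract_features(x + 11.3).as_dict()
    for short in ("kurtosis", "skewness", "std", "iqr", "mad",
                  "curve_length", "activity"):
        name = next(n for n in FEATURE_NAMES if n.endswith(short))
        assert shifted[name] == pytest.approx(base[name], rel=1e-9, abs=1e-9), short


def test_matrix_shape_and_alignment(rng):
    fs = 100.0
    sets = []
    for sid, label in (("a", "COPD"), ("b", "HEALTHY")):
        sig = rng.standard_normal((4, 600))
        bands = pc.BandSet(*sig, fs=fs)
        sets.append(pc.epoch(bands, 2.0, subject_id=sid, label=label))
    cohort = pc.Cohort([
        pc.PpgRecord("a", rng.standard_normal(10), fs, label="COPD",
                     age=60.0, weight=100.0, height=170.0),
        pc.PpgRecord("b", rng.standard_normal(10), fs, label="HEALTHY",
                     age=50.0, weight=90.0, height=180.0)])
    m = pc.build_matrix(sets, cohort)
    assert m.data.shape == (6, 100)
    assert list(m.data.columns) == all_signal_columns()
    assert list(m.labels) == [1, 1, 1, 0, 0, 0]
    # row 1 = subject a's second epoch; spot-check the LF block
    want = pc.extract_features(sets[0].epochs[1, 1, :]).values
    np.testing.assert_allclose(
        m.data.iloc[1][m.pool_columns("LF")].to_numpy(), want)

    md = pc.build_matrix(sets, cohort, include_demographics=True)
    assert md.data.shape == (6, 103)
    assert md.data["demo/age"].tolist() == [60.0] * 3 + [50.0] * 3

    with pytest.raises(ManifestMismatch):
        pc.build_matrix(sets, pc.Cohort(cohort.records[:1]))


def test_matrix_csv_round_trip(tmp_path, small_matrix):
    p = tmp_path / "m.csv"
    small_matrix.to_csv(p)
    back = pc.FeatureMatrix.from_csv(p)
    np.testing.assert_array_equal(back.labels, small_matrix.labels)
    np.testing.assert_allclose(back.data.to_numpy(),
                               small_matrix.data.to_numpy(), rtol=0, atol=0)
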