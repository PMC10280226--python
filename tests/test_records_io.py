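"""Record model, CSV/EDF round trips and cohort manifests."""

import numpy as np
import pandas as pd
import pytest

import ppgcopd as pc
from ppgcopd.exceptions import (ChannelNotFound, CorruptSignal,
                                DuplicateSubject, IrregularSampling,
                                LabelParseError, PpgIoError)


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        pc.PpgRecord("s", [], fs=100)
    with pytest.raises(ValueError):
        pc.PpgRecord("s", [1.0, 2.0], fs=0)
    with pytest.raises(CorruptSignal):
        pc.PpgRecord("s", [1.0, np.nan], fs=100)
    with pytest.raises(LabelParseError):
        pc.PpgRecord("s", [1.0], fs=100, label="sickish")


def test_csv_round_trip_bit_identical(tmp_path, rng):
    x = rng.standard_normal(500)
    rec = pc.PpgRecord("s1", x, fs=128.0, label="COPD")
    p = tmp_path / "s1.csv"
    pc.write_record(rec, p)
    back = pc.read_record(p, label="copd")
    assert back.fs == 128.0
    np.testing.assert_array_equal(back.samples, x)
    assert back.label == pc.COPD


def test_csv_fs_from_time_column(tmp_path):
    t = np.arange(300) * 0.01
    pd.DataFrame({"time": t, "amplitude": np.sin(t)}).to_csv(
        tmp_path / "a.csv", index=False)
    rec = pc.read_record(tmp_path / "a.csv")
    assert rec.fs == pytest.approx(100.0)


def test_csv_single_column_needs_fs(tmp_path):
    pd.DataFrame({"amplitude": [0.0, 1.0, 0.0, -1.0]}).to_csv(
        tmp_path / "a.csv", index=False)
    with pytest.raises(PpgIoError):
        pc.read_record(tmp_path / "a.csv")
    rec = pc.read_record(tmp_path / "a.csv", fs=4)
    assert rec.fs == 4 and rec.samples.size == 4


def test_irregular_time_grid_rejected(tmp_path):
    t = np.arange(100) * 0.01
    t[50] += 0.004  # 40% of the median step
    pd.DataFrame({"time": t, "amplitude": t}).to_csv(
        tmp_path / "bad.csv", index=False)
    with pytest.raises(IrregularSampling):
        pc.read_record(tmp_path / "bad.csv")


def test_nonfinite_samples_rejected(tmp_path):
    pd.DataFrame({"time": [0, 0.01, 0.02], "amplitude": [1, np.inf, 3]}
                 ).to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(CorruptSignal):
        pc.read_record(tmp_path / "bad.csv")


@pytest.mark.parametrize("fs", [100.0, 128.0, 62.5, 97.3])
def test_edf_round_trip_quantization_bound(tmp_path, rng, fs):
    """EDF stores 16-bit ints over a declared physical range: the round
    trip must preserve fs exactly and samples within range/2**15."""
    x = rng.standard_normal(1234) * 3.7
    rec = pc.PpgRecord("e1", x, fs=fs)
    p = tmp_path / "e1.edf"
    pc.write_record(rec, p)
    back = pc.read_record(p)
    assert back.fs == fs
    assert back.samples.size == x.size
    declared_range = 2 * np.max(np.abs(back.samples))  # <= writer's range
    bound = max(declared_range, 2 * np.max(np.abs(x))) / 2 ** 15
    assert np.max(np.abs(back.samples - x)) <= bound


def test_edf_matches_independent_reader(tmp_path, rng):
    """Cross-check the hand-written EDF writer against mne's EDF reader."""
    mne = pytest.importorskip("mne")
    x = rng.standard_normal(800)
    rec = pc.PpgRecord("x", x, fs=100.0)
    p = tmp_path / "x.edf"
    pc.write_record(rec, p)
    raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    assert raw.info["sfreq"] == pytest.approx(100.0)
    got = raw.get_data()[0][: x.size]
    # mne may rescale to SI units; compare up to that constant factor
    scale = np.dot(got, x) / np.dot(x, x)
    np.testing.assert_allclose(got / scale, x, atol=2e-4 * np.abs(x).max())


def test_edf_missing_channel(tmp_path, rng):
    rec = pc.PpgRecord("x", rng.standard_normal(200), fs=100.0)
    p = tmp_path / "x.edf"
    pc.write_record(rec, p)
    with pytest.raises(ChannelNotFound):
        pc.read_record(p, channel="SpO2")


def test_manifest_round_trip_order_stable(tmp_path, rng):
    recs = [pc.PpgRecord(f"s{i}", rng.standard_normal(200), fs=100.0,
                         label=pc.COPD if i % 2 else pc.HEALTHY,
                         age=50.0 + i, weight=90.0, height=170.0, sex="M")
            for i in range(4)]
    paths = []
    for r in recs:
        p = tmp_path / f"{r.subject_id}.csv"
        pc.write_record(r, p)
        paths.append(p.name)
    from ppgcopd.records import write_manifest
    write_manifest(pc.Cohort(recs), paths, tmp_path / "manifest.csv")
    cohort = pc.load_cohort(tmp_path / "manifest.csv")
    assert [r.subject_id for r in cohort] == [r.subject_id for r in recs]
    assert cohort.labels == [r.label for r in recs]
    assert cohort.records[1].age == 51.0


def test_manifest_missing_file_names_row(tmp_path):
    pd.DataFrame({"path": ["nope.csv"], "label": ["copd"]}).to_csv(
        tmp_path / "manifest.csv", index=False)
    with pytest.raises(PpgIoError, match="row 0"):
        pc.load_cohort(tmp_path / "manifest.csv")


def test_duplicate_subject_rejected(rng):
    r = pc.PpgRecord("dup", rng.standard_normal(10), fs=100.0)
    with pytest.raises(DuplicateSubject):
        pc.Cohort([r, pc.PpgRecord("dup", rng.standard_normal(10), fs=100.0)])


def test_label_parsing_case_insensitive():
    assert pc.parse_label("Copd") == pc.COPD
    assert pc.parse_label("HEALTHY") == pc.HEALTHY
    with pytest.raises(LabelParseError):
        pc.parse_label("maybe")
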