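"""Container I/O, resample/pad pipeline, measurement oracle, splits."""

import numpy as np
import pytest

from ecgdx.container import FormatError, read_dataset, write_dataset, labels_from_sidecar
from ecgdx.measure import detect_r_peaks, measure_record
from ecgdx.preprocess import (
    DatasetSplit,
    preprocess_record,
    resample_record,
    split_dataset,
    zero_pad_record,
)
from ecgdx.records import ECGRecord
from ecgdx.synthetic import (
    SyntheticRecordSpec,
    make_morphology,
    render_ecg,
    synthesize_record,
)


def _rec(n=3000, fs=300.0, **kw):
    rng = np.random.default_rng(1)
    return ECGRecord(signal=rng.normal(size=(n, 12)).astype(np.float32), fs=fs, **kw)


class TestContainer:
    def test_roundtrip(self, tmp_path, small_dataset):
        records, labels, _ = small_dataset
        h5, csv = str(tmp_path / "t.h5"), str(tmp_path / "l.csv")
        write_dataset(h5, csv, records[:5], labels[:5])
        back, sidecar = read_dataset(h5, csv)
        assert len(back) == 5
        for orig, rt in zip(records[:5], back):
            assert np.array_equal(orig.signal, rt.signal)
            assert rt.fs == orig.fs
        assert np.array_equal(labels_from_sidecar(sidecar), labels[:5])

    def test_wrong_lead_count_rejected(self, tmp_path):
        import h5py

        path = str(tmp_path / "bad.h5")
        with h5py.File(path, "w") as f:
            f.create_dataset("tracings", data=np.zeros((3, 100, 11), dtype=np.float32))
        with pytest.raises(FormatError):
            read_dataset(path)

    def test_sidecar_count_mismatch_rejected(self, tmp_path, small_dataset):
        records, labels, _ = small_dataset
        h5, csv = str(tmp_path / "t.h5"), str(tmp_path / "l.csv")
        write_dataset(h5, csv, records[:5], labels[:5])
        write_dataset(None, str(tmp_path / "short.csv"), records[:3], labels[:3])
        with pytest.raises(FormatError):
            read_dataset(h5, str(tmp_path / "short.csv"))


class TestResample:
    def test_identity_at_target_rate(self):
        rec = _rec(4000, 400.0)
        out = resample_record(rec, 400.0)
        assert out.n_samples == 4000 and out.fs == 400.0

    def test_length_scales_with_rate(self):
        out = resample_record(_rec(3000, 300.0), 400.0)
        assert out.n_samples == 4000
        assert out.fs == 400.0

    def test_band_limited_content_preserved(self):
        t = np.arange(6000) / 600.0
        sig = np.tile(np.sin(2 * np.pi * 5.0 * t)[:, None], (1, 12)).astype(np.float32)
        out = resample_record(ECGRecord(signal=sig, fs=600.0), 400.0)
        ref = np.sin(2 * np.pi * 5.0 * np.arange(out.n_samples) / 400.0)
        # ignore filter edge effects
        sl = slice(50, -50)
        c = np.corrcoef(out.signal[sl, 0], ref[sl])[0, 1]
        assert c > 0.999

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resample_record(_rec(), 0.0)


class TestZeroPad:
    def test_pad_to_4096(self):
        out = zero_pad_record(_rec(2800, 400.0))
        assert out.n_samples == 4096
        assert np.array_equal(out.signal[:2800], _rec(2800, 400.0).signal)
        assert np.all(out.signal[2800:] == 0)

    def test_identity_and_energy(self):
        rec = _rec(2800, 400.0)
        out = zero_pad_record(rec)
        assert np.sum(np.abs(out.signal)) == pytest.approx(np.sum(np.abs(rec.signal)), rel=1e-6)
        same = zero_pad_record(_rec(4096, 400.0))
        assert same.n_samples == 4096

    def test_symmetric_placement(self):
        out = zero_pad_record(_rec(2800, 400.0), placement="symmetric")
        assert np.all(out.signal[:648] == 0) and np.all(out.signal[-648:] == 0)

    def test_long_record_policy(self):
        with pytest.raises(ValueError):
            zero_pad_record(_rec(5000, 400.0))
        out = zero_pad_record(_rec(5000, 400.0), long_policy="center-crop")
        assert out.n_samples == 4096


class TestPreprocess:
    @pytest.mark.parametrize("fs,dur", [(300, 7.0), (400, 10.0), (600, 8.3)])
    def test_output_shape_fixed(self, fs, dur):
        rec = _rec(int(fs * dur), float(fs))
        out = preprocess_record(rec)
        assert out.signal.shape == (4096, 12)
        assert out.fs == 400.0

    def test_zero_in_zero_out_and_idempotence(self):
        rec = ECGRecord(signal=np.zeros((3000, 12), dtype=np.float32), fs=300.0)
        out = preprocess_record(rec)
        assert np.all(out.signal == 0)
        again = preprocess_record(out)
        assert np.array_equal(again.signal, out.signal)


class TestRPeaks:
    def test_sinus_peak_count_and_spacing(self):
        morph = make_morphology()
        r_times = 0.5 + np.arange(10) * 1.0
        sig = render_ecg(morph, r_times, 10.0, 400.0)
        rec = ECGRecord(signal=sig, fs=400.0)
        peaks = detect_r_peaks(rec)
        assert 9 <= len(peaks) <= 11
        gaps = np.diff(peaks)
        assert np.all(np.abs(gaps - 400) <= 2)

    def test_flat_signal_empty(self):
        rec = ECGRecord(signal=np.zeros((2000, 12), dtype=np.float32), fs=400.0)
        assert len(detect_r_peaks(rec)) == 0

    def test_offset_invariance(self):
        morph = make_morphology()
        sig = render_ecg(morph, 0.5 + np.arange(8) * 1.0, 9.0, 400.0)
        p1 = detect_r_peaks(ECGRecord(signal=sig, fs=400.0))
        p2 = detect_r_peaks(ECGRecord(signal=sig + 0.7, fs=400.0))
        assert np.array_equal(p1, p2)


class TestMeasure:
    def test_constant_rr_gives_exact_rate_and_zero_sdnn(self):
        morph = make_morphology()
        sig = render_ecg(morph, 0.5 + np.arange(9) * 1.0, 10.0, 400.0)
        m = measure_record(ECGRecord(signal=sig, fs=400.0))
        assert m.heart_rate == pytest.approx(60.0, abs=0.1)
        assert m.sdnn == pytest.approx(0.0, abs=2.0)

    def test_rate_from_prescribed_rr(self):
        # RR = 0.8, 0.85, 0.75 s -> mean 0.8 s -> 75 bpm
        morph = make_morphology()
        r_times = 0.5 + np.r_[0.0, np.cumsum([0.8, 0.85, 0.75, 0.8, 0.85, 0.75])]
        sig = render_ecg(morph, r_times, 6.5, 400.0)
        m = measure_record(ECGRecord(signal=sig, fs=400.0))
        assert m.heart_rate == pytest.approx(75.0, abs=0.5)

    def test_too_few_beats_flagged_missing(self):
        morph = make_morphology()
        sig = render_ecg(morph, np.array([1.5]), 3.0, 400.0)
        m = measure_record(ECGRecord(signal=sig, fs=400.0))
        assert m.n_beats <= 1
        assert np.isnan(m.heart_rate) and np.isnan(m.sdnn)

    def test_prolonged_pr_recovered(self):
        spec = SyntheticRecordSpec(labels={"1dAVb": True}, seed=2,
                                   noise_sd=0.0, baseline_amp=0.0)
        rec, _, truth = synthesize_record(spec)
        m = measure_record(rec)
        assert m.pr_interval == pytest.approx(truth.pr_interval, abs=10.0)


class TestSplits:
    def _records(self, n, n_patients=None, dated=True):
        out = []
        for i in range(n):
            pid = f"p{i % (n_patients or n)}"
            out.append(ECGRecord(
                signal=np.zeros((100, 12), dtype=np.float32), fs=400.0,
                exam_id=f"e{i}", patient_id=pid,
                acquisition_date=f"2015-{1 + i % 12:02d}-{1 + i % 28:02d}" if dated else None,
            ))
        return out

    def test_random_split_sizes(self):
        tr, va, te = split_dataset(self._records(100), DatasetSplit("random"))
        assert (len(tr), len(va), len(te)) == (90, 5, 5)
        assert len(set(tr) | set(va) | set(te)) == 100

    def test_by_patient_never_splits_a_patient(self):
        recs = self._records(40, n_patients=8)
        tr, va, te = split_dataset(recs, DatasetSplit("by_patient", (0.5, 0.25, 0.25), seed=1))
        parts = [set(recs[i].patient_id for i in idx) for idx in (tr, va, te)]
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) and not (parts[1] & parts[2])

    def test_single_patient_stays_together(self):
        recs = self._records(10, n_patients=1)
        tr, va, te = split_dataset(recs, DatasetSplit("by_patient"))
        assert sorted(len(p) for p in (tr, va, te)) == [0, 0, 10]

    def test_chronological_ordering(self):
        recs = self._records(60)
        tr, va, te = split_dataset(recs, DatasetSplit("chronological"))
        d = lambda idx: [recs[i].acquisition_date for i in idx]
        assert max(d(tr)) <= min(d(va)) and max(d(va)) <= min(d(te))

    def test_determinism_and_missing_metadata(self):
        recs = self._records(30)
        a = split_dataset(recs, DatasetSplit("random", seed=3))
        b = split_dataset(recs, DatasetSplit("random", seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        undated = self._records(10, dated=False)
        with pytest.raises(ValueError, match="acquisition_date"):
            split_dataset(undated, DatasetSplit("chronological"))
        for r in undated:
            r.patient_id = ""
        with pytest.raises(ValueError, match="patient_id"):
            split_dataset(undated, DatasetSplit("by_patient"))
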