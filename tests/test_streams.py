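"""Rate unification, stream composition and subject-wise splitting."""

import numpy as np
import pytest

from melstage.mfcc import MfccParams
from melstage.recording import Channel, Recording
from melstage.staging import Hypnogram
from melstage.streams import (
    FeatureStream,
    StreamConfig,
    build_streams,
    compute_epoch_features,
    load_streams,
    save_streams,
    split_subjects,
    streams_from_recording,
    unify_rates,
)


def two_rate_recording(duration_s=90.0, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(
        channels=[
            Channel("C3A2", rng.standard_normal(int(128 * duration_s)), 128.0),
            Channel("EMG", rng.standard_normal(int(64 * duration_s)), 64.0),
        ],
        subject_id="U01",
    )


class TestUnifyRates:
    def test_channel_at_target_returned_sample_identical(self):
        rec = two_rate_recording()
        out = unify_rates(rec)
        assert out.get_channel("C3A2").samples is rec.get_channel("C3A2").samples

    def test_upsampled_emg_length(self):
        out = unify_rates(two_rate_recording(duration_s=90.0))
        assert len(out.get_channel("EMG").samples) == 90 * 128  # 11520

    def test_sine_peak_survives_resampling(self):
        t = np.arange(64 * 30) / 64.0
        rec = Recording(
            channels=[
                Channel("C3A2", np.zeros(128 * 30), 128.0),
                Channel("EMG", np.sin(2 * np.pi * 5.0 * t), 64.0),
            ]
        )
        out = unify_rates(rec)
        y = out.get_channel("EMG").samples
        freqs = np.fft.rfftfreq(len(y), 1 / 128.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert abs(peak - 5.0) < freqs[1]  # within one bin


class TestBuildStreams:
    def epoch_feats(self, n_epochs, n_frames=119, L=13, channels=("C3A2", "C4A1", "EMG")):
        rng = np.random.default_rng(1)
        return [
            {ch: rng.standard_normal((n_frames, L)) for ch in channels}
            for _ in range(n_epochs)
        ]

    def test_default_tensor_shape(self):
        feats = self.epoch_feats(5)
        labels = ["W", "S1", "S2", "S3", "REM"]
        streams = build_streams(feats, labels)
        assert len(streams) == 5
        assert all(s.tensor.shape == (39, 357) for s in streams)  # 13*3 x 119*3

    def test_single_epoch_context_is_stacked_map(self):
        feats = self.epoch_feats(3)
        streams = build_streams(feats, ["W", "S2", "W"], StreamConfig(context_epochs=1))
        k = 1
        expected = np.vstack([feats[k][ch].T for ch in feats[k]])
        np.testing.assert_allclose(streams[k].tensor, expected, atol=1e-6)

    def test_boundary_replication_keeps_count_and_duplicates_edges(self):
        feats = self.epoch_feats(4)
        labels = ["W", "S1", "S2", "S3"]
        streams = build_streams(feats, labels)
        assert len(streams) == len(labels)
        first = streams[0].tensor
        w = first.shape[1] // 3
        np.testing.assert_array_equal(first[:, :w], first[:, w : 2 * w])  # epoch 0 duplicated

    def test_drop_boundary_policy(self):
        feats = self.epoch_feats(4)
        streams = build_streams(feats, ["W", "S1", "S2", "S3"], StreamConfig(boundary="drop"))
        assert [s.epoch_index for s in streams] == [1, 2]

    def test_composition_never_relabels(self):
        labels = ["W", "S2", "S2", None, "REM", "S3"]
        feats = self.epoch_feats(len(labels))
        streams = build_streams(feats, labels)
        got = [s.label for s in streams]
        assert got == [l for l in labels if l is not None]

    def test_inconsistent_shapes_rejected(self):
        feats = self.epoch_feats(2)
        feats[1]["EMG"] = feats[1]["EMG"][:, :7]
        with pytest.raises(ValueError, match="inconsistent"):
            build_streams(feats, ["W", "S2"])

    def test_even_context_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            StreamConfig(context_epochs=2)

    def test_standardize_option(self):
        feats = self.epoch_feats(3)
        streams = build_streams(feats, ["W", "S2", "W"], StreamConfig(standardize=True))
        for s in streams:
            assert abs(float(s.tensor.mean())) < 1e-5
            assert abs(float(s.tensor.std()) - 1.0) < 1e-4


class TestEndToEndComposition:
    def test_stream_count_equals_hypnogram_length(self, small_cohort):
        rec, hyp = small_cohort[0]
        streams = streams_from_recording(rec, hyp)
        assert len(streams) == len(hyp)
        assert all(s.tensor.shape == (39, 357) for s in streams)
        assert all(s.subject_id == rec.subject_id for s in streams)

    def test_per_class_counts_preserved(self, small_cohort):
        rec, hyp = small_cohort[1]
        streams = streams_from_recording(rec, hyp)
        from collections import Counter

        assert Counter(s.label for s in streams) == {
            k: v for k, v in hyp.class_counts().items() if v > 0
        }

    def test_deterministic_and_order_stable(self, small_cohort):
        rec, hyp = small_cohort[0]
        a = streams_from_recording(rec, hyp)
        b = streams_from_recording(rec, hyp)
        assert [s.epoch_index for s in a] == [s.epoch_index for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.tensor, sb.tensor)

    def test_epoch_feature_shapes_uniform(self, small_cohort):
        rec, hyp = small_cohort[0]
        feats, labels, idx = compute_epoch_features(rec, hyp, MfccParams())
        shapes = {m.shape for f in feats for m in f.values()}
        assert shapes == {(119, 13)}


def _fake_streams(n_subjects, per_subject=4):
    rng = np.random.default_rng(0)
    out = []
    for i in range(n_subjects):
        for k in range(per_subject):
            out.append(
                FeatureStream(
                    tensor=rng.standard_normal((3, 4)).astype(np.float32),
                    label="S2",
                    subject_id=f"P{i:02d}",
                    epoch_index=k,
                )
            )
    return out


class TestSplitSubjects:
    def test_ten_subjects_split_7_2_1(self):
        tr, va, te = split_subjects(_fake_streams(10), seed=3)
        count = lambda part: len({s.subject_id for s in part})
        assert (count(tr), count(va), count(te)) == (7, 2, 1)

    def test_deterministic_given_seed(self):
        streams = _fake_streams(8)
        a = split_subjects(streams, seed=11)
        b = split_subjects(streams, seed=11)
        for pa, pb in zip(a, b):
            assert [s.subject_id for s in pa] == [s.subject_id for s in pb]

    def test_no_subject_leaks_across_partitions(self):
        tr, va, te = split_subjects(_fake_streams(9), seed=5)
        sets = [{s.subject_id for s in part} for part in (tr, va, te)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert len(tr) + len(va) + len(te) == 9 * 4

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            split_subjects(_fake_streams(2))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_subjects(_fake_streams(5), fractions=(0.5, 0.2, 0.1))


def test_mfcc_map_csv_export(tmp_path, rng):
    from melstage.mfcc import extract_mfcc

    m = extract_mfcc(rng.standard_normal(2 * 128), 128.0)
    p = tmp_path / "map.csv"
    m.to_csv(p)
    lines = p.read_text().splitlines()
    assert lines[0] == "time_s," + ",".join(f"C{n}" for n in range(1, 14))
    assert len(lines) == 1 + m.coeffs.shape[0]


def test_save_load_round_trip(tmp_path):
    streams = _fake_streams(2)
    p = tmp_path / "streams.h5"
    save_streams(p, streams, attrs={"window": 0.5})
    back, attrs = load_streams(p)
    assert attrs["window"] == 0.5
    assert len(back) == len(streams)
    for a, b in zip(streams, back):
        assert np.array_equal(a.tensor, b.tensor)
        assert (a.label, a.subject_id, a.epoch_index) == (b.label, b.subject_id, b.epoch_index)
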