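"""Window segmentation, Std and ApEn features, and their invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seatsense as ss
from seatsense.features import DEFAULT_PURITY

from _oracles import naive_apen


class TestSegment:
    def test_default_window_arithmetic(self):
        cfg = ss.WindowConfig()  # tw=30 s, overlap 0.5, fs=10
        assert cfg.n_samples == 300
        assert cfg.stride == 150

    def test_19_windows_in_3000_samples(self):
        windows = ss.segment(3000, ss.WindowConfig())
        assert len(windows) == 19  # floor((3000-300)/150) + 1
        assert windows[0] == (0, 300)
        assert windows[-1] == (2700, 3000)

    def test_exact_fit_yields_one_window(self):
        assert ss.segment(300, ss.WindowConfig()) == [(0, 300)]

    def test_too_short_yields_none(self):
        assert ss.segment(299, ss.WindowConfig()) == []

    @settings(deadline=None, max_examples=50)
    @given(
        length=st.integers(4, 5000),
        tw=st.floats(0.5, 60.0),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_segment_structure(self, length, tw, overlap):
        """Equal-length ordered windows, consecutive starts exactly stride apart."""
        try:
            cfg = ss.WindowConfig(tw=tw, overlap=overlap, fs=10.0)
        except ss.ValidationError:
            return  # fewer than 4 samples per window: rejected by the config
        windows = ss.segment(length, cfg)
        assert all(e - s == cfg.n_samples for s, e in windows)
        assert all(e <= length for _, e in windows)
        starts = [s for s, _ in windows]
        assert all(b - a == cfg.stride for a, b in zip(starts, starts[1:]))
        expected = (
            0 if length < cfg.n_samples
            else (length - cfg.n_samples) // cfg.stride + 1
        )
        assert len(windows) == expected


class TestStdFeature:
    def test_constant_window_has_zero_std(self):
        assert ss.std_feature(np.full(10, 3.7)) == 0.0

    def test_two_point_window_closed_form(self):
        assert ss.std_feature(np.array([0.0, 2.0])) == pytest.approx(math.sqrt(2))

    def test_permutation_invariance(self):
        x = np.array([1.0, -1.0] * 5)
        rng = np.random.default_rng(0)
        assert ss.std_feature(rng.permutation(x)) == ss.std_feature(x)

    def test_single_sample_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.std_feature(np.array([1.0]))


class TestApEn:
    def test_constant_window_returns_zero(self):
        assert ss.apen(np.full(50, 2.5)) == 0.0

    @pytest.mark.parametrize("n", [50, 100, 300])
    def test_matches_naive_oracle(self, n):
        """Vectorised ApEn equals the triple-loop reference to 1e-10."""
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.standard_normal(n)
            assert ss.apen(x) == pytest.approx(naive_apen(x), abs=1e-10)

    def test_sinusoid_below_noise(self):
        """A periodic signal is more regular than iid noise of equal sd."""
        n = 300
        rng = np.random.default_rng(1)
        t = np.arange(n) / 10.0
        sine = np.sin(2 * np.pi * 0.4 * t)
        noise = rng.standard_normal(n) * sine.std(ddof=1)
        assert ss.apen(sine) < ss.apen(noise)

    def test_shuffling_increases_apen(self):
        """Shuffling a repetitive series destroys structure at equal sd."""
        n = 300
        t = np.arange(n) / 10.0
        sine = np.sin(2 * np.pi * 0.4 * t)
        rng = np.random.default_rng(2)
        assert ss.apen(sine) < ss.apen(rng.permutation(sine))

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, scale, offset, flip):
        """ApEn(a*x + b) = ApEn(x): r scales with sd, distances scale alike."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(80)
        a = -scale if flip else scale
        assert ss.apen(a * x + offset) == pytest.approx(ss.apen(x), abs=1e-10)

    def test_window_too_short_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.apen(np.array([1.0, 2.0, 3.0]), ss.ApEnParams(m=2))


def labelled_stream(n: int, label: str = "reading", fs: float = 10.0):
    rng = np.random.default_rng(11)
    return ss.RawStream(
        t=np.arange(n) / fs,
        fsr=rng.uniform(1.0, 5.0, size=(n, 6)),
        gyro_x=rng.normal(size=n),
        gyro_y=rng.normal(size=n),
        fs=fs,
        label=np.array([label] * n, dtype=object),
        subject="S1",
    )


class TestExtractFeatures:
    def test_composition_19_rows_8_features(self):
        stream = labelled_stream(3000)
        rows = ss.extract_features(stream, ss.compute_cop(stream), sets="both")
        assert len(rows) == 19
        assert all(len(r.features) == 8 for r in rows)
        assert all(r.activity == ss.Activity.READING for r in rows)
        assert all(r.level == "light" for r in rows)

    def test_std_only_has_4_features(self):
        stream = labelled_stream(600)
        rows = ss.extract_features(stream, ss.compute_cop(stream), sets="std")
        assert all(sorted(r.features) == ["std_cx", "std_cy", "std_gx", "std_gy"]
                   for r in rows)

    def test_unoccupied_gap_drops_only_that_window(self):
        stream = labelled_stream(600)  # windows [0,300) and [150,450) and [300,600)
        stream.fsr[310:320] = 0.0  # gap inside the 2nd and 3rd windows
        rows = ss.extract_features(stream, ss.compute_cop(stream), sets="std")
        assert len(rows) == 1
        assert rows[0].window_start_s == 0.0

    def test_mixed_label_window_dropped(self):
        stream = labelled_stream(600)
        half = np.array(["reading"] * 300 + ["swing"] * 300, dtype=object)
        stream.label = half
        rows = ss.extract_features(stream, ss.compute_cop(stream), sets="std")
        # middle window [150,450) is a 50/50 mix, below the purity threshold
        assert DEFAULT_PURITY > 0.5
        starts = [r.window_start_s for r in rows]
        assert starts == [0.0, 30.0]
        assert [r.activity.value for r in rows] == ["reading", "swing"]

    def test_feature_frame_columns(self):
        stream = labelled_stream(300)
        rows = ss.extract_features(stream, ss.compute_cop(stream), sets="both")
        frame = ss.feature_frame(rows)
        assert list(frame.columns) == [
            "std_cx", "std_cy", "std_gx", "std_gy",
            "apen_cx", "apen_cy", "apen_gx", "apen_gy",
            "activity", "level", "subject", "window_start_s",
        ]
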