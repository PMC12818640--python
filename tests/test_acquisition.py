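import numpy as np
import pytest

from rppgkit.acquisition import (
    BrightPatchDetector,
    CLAHEParams,
    FrameSequence,
    RawTrace,
    ROIGeometry,
    StubFaceDetector,
    clip_box,
    detect_face,
    enhance_for_detection,
    extract_trace,
    layout_rois,
    spatial_average,
)
from rppgkit.errors import DegenerateROIError, ExtractionError, InputError
from rppgkit.synthetic import SyntheticSpec, generate_video


def make_frame(value=0.5, size=(64, 64)):
    return np.full((*size, 3), value, dtype=float)


class TestDetectFace:
    def test_stub_pass_through(self):
        box = (10, 12, 20, 20)
        assert detect_face(make_frame(), StubFaceDetector(box)) == box

    def test_blank_frame_no_detection(self):
        assert detect_face(make_frame(0.3), BrightPatchDetector()) is None

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((-5, -5, 20, 20), (0, 0, 15, 15)),   # clipped at origin
            ((55, 55, 20, 20), (55, 55, 9, 9)),    # clipped at far edge
            ((10, 10, 10, 10), (10, 10, 10, 10)),  # fully inside
        ],
    )
    def test_box_clipped_to_frame(self, raw, expected):
        # oracle: interval intersection with [0, 64) on each axis
        assert detect_face(make_frame(), StubFaceDetector(raw)) == expected

    def test_fully_outside_box_becomes_absent(self):
        assert detect_face(make_frame(), StubFaceDetector((100, 100, 5, 5))) is None

    def test_invalid_frame_shape_rejected(self):
        with pytest.raises(InputError):
            detect_face(np.zeros((4, 4, 7)), StubFaceDetector((0, 0, 2, 2)))

    def test_bright_patch_detector_finds_embedded_face(self):
        frame = make_frame(0.1)
        frame[20:44, 16:48, :] = 0.7
        box = detect_face(frame, BrightPatchDetector())
        assert box == (16, 20, 32, 24)


class TestEnhance:
    def test_uniform_frame_stays_uniform(self):
        out = enhance_for_detection(make_frame(0.5))
        assert float(out.std()) == 0.0

    def test_low_contrast_range_not_reduced(self):
        gradient = np.linspace(0.45, 0.55, 64)
        frame = np.repeat(np.tile(gradient, (64, 1))[..., None], 3, axis=-1)
        out = enhance_for_detection(frame)
        assert out.max() - out.min() >= 0.1 - 1e-9  # oracle: histogram range

    def test_output_within_valid_range(self, rng):
        frame = rng.random((40, 40, 3))
        out = enhance_for_detection(frame, CLAHEParams(clip_limit=2.0, tile_grid=(4, 4)))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestLayoutROIs:
    def test_default_geometry_containment(self):
        layout = layout_rois((0, 0, 100, 100))
        fx, fy, fw, fh = layout.face_box
        for name, (x, y, w, h) in layout.regions.items():
            assert x >= fx and y >= fy and x + w <= fx + fw and y + h <= fy + fh
        # forehead in the upper half, cheeks in the lower half
        assert layout.regions["forehead"][1] + layout.regions["forehead"][3] <= 50
        for cheek in ("left_cheek", "right_cheek"):
            assert layout.regions[cheek][1] >= 50

    def test_identity_tiling_k1(self):
        layout = layout_rois((0, 0, 100, 100), ROIGeometry(grid=1))
        for name, rect in layout.regions.items():
            assert layout.sub_rois[name] == [rect]

    def test_k2_tiles_partition_region(self):
        # oracle: exhaustive pixel membership — tiles disjoint, union == region
        layout = layout_rois((0, 0, 100, 100), ROIGeometry(forehead=(0.2, 0.6, 0.1, 0.5), grid=2))
        x, y, w, h = layout.regions["forehead"]
        assert (w, h) == (40, 40)
        cover = np.zeros((h, w), dtype=int)
        for (tx, ty, tw, th) in layout.sub_rois["forehead"]:
            assert (tw, th) == (20, 20)
            cover[ty - y : ty - y + th, tx - x : tx - x + tw] += 1
        assert np.all(cover == 1)

    def test_too_small_face_box_raises(self):
        with pytest.raises(DegenerateROIError):
            layout_rois((0, 0, 4, 4), ROIGeometry(grid=2))

    def test_zero_area_face_box_raises(self):
        with pytest.raises(DegenerateROIError):
            layout_rois((5, 5, 0, 10))


class TestSpatialAverage:
    def test_uniform_field(self):
        layout = layout_rois((0, 0, 60, 60))
        mean, n = spatial_average(make_frame(0.5), layout, "g")
        assert mean == pytest.approx(0.5)
        assert n > 0

    def test_small_patch_arithmetic_mean(self):
        frame = np.zeros((4, 4, 3))
        frame[0:2, 0:2, 1] = [[10, 20], [30, 40]]
        layout = layout_rois((0, 0, 4, 4), ROIGeometry(forehead=(0.0, 0.5, 0.0, 0.5),
                                                       left_cheek=(0.0, 0.25, 0.5, 1.0),
                                                       right_cheek=(0.5, 0.75, 0.5, 1.0),
                                                       grid=1))
        # restrict to the forehead tile only
        layout.sub_rois = {"forehead": layout.sub_rois["forehead"]}
        mean, n = spatial_average(frame, layout, "g")
        assert mean == pytest.approx(25.0)
        assert n == 4

    def test_matches_double_loop_oracle(self, rng):
        frame = rng.random((32, 32, 3))
        layout = layout_rois((4, 4, 24, 24))
        for channel, ci in (("r", 0), ("g", 1), ("b", 2)):
            mean, n = spatial_average(frame, layout, channel)
            total, count = 0.0, 0
            for (x, y, w, h) in layout.all_tiles():
                for i in range(y, y + h):
                    for j in range(x, x + w):
                        total += frame[i, j, ci]
                        count += 1
            assert mean == pytest.approx(total / count, abs=1e-12)
            assert n == count

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_invariant_to_tiling_granularity(self, rng, k):
        frame = rng.random((64, 64, 3))
        base = layout_rois((8, 8, 48, 48), ROIGeometry(grid=1))
        tiled = layout_rois((8, 8, 48, 48), ROIGeometry(grid=k))
        m0, _ = spatial_average(frame, base, "g")
        mk, _ = spatial_average(frame, tiled, "g")
        assert mk == pytest.approx(m0, abs=1e-12)

    def test_tile_outside_frame_raises(self):
        layout = layout_rois((0, 0, 60, 60))
        with pytest.raises(DegenerateROIError):
            spatial_average(np.zeros((20, 20, 3)), layout, "g")


class TestExtractTrace:
    def _sequence(self, values, size=(64, 64)):
        frames = np.stack([make_frame(v, size) for v in values]).astype(float)
        return FrameSequence(frames=frames, fps=30.0)

    def test_constant_skin_value(self):
        seq = self._sequence([0.42] * 30)
        trace = extract_trace(seq, StubFaceDetector((8, 8, 48, 48)))
        assert np.allclose(trace.channel("g"), 0.42)
        assert not trace.flagged.any()

    def test_recovers_injected_sinusoid(self):
        t = np.arange(90) / 30.0
        values = 0.5 + 0.1 * np.sin(2 * np.pi * 1.2 * t)
        seq = self._sequence(values)
        trace = extract_trace(seq, StubFaceDetector((8, 8, 48, 48)))
        assert np.allclose(trace.channel("g"), values, atol=1e-12)

    def test_detection_failure_carries_forward_and_flags(self):
        class Flaky:
            def __call__(self, frame):
                # fails exactly on frames 10-12 (detector called per frame)
                self.calls = getattr(self, "calls", -1) + 1
                return None if self.calls in (10, 11, 12) else (8, 8, 48, 48)

        seq = self._sequence([0.4] * 30)
        trace = extract_trace(seq, Flaky(), redetect_every=1)
        assert len(trace) == 30
        assert np.isfinite(trace.channel("g")).all()
        assert list(np.where(trace.flagged)[0]) == [10, 11, 12]

    def test_no_face_ever_raises(self):
        seq = self._sequence([0.4] * 10)
        with pytest.raises(ExtractionError):
            extract_trace(seq, StubFaceDetector(None))

    def test_enhancement_never_alters_trace_values(self):
        vals = 0.5 + 0.05 * np.sin(np.arange(60))
        seq = self._sequence(list(vals))
        det = StubFaceDetector((8, 8, 48, 48))
        t_plain = extract_trace(seq, det, enhance=False)
        t_enh = extract_trace(seq, det, enhance=True)
        assert np.array_equal(t_plain.channel("g"), t_enh.channel("g"))

    def test_roundtrip_on_synthetic_video(self):
        spec = SyntheticSpec(duration=10.0, noise_sigma=0.0, drift_amplitude=0.0, seed=4)
        seq, box, _ = generate_video(spec, (64, 64))
        trace = extract_trace(seq, BrightPatchDetector())
        from rppgkit.synthetic import generate_trace

        ref, _ = generate_trace(spec)
        r = np.corrcoef(trace.channel("g"), ref.channel("g"))[0, 1]
        assert r > 0.99


class TestRawTraceIO:
    def test_csv_roundtrip(self, tmp_path, noisy_trace):
        trace, _ = noisy_trace
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = RawTrace.from_csv(path)
        assert np.allclose(back.channel("g"), trace.channel("g"))
        assert back.fps == pytest.approx(trace.fps, rel=1e-6)

    def test_frame_sequence_validates_timing(self):
        frames = np.zeros((5, 8, 8, 3))
        with pytest.raises(InputError):
            FrameSequence(frames=frames, fps=30.0, timestamps=np.array([0, 1, 2, 3, 4.0]))
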