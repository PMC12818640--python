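"""Video-to-trace acquisition: face detection, ROI geometry, spatial averaging.

The raw rPPG signal is the per-frame spatial mean of pixel intensities over a
set of facial regions of interest (forehead and both cheeks), computed
independently for each colour channel:

    g(t) = (1/N) * sum_{(i,j) in ROI} I_c(i, j, t)

Each region is tiled into k x k sub-ROIs to limit the influence of uneven
illumination; because the mean over the union of disjoint tiles equals the
pixel-count-weighted mean of tile means, tiling does not change g(t) itself
but gives downstream code per-tile diagnostics.

Face detection is a pluggable interface: any callable mapping a frame to a
``(x, y, w, h)`` box (or ``None``) works. :class:`BrightPatchDetector` is a
simple default suited to the synthetic videos produced by
:mod:`rppgkit.synthetic`; production use would plug in a cascade or DNN
detector. Contrast enhancement (CLAHE) is applied only to a grayscale copy
used for detection — the RGB values entering the spatial average are never
modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, ExtractionError, InputError

Rect = tuple[int, int, int, int]  # (x, y, w, h), 0-based, half-open


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """An ordered stack of H x W x 3 frames with timing metadata."""

    frames: np.ndarray  # (T, H, W, 3), uint8 or float
    fps: float
    timestamps: np.ndarray = None  # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise InputError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if not self.fps > 0:
            raise InputError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise InputError("len(timestamps) != len(frames)")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise InputError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fps) > 0.1 / self.fps):
                raise InputError("inter-frame spacing deviates from 1/fps by more than 10%")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ROIGeometry:
    """Fractional placement of the forehead/cheek regions within a face box.

    Fractions are (x0, x1, y0, y1) relative to the face box. Defaults put the
    forehead in the upper central band and the cheeks in the lower lateral
    part of the face. ``grid`` is the k of the k x k sub-ROI tiling.
    """

    forehead: tuple[float, float, float, float] = (0.20, 0.80, 0.05, 0.25)
    left_cheek: tuple[float, float, float, float] = (0.15, 0.45, 0.55, 0.80)
    right_cheek: tuple[float, float, float, float] = (0.55, 0.85, 0.55, 0.80)
    grid: int = 2


@dataclass
class ROILayout:
    """Named facial regions and their sub-ROI tiles, in absolute pixel coords."""

    face_box: Rect
    regions: dict[str, Rect]
    sub_rois: dict[str, list[Rect]]
    source_frame_index: int = 0

    def all_tiles(self) -> list[Rect]:
        return [t for tiles in self.sub_rois.values() for t in tiles]


@dataclass
class RawTrace:
    """Per-frame spatially averaged channel intensities.

    ``channels`` maps 'r'/'g'/'b' to same-length series of ROI means;
    ``n_pixels_used`` records N of the spatial average; ``flagged`` marks
    frames where face detection failed and the previous layout was reused.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    fps: float
    n_pixels_used: np.ndarray = None
    flagged: np.ndarray = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {c: np.asarray(v, dtype=float) for c, v in self.channels.items()}
        n = len(self.time)
        for c, v in self.channels.items():
            if len(v) != n:
                raise InputError(f"channel {c!r} length {len(v)} != {n}")
            if not np.all(np.isfinite(v)):
                raise InputError(f"channel {c!r} contains non-finite values")
        if self.n_pixels_used is None:
            self.n_pixels_used = np.zeros(n, dtype=int)
        if self.flagged is None:
            self.flagged = np.zeros(n, dtype=bool)
        self.n_pixels_used = np.asarray(self.n_pixels_used, dtype=int)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return len(self.time)

    def channel(self, name: str = "g") -> np.ndarray:
        return self.channels[name]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "r": self.channels["r"],
                "g": self.channels["g"],
                "b": self.channels["b"],
                "n_pixels": self.n_pixels_used,
                "flagged": self.flagged.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RawTrace":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        tcol = cols.get("time_s", cols.get("time"))
        if tcol is None or not {"r", "g", "b"} <= set(cols):
            raise InputError("trace CSV needs columns time(_s), r, g, b")
        t = df[tcol].to_numpy(dtype=float)
        if len(t) < 2:
            raise InputError("trace CSV too short")
        fps = 1.0 / float(np.median(np.diff(t)))
        return cls(
            time=t,
            channels={c: df[cols[c]].to_numpy(dtype=float) for c in "rgb"},
            fps=fps,
            n_pixels_used=df[cols["n_pixels"]].to_numpy() if "n_pixels" in cols else None,
            flagged=df[cols["flagged"]].to_numpy(dtype=bool) if "flagged" in cols else None,
        )


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

FaceDetector = Callable[[np.ndarray], Optional[Rect]]


class StubFaceDetector:
    """Detector returning a fixed box; used when the face location is known."""

    def __init__(self, box: Optional[Rect]):
        self.box = None if box is None else tuple(int(v) for v in box)

    def __call__(self, frame: np.ndarray) -> Optional[Rect]:
        return self.box


class BrightPatchDetector:
    """Detect the largest bright connected component above a threshold.

    Suited to synthetic frames where the skin patch is brighter than the
    background. Real deployments should plug in a trained face detector via
    the same callable interface.
    """

    def __init__(self, threshold: Optional[float] = None, min_area: int = 16):
        self.threshold = threshold
        self.min_area = min_area

    def __call__(self, frame: np.ndarray) -> Optional[Rect]:
        from skimage.measure import label, regionprops

        gray = _to_gray(frame)
        thr = self.threshold
        if thr is None:
            lo, hi = float(gray.min()), float(gray.max())
            if hi - lo < 1e-12:
                return None
            thr = 0.5 * (lo + hi)
        mask = gray > thr
        if not mask.any():
            return None
        labels = label(mask)
        best = max(regionprops(labels), key=lambda r: r.area)
        if best.area < self.min_area:
            return None
        r0, c0, r1, c1 = best.bbox
        return (int(c0), int(r0), int(c1 - c0), int(r1 - r0))


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        g = frame.astype(float)
    elif frame.ndim == 3 and frame.shape[-1] == 3:
        # ITU-R 601 luminance
        g = frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114
    else:
        raise InputError(f"frame must be HxW or HxWx3, got shape {frame.shape}")
    if np.issubdtype(frame.dtype, np.integer):
        g = g / 255.0
    return g.astype(float)


def clip_box(box: Rect, width: int, height: int) -> Optional[Rect]:
    """Intersect a (x, y, w, h) box with the frame rectangle."""
    x0, y0 = max(box[0], 0), max(box[1], 0)
    x1, y1 = min(box[0] + box[2], width), min(box[1] + box[3], height)
    if x1 <= x0 or y1 <= y0:
        return None
    return (x0, y0, x1 - x0, y1 - y0)


def detect_face(frame: np.ndarray, detector: FaceDetector) -> Optional[Rect]:
    """Run the detector and return the face box clipped to frame bounds."""
    frame = np.asarray(frame)
    if frame.ndim not in (2, 3) or (frame.ndim == 3 and frame.shape[-1] != 3):
        raise InputError(f"invalid frame shape {frame.shape}")
    box = detector(frame)
    if box is None:
        return None
    h, w = frame.shape[:2]
    return clip_box(tuple(int(v) for v in box), w, h)


@dataclass
class CLAHEParams:
    """OpenCV-convention CLAHE parameters (clip limit ~2.0, 8x8 tile grid)."""

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)


def enhance_for_detection(frame: np.ndarray, clahe_params: CLAHEParams | None = None) -> np.ndarray:
    """CLAHE-enhanced grayscale copy of a frame, for face detection only.

    The returned image never feeds the spatial average; it exists solely to
    make faces detectable under poor illumination. Output is float in [0, 1].
    """
    from skimage.exposure import equalize_adapthist

    params = clahe_params or CLAHEParams()
    gray = _to_gray(frame)
    if float(gray.max() - gray.min()) < 1e-12:
        return gray.copy()  # nothing to equalize
    ky = max(1, gray.shape[0] // params.tile_grid[0])
    kx = max(1, gray.shape[1] // params.tile_grid[1])
    clip = min(1.0, max(1e-3, params.clip_limit / 100.0))
    return equalize_adapthist(np.clip(gray, 0.0, 1.0), kernel_size=(ky, kx), clip_limit=clip)


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _frac_rect(face_box: Rect, frac: tuple[float, float, float, float]) -> Rect:
    fx, fy, fw, fh = face_box
    x0f, x1f, y0f, y1f = frac
    x0 = fx + int(round(x0f * fw))
    x1 = fx + int(round(x1f * fw))
    y0 = fy + int(round(y0f * fh))
    y1 = fy + int(round(y1f * fh))
    return (x0, y0, x1 - x0, y1 - y0)


def _tile_rect(rect: Rect, k: int) -> list[Rect]:
    x, y, w, h = rect
    xs = np.linspace(x, x + w, k + 1).round().astype(int)
    ys = np.linspace(y, y + h, k + 1).round().astype(int)
    return [
        (int(xs[i]), int(ys[j]), int(xs[i + 1] - xs[i]), int(ys[j + 1] - ys[j]))
        for j in range(k)
        for i in range(k)
    ]


def layout_rois(face_box: Rect, geometry: ROIGeometry | None = None, source_frame_index: int = 0) -> ROILayout:
    """Place forehead and cheek regions inside a face box and tile them k x k."""
    geometry = geometry or ROIGeometry()
    if face_box[2] <= 0 or face_box[3] <= 0:
        raise DegenerateROIError(f"face box has non-positive area: {face_box}")
    regions: dict[str, Rect] = {}
    sub_rois: dict[str, list[Rect]] = {}
    for name in ("forehead", "left_cheek", "right_cheek"):
        rect = _frac_rect(face_box, getattr(geometry, name))
        if rect[2] < geometry.grid or rect[3] < geometry.grid:
            raise DegenerateROIError(
                f"region {name!r} ({rect[2]}x{rect[3]} px) too small for {geometry.grid}x{geometry.grid} tiling"
            )
        regions[name] = rect
        sub_rois[name] = _tile_rect(rect, geometry.grid)
    return ROILayout(face_box=tuple(face_box), regions=regions, sub_rois=sub_rois, source_frame_index=source_frame_index)


_CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2}


def spatial_average(frame: np.ndarray, roi_layout: ROILayout, channel: str = "g") -> tuple[float, int]:
    """Mean intensity of one channel over the union of sub-ROI pixels.

    Returns ``(mean, N)``. Computed as the pixel-count-weighted average of
    per-tile means, which equals the flat mean over the pixel union because
    the tiles partition each region.
    """
    if channel not in _CHANNEL_INDEX:
        raise InputError(f"channel must be one of r/g/b, got {channel!r}")
    frame = np.asarray(frame)
    plane = frame[..., _CHANNEL_INDEX[channel]] if frame.ndim == 3 else frame
    h, w = plane.shape
    total, n = 0.0, 0
    for (x, y, tw, th) in roi_layout.all_tiles():
        if x < 0 or y < 0 or x + tw > w or y + th > h:
            raise DegenerateROIError(f"tile {(x, y, tw, th)} outside frame {w}x{h}")
        patch = plane[y : y + th, x : x + tw]
        total += float(patch.sum())
        n += patch.size
    if n == 0:
        raise DegenerateROIError("empty ROI pixel set")
    return total / n, n


def extract_trace(
    seq: FrameSequence,
    detector: FaceDetector,
    geometry: ROIGeometry | None = None,
    redetect_every: int = 30,
    clahe_params: CLAHEParams | None = None,
    enhance: bool = False,
) -> RawTrace:
    """Run detection + ROI averaging over a frame sequence.

    The face is (re-)detected every ``redetect_every`` frames on a CLAHE
    grayscale copy when ``enhance`` is set; between re-detections the layout
    is held fixed. Frames where detection fails reuse the last layout and are
    flagged. Raises :class:`ExtractionError` if no face is ever found.
    """
    if len(seq) == 0:
        raise ExtractionError("empty frame sequence")
    geometry = geometry or ROIGeometry()
    layout: Optional[ROILayout] = None
    values = {c: np.empty(len(seq)) for c in "rgb"}
    n_pix = np.zeros(len(seq), dtype=int)
    flagged = np.zeros(len(seq), dtype=bool)
    pending: list[int] = []  # frames before the first successful detection

    for i, frame in enumerate(seq.frames):
        if layout is None or i % redetect_every == 0:
            det_input = enhance_for_detection(frame, clahe_params) if enhance else frame
            box = detect_face(det_input, detector)
            if box is not None:
                layout = layout_rois(box, geometry, source_frame_index=i)
            elif layout is not None:
                flagged[i] = True
        if layout is None:
            pending.append(i)
            continue
        while pending:  # backfill leading undetected frames with first layout
            j = pending.pop()
            for c in "rgb":
                values[c][j], n_pix[j] = spatial_average(seq.frames[j], layout, c)
            flagged[j] = True
        for c in "rgb":
            values[c][i], n_pix[i] = spatial_average(frame, layout, c)

    if layout is None:
        raise ExtractionError("no face detected in any frame")
    return RawTrace(time=seq.timestamps.copy(), channels=values, fps=seq.fps, n_pixels_used=n_pix, flagged=flagged)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_frame_directory(path, fps: float, pattern: str = "*.png") -> FrameSequence:
    """Load a numbered image directory as a FrameSequence."""
    import imageio.v3 as iio

    files = sorted(Path(path).glob(pattern))
    if not files:
        raise InputError(f"no frames matching {pattern!r} under {path}")
    frames = np.stack([iio.imread(f) for f in files])
    if frames.ndim == 3:  # grayscale -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return FrameSequence(frames=frames[..., :3], fps=fps)


def read_video(path, fps: float | None = None) -> FrameSequence:
    """Load a video container via imageio (requires an ffmpeg-capable plugin)."""
    import imageio.v3 as iio

    frames = iio.imread(path)
    if fps is None:
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 30.0))
    return FrameSequence(frames=np.asarray(frames)[..., :3], fps=fps)


def read_pure_session(session_dir, fps: float = 30.0) -> tuple[FrameSequence, pd.DataFrame]:
    """Read a PURE-layout session: a PNG frame folder plus a JSON ground truth.

    The JSON's ``/FullPackage`` entries carry pulse-rate values with
    nanosecond timestamps; returned as a DataFrame with columns
    ``time_s`` (zeroed to the first frame) and ``hr_bpm``.
    """
    import json

    session_dir = Path(session_dir)
    json_files = sorted(session_dir.glob("*.json")) or sorted(session_dir.parent.glob(session_dir.name + "*.json"))
    if not json_files:
        raise InputError(f"no ground-truth JSON found for PURE session {session_dir}")
    with open(json_files[0]) as fh:
        payload = json.load(fh)
    entries = payload.get("/FullPackage", payload.get("FullPackage", []))
    t_ns = np.array([e["Timestamp"] for e in entries], dtype=float)
    hr = np.array([e["Value"]["pulseRate"] for e in entries], dtype=float)
    frame_dirs = [d for d in (session_dir, *sorted(p for p in session_dir.iterdir() if p.is_dir()))
                  if list(d.glob("*.png"))] if session_dir.is_dir() else []
    if not frame_dirs:
        raise InputError(f"no PNG frames under PURE session {session_dir}")
    seq = read_frame_directory(frame_dirs[0], fps=fps)
    t0 = t_ns[0] if len(t_ns) else 0.0
    gt = pd.DataFrame({"time_s": (t_ns - t0) / 1e9, "hr_bpm": hr})
    return seq, gt
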