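"""Frame-sequence pre-processing and blob/centroid skeleton modelling.

A median background model is subtracted from each frame, the residual
is thresholded and cleaned by a morphological opening, and the figure's
skeleton landmarks are recovered as blob centroids.  Blobs are defined
from the bright landmark markers: a single erosion removes the thin
limb strokes connecting them, leaving one connected component per
movable part.  Centroids are assigned to seven body-point categories
(head, shoulders, elbows, wrists, torso, knees, ankles) by their
normalized vertical position within the figure's bounding box, with a
left/right split about the vertical midline for the paired categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

CATEGORIES = ["head", "shoulders", "elbows", "wrists", "torso", "knees", "ankles"]
_PAIRED = {"shoulders", "elbows", "wrists", "knees", "ankles"}
_EXPECTED = {c: (1 if c in ("head", "torso") else 2) for c in CATEGORIES}

# category bands as fractions of the figure bounding-box height
BANDS = {
    "head": (0.0, 0.12),
    "shoulders": (0.12, 0.25),
    "elbows": (0.25, 0.40),
    "wrists": (0.40, 0.52),
    "torso": (0.25, 0.55),  # central column only
    "knees": (0.55, 0.78),
    "ankles": (0.78, 1.001),
}


@dataclass
class FrameSequence:
    frames: np.ndarray  # (T, H, W) grayscale or (T, H, W, 3)
    fps: float
    stride: int = 1

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def __len__(self) -> int:
        return len(self.frames)

    def gray(self) -> np.ndarray:
        if self.frames.ndim == 4:
            return self.frames.mean(axis=3)
        return self.frames.astype(float)


@dataclass
class SkeletonPoints:
    """Per-frame landmark estimates grouped by body-point category."""

    points: dict = field(default_factory=dict)  # category -> list[(row, col)]
    sides: dict = field(default_factory=dict)  # category -> list["l"|"r"|"c"]
    confidence: dict = field(default_factory=dict)  # category -> [0, 1]

    def total_points(self) -> int:
        return sum(len(v) for v in self.points.values())

    def mean_confidence(self) -> float:
        if not self.confidence:
            return 0.0
        return float(np.mean([self.confidence.get(c, 0.0) for c in CATEGORIES]))

    def get(self, category: str, side: str | None = None):
        pts = self.points.get(category, [])
        if side is None:
            return pts
        sides = self.sides.get(category, [])
        for p, s in zip(pts, sides):
            if s == side:
                return p
        return None


def sample_frames(seq: FrameSequence, delta: int) -> FrameSequence:
    """Keep every delta-th frame starting at index 0."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if len(seq) == 0:
        raise ValueError("empty frame sequence")
    return FrameSequence(
        frames=seq.frames[::delta].copy(),
        fps=seq.fps / delta,
        stride=seq.stride * delta,
    )


def background_model(seq: FrameSequence) -> np.ndarray:
    """Per-pixel median across frames; robust to a figure that occupies
    any given pixel in fewer than half the frames."""
    if len(seq) < 3:
        raise ValueError("need at least 3 frames for a background model")
    return np.median(seq.gray(), axis=0)


def denoise_frame(frame: np.ndarray, wavelet: str = "db2") -> np.ndarray:
    """Single-level 2-D DWT soft-threshold denoising."""
    frame = np.asarray(frame, dtype=float)
    cA, (cH, cV, cD) = pywt.dwt2(frame, wavelet, mode="symmetric")
    sigma = np.median(np.abs(cD)) / 0.6745 if cD.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(frame.size, 2)))
    if thr <= 0:
        return frame.copy()
    den = (cA, tuple(pywt.threshold(c, thr, mode="soft") for c in (cH, cV, cD)))
    out = pywt.idwt2(den, wavelet, mode="symmetric")
    return out[: frame.shape[0], : frame.shape[1]]


def subtract_background(
    frame: np.ndarray, bg: np.ndarray, thresh: float = 40.0
) -> np.ndarray:
    """Binary foreground mask |frame - bg| > thresh, followed by a 3x3
    morphological opening to remove speckle."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    bg = np.asarray(bg, dtype=float)
    if frame.shape != bg.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs bg {bg.shape}")
    mask = np.abs(frame - bg) > thresh
    return ndimage.binary_opening(mask, structure=np.ones((3, 3), bool))


def extract_skeleton(mask: np.ndarray, min_area: int = 1) -> SkeletonPoints:
    """Blob centroids assigned to the seven body-point categories.

    The mask is eroded once so that 1-px limb strokes disappear and the
    landmark markers separate into individual blobs; if erosion empties
    the mask the original components are used.  Degenerate masks yield
    an empty result with zero confidences rather than an error.
    """
    mask = np.asarray(mask, dtype=bool)
    out = SkeletonPoints(
        points={c: [] for c in CATEGORIES},
        sides={c: [] for c in CATEGORIES},
        confidence={c: 0.0 for c in CATEGORIES},
    )
    if not mask.any():
        return out
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    work = eroded if eroded.any() else mask
    labels = cc_label(work, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    if not props:
        return out
    centroids = np.array([p.centroid for p in props])  # (row, col)
    # figure bounding box from the full mask (limbs included)
    rows, cols = np.nonzero(mask)
    top, bottom = rows.min(), rows.max()
    left, right = cols.min(), cols.max()
    height = max(bottom - top, 1)
    mid_col = 0.5 * (left + right)
    width = max(right - left, 1)

    for r, c in centroids:
        yf = (r - top) / height
        central = abs(c - mid_col) <= 0.2 * width
        candidates = []
        for cat, (lo, hi) in BANDS.items():
            if lo <= yf < hi:
                if cat == "torso" and not central:
                    continue
                if cat in ("elbows", "wrists") and central:
                    continue  # central column inside these bands is torso
                candidates.append(cat)
        if not candidates:
            continue
        # nearest band center wins
        cat = min(candidates, key=lambda k: abs(yf - 0.5 * (BANDS[k][0] + BANDS[k][1])))
        side = "c" if cat in ("head", "torso") else ("l" if c < mid_col else "r")
        if cat in _PAIRED and side in out.sides[cat]:
            continue  # one point per side
        if len(out.points[cat]) >= _EXPECTED[cat]:
            continue
        out.points[cat].append((float(r), float(c)))
        out.sides[cat].append(side)
    for cat in CATEGORIES:
        out.confidence[cat] = len(out.points[cat]) / _EXPECTED[cat]
    return out


def skeleton_series(
    frames: np.ndarray, bg: np.ndarray | None = None, thresh: float = 40.0,
    denoise: bool = False,
) -> list[SkeletonPoints]:
    """Convenience: background-subtract and extract skeletons for every
    frame of a sequence array."""
    seq = FrameSequence(frames=frames, fps=1.0)
    gray = seq.gray()
    if bg is None:
        bg = np.median(gray, axis=0)
    out = []
    for f in gray:
        if denoise:
            f = denoise_frame(f)
        out.append(extract_skeleton(subtract_background(f, bg, thresh)))
    return out


def skeleton_to_frame(sk: SkeletonPoints) -> dict:
    """Flatten one SkeletonPoints into rows for CSV export."""
    rows = []
    for cat in CATEGORIES:
        for (r, c), side in zip(sk.points[cat], sk.sides[cat]):
            rows.append({"category": cat, "side": side, "row": r, "col": c,
                         "confidence": sk.confidence[cat]})
    return rows
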