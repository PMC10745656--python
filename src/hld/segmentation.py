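"""Windowing of motion/ambient streams and event-based vision segments.

Motion and ambient data are cut into fixed-length overlapped windows
(default 2 s with 50% overlap); each window carries the majority ground
-truth label over its span.  Vision data is segmented at change-points
of the smoothed inter-frame skeleton displacement: spans where the
figure is moving alternate with spans where it is still.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class Segment:
    modality: str  # motion | ambient | vision
    start_s: float
    end_s: float
    payload: object  # slice of the pre-processed stream
    label: str

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def majority_label(labels) -> str:
    """Most frequent label; ties broken toward the earliest occurring."""
    labels = list(labels)
    if not labels:
        return "none"
    counts = Counter(labels)
    best = max(counts.values())
    for lab in labels:  # first label reaching the max count wins
        if counts[lab] == best:
            return lab
    return "none"


def window(
    data: np.ndarray,
    sample_rate: float,
    W: float = 2.0,
    overlap: float = 0.5,
    labels: np.ndarray | None = None,
    modality: str = "motion",
    t0: float = 0.0,
) -> list[Segment]:
    """Fixed-length overlapped windows; the last partial window is dropped."""
    if W <= 0:
        raise ValueError("window length must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    data = np.asarray(data)
    n = len(data)
    win = int(round(W * sample_rate))
    hop = int(round(win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large for this window length")
    if win > n:
        log.info("stream shorter than one window (%d < %d); no segments", n, win)
        return []
    segments = []
    for start in range(0, n - win + 1, hop):
        sl = data[start : start + win]
        lab = (
            majority_label(labels[start : start + win])
            if labels is not None
            else "none"
        )
        segments.append(
            Segment(
                modality=modality,
                start_s=t0 + start / sample_rate,
                end_s=t0 + (start + win) / sample_rate,
                payload=sl,
                label=lab,
            )
        )
    return segments


def skeleton_displacement(skeletons) -> np.ndarray:
    """Mean displacement (px) of matching landmarks between consecutive
    frames; landmarks missing in either frame are skipped.

    Accepts either a list of ``SkeletonPoints`` or an array of shape
    (T, n_landmarks, 2) of ground-truth coordinates.
    """
    if isinstance(skeletons, np.ndarray):
        if len(skeletons) < 2:
            return np.zeros(0)
        d = np.linalg.norm(np.diff(skeletons, axis=0), axis=2)
        return d.mean(axis=1)
    disp = np.zeros(max(len(skeletons) - 1, 0))
    for i in range(len(skeletons) - 1):
        a, b = skeletons[i], skeletons[i + 1]
        dists = []
        for cat in a.points:
            for side in set(a.sides.get(cat, [])) & set(b.sides.get(cat, [])):
                pa, pb = a.get(cat, side), b.get(cat, side)
                if pa is not None and pb is not None:
                    dists.append(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))
        disp[i] = np.mean(dists) if dists else 0.0
    return disp


def event_segments(
    frame_times: np.ndarray,
    skeletons,
    threshold: float = 1.0,
    smooth: int = 5,
    frame_labels: np.ndarray | None = None,
) -> list[Segment]:
    """Event-based vision segments.

    The smoothed inter-frame skeleton displacement is compared with
    ``threshold`` (displacement >= threshold counts as motion); each
    maximal run of constant motion state becomes one segment.  Segments
    are disjoint and cover the whole sequence.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    T = len(frame_times)
    if T < 2:
        return []
    disp = skeleton_displacement(skeletons)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        disp = np.convolve(disp, kernel, mode="same")
    moving = disp >= threshold  # tie -> moving
    # state per frame: frame i inherits the state of transition i-1 -> i
    state = np.concatenate([[moving[0]], moving])
    segments = []
    run_start = 0
    dt = frame_times[1] - frame_times[0] if T > 1 else 1.0
    for i in range(1, T + 1):
        if i == T or state[i] != state[run_start]:
            t_start = frame_times[run_start]
            t_end = frame_times[i - 1] + dt if i == T else frame_times[i]
            lab = (
                majority_label(frame_labels[run_start:i])
                if frame_labels is not None
                else "none"
            )
            segments.append(
                Segment(
                    modality="vision",
                    start_s=float(t_start),
                    end_s=float(t_end),
                    payload=(run_start, i),
                    label=lab,
                )
            )
            run_start = i
    return segments
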