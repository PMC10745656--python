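"""Vision descriptors: thermal map, GGD saliency, skeleton orientation
angles, and spider local image features (SLIF).

* The thermal map accumulates absolute inter-frame differences; its
  scalar summary is the sum of log(1 + heat) over pixels, so a still
  scene scores exactly zero and the score is monotone in every pixel's
  accumulated motion.
* Saliency models multiscale band-pass responses with a generalized
  Gaussian distribution (GGD) per channel and scores each pixel by its
  negative log-likelihood: rare responses are salient.
* Orientation angles measure the interior angle at the middle joint of
  a fixed catalogue of skeleton triangles, via atan2(‖u×v‖, u·v).
* SLIF samples pixel intensities on a polar spiderweb of N spokes and
  M rings centered on each skeleton point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import gammaln

from .vision import SkeletonPoints


# ---------------------------------------------------------------- thermal

@dataclass
class ThermalMap:
    heat: np.ndarray  # (H, W) accumulated |frame difference|
    summary: float  # sum of log1p(heat)
    pooled: np.ndarray  # (8, 8) mean-pooled heat

    @property
    def vectorized(self) -> np.ndarray:
        return np.concatenate([[self.summary], self.pooled.ravel()])


def _mean_pool(img: np.ndarray, grid: int = 8) -> np.ndarray:
    H, W = img.shape
    grid = min(grid, H, W)  # tiny images: avoid empty pooling cells
    rows = np.array_split(np.arange(H), grid)
    cols = np.array_split(np.arange(W), grid)
    out = np.empty((grid, grid))
    for i, rs in enumerate(rows):
        for j, cs in enumerate(cols):
            out[i, j] = img[np.ix_(rs, cs)].mean()
    return out


def thermal_map(frames: np.ndarray, log_mode: str = "log1p") -> ThermalMap:
    """Accumulated per-pixel absolute difference over consecutive frames.

    ``log_mode='log1p'`` (default) sums ln(1 + heat); ``'as_printed_ln'``
    sums ln(heat) over strictly positive heat values only.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:
        frames = frames.mean(axis=3)
    if len(frames) < 2:
        raise ValueError("thermal map needs at least two frames")
    heat = np.abs(np.diff(frames, axis=0)).sum(axis=0)
    if log_mode == "log1p":
        summary = float(np.log1p(heat).sum())
    elif log_mode == "as_printed_ln":
        pos = heat[heat > 0]
        summary = float(np.log(pos).sum()) if pos.size else 0.0
    else:
        raise ValueError(f"unknown log_mode {log_mode!r}")
    return ThermalMap(heat=heat, summary=summary, pooled=_mean_pool(heat))


# ------------------------------------------------------------------- GGD

@dataclass(frozen=True)
class GGDParams:
    theta: float  # shape (2 = Gaussian, 1 = Laplacian)
    sigma: float  # scale

    def __post_init__(self):
        if self.theta <= 0 or self.sigma <= 0:
            raise ValueError("GGD shape and scale must be strictly positive")

    def neg_log_pdf(self, x: np.ndarray) -> np.ndarray:
        th, sg = self.theta, self.sigma
        log_norm = np.log(th) - np.log(2 * sg) - gammaln(1.0 / th)
        return np.abs(np.asarray(x) / sg) ** th - log_norm


def _ggd_moment_ratio(theta: float) -> float:
    # E|x|^2 / (E|x|)^2 = Gamma(1/t) Gamma(3/t) / Gamma(2/t)^2
    return float(
        np.exp(gammaln(1.0 / theta) + gammaln(3.0 / theta) - 2 * gammaln(2.0 / theta))
    )


def fit_ggd(samples: np.ndarray, min_samples: int = 50) -> GGDParams:
    """Moment-matching GGD fit: the ratio E|x|²/(E|x|)² pins the shape
    (inverted by bisection), then the scale follows in closed form from
    the first absolute moment."""
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    x = x - x.mean()
    m1 = np.abs(x).mean()
    m2 = (x**2).mean()
    if m1 < 1e-300 or m2 < 1e-300:
        raise ValueError("degenerate samples: all (nearly) equal")
    r = m2 / m1**2
    lo, hi = 0.05, 20.0
    f = lambda t: _ggd_moment_ratio(t) - r
    if f(lo) < 0:
        theta = lo
    elif f(hi) > 0:
        theta = hi
    else:
        theta = brentq(f, lo, hi, xtol=1e-10)
    # E|x| = sigma * Gamma(2/t) / Gamma(1/t)
    sigma = m1 * float(np.exp(gammaln(1.0 / theta) - gammaln(2.0 / theta)))
    return GGDParams(theta=theta, sigma=sigma)


def sample_ggd(theta: float, sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw GGD samples: |x| = sigma * G^(1/theta), G ~ Gamma(1/theta, 1),
    with a random sign."""
    g = rng.gamma(1.0 / theta, 1.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * sigma * g ** (1.0 / theta)


# -------------------------------------------------------------- saliency

_SCALE_PAIRS = [(1.0, 2.0), (2.0, 4.0), (4.0, 8.0)]


def bandpass_stack(frame: np.ndarray) -> np.ndarray:
    """Three difference-of-smoothing band-pass channels (DC-free)."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    return np.stack(
        [
            ndimage.gaussian_filter(frame, s0) - ndimage.gaussian_filter(frame, s1)
            for s0, s1 in _SCALE_PAIRS
        ]
    )


def fit_ggd_bank(frame: np.ndarray) -> list:
    """Fit one GGD per band-pass channel; degenerate channels yield None."""
    bank = []
    for chan in bandpass_stack(frame):
        try:
            bank.append(fit_ggd(chan.ravel()))
        except ValueError:
            bank.append(None)
    return bank


def saliency_map(frame: np.ndarray, ggd_bank: list) -> np.ndarray:
    """Per-pixel salience = sum over channels of -log P(channel value),
    min-max normalized to [0, 1].  A constant map normalizes to 1e-9."""
    if ggd_bank is None:
        raise ValueError("GGD bank must be fitted before computing saliency")
    channels = bandpass_stack(frame)
    if len(ggd_bank) != len(channels):
        raise ValueError("bank size does not match the channel stack")
    sal = np.zeros(channels.shape[1:])
    for chan, params in zip(channels, ggd_bank):
        if params is None:
            continue
        sal += params.neg_log_pdf(chan)
    rng_ = sal.max() - sal.min()
    if rng_ < 1e-12:
        return np.full(sal.shape, 1e-9)
    return (sal - sal.min()) / rng_


# ---------------------------------------------------- orientation angles

#: (a, b, c): interior angle measured at b between rays b->a and b->c.
TRIANGLE_CATALOGUE = [
    (("shoulders", "l"), ("head", "c"), ("shoulders", "r")),
    (("shoulders", "l"), ("elbows", "l"), ("wrists", "l")),
    (("shoulders", "r"), ("elbows", "r"), ("wrists", "r")),
    (("knees", "l"), ("torso", "c"), ("knees", "r")),
    (("torso", "c"), ("knees", "l"), ("ankles", "l")),
    (("torso", "c"), ("knees", "r"), ("ankles", "r")),
]


@dataclass
class OrientationDescriptor:
    angles: np.ndarray  # (6,) radians in [0, pi]; NaN for missing triangles
    valid: np.ndarray  # (6,) bool

    @property
    def vectorized(self) -> np.ndarray:
        return np.where(self.valid, self.angles, 0.0)


def angle_at_vertex(u: np.ndarray, v: np.ndarray) -> float:
    """Interior angle between side vectors u and v via
    atan2(‖u×v‖, u·v) — numerically robust and exactly acos of the
    normalized dot product."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[0] * v[1] - u[1] * v[0]
    return float(np.arctan2(abs(cross), u @ v))


def orientation_angles(sk: SkeletonPoints) -> OrientationDescriptor:
    angles = np.full(len(TRIANGLE_CATALOGUE), np.nan)
    valid = np.zeros(len(TRIANGLE_CATALOGUE), dtype=bool)
    for i, (a, b, c) in enumerate(TRIANGLE_CATALOGUE):
        pa = sk.get(a[0], a[1])
        pb = sk.get(b[0], b[1])
        pc = sk.get(c[0], c[1])
        if pa is None or pb is None or pc is None:
            continue
        u = np.subtract(pa, pb)
        v = np.subtract(pc, pb)
        if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
            continue  # degenerate triangle: skip, leave flagged invalid
        angles[i] = angle_at_vertex(u, v)
        valid[i] = True
    return OrientationDescriptor(angles=angles, valid=valid)


# ------------------------------------------------------------------ SLIF

@dataclass
class SLIFDescriptor:
    nodes: np.ndarray  # (M, N, 2) web node (row, col) coordinates
    samples: np.ndarray  # (M, N) bilinear pixel intensities (0 off-frame)
    in_frame: np.ndarray  # (M, N) bool

    @property
    def vectorized(self) -> np.ndarray:
        return self.samples.ravel()  # m outer, n inner


def slif(
    frame: np.ndarray,
    point: tuple[float, float],
    N: int = 8,
    M: int = 3,
    ring_step: float = 2.0,
) -> SLIFDescriptor:
    """Spiderweb sampling around one skeleton point.

    Node (n, m) sits at ``point + m*ring_step*(cos(2πn/N), sin(2πn/N))``
    in (row, col) coordinates, for rings m = 1..M and spokes n = 0..N-1.
    Intensities are bilinearly interpolated; nodes outside the frame
    sample 0 and are flagged.
    """
    if N < 3:
        raise ValueError("need at least 3 spokes")
    if M < 1:
        raise ValueError("need at least 1 ring")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    H, W = frame.shape
    r0, c0 = point
    angles = 2 * np.pi * np.arange(N) / N
    rings = np.arange(1, M + 1)[:, None] * ring_step
    rows = r0 + rings * np.cos(angles)[None, :]
    cols = c0 + rings * np.sin(angles)[None, :]
    in_frame = (rows >= 0) & (rows <= H - 1) & (cols >= 0) & (cols <= W - 1)
    samples = ndimage.map_coordinates(
        frame, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(M, N)
    samples[~in_frame] = 0.0
    nodes = np.stack([rows, cols], axis=-1)
    return SLIFDescriptor(nodes=nodes, samples=samples, in_frame=in_frame)


def slif_pooled(frame: np.ndarray, sk: SkeletonPoints, N: int = 8, M: int = 3,
                ring_step: float = 2.0) -> np.ndarray:
    """Mean SLIF vector over all detected skeleton points (zeros if the
    skeleton is empty) — a fixed-length N*M per-frame descriptor."""
    vecs = []
    for cat in sk.points:
        for pt in sk.points[cat]:
            vecs.append(slif(frame, pt, N=N, M=M, ring_step=ring_step).vectorized)
    if not vecs:
        return np.zeros(N * M)
    return np.mean(vecs, axis=0)
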