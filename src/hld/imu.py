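"""Quaternion-based filtration of inertial and magnetic signals.

The chain mirrors a classical wearable-sensor front end: zero-phase
Butterworth low/high-pass split of each channel, a Euclidean combined
magnitude of the six filtered components, gravity estimation from a
stationary interval and removal in the sensor frame, hard-iron
magnetometer correction against the Earth reference field, wavelet
denoising of the gyroscope, and orientation tracking by integrating the
quaternion derivative with a gradient-descent correction toward the
measured gravity (and, when available, magnetic) directions — the
Madgwick-style complementary structure.  Euler angles are read off the
body-frame gravity direction with plain atan2 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

from . import quat


@dataclass(frozen=True)
class FilterConfig:
    order: int = 4
    fc_low: float = 5.0  # Hz, low-pass corner
    fc_high: float = 0.3  # Hz, high-pass corner
    sample_rate: float = 50.0
    wavelet_name: str = "db4"
    dwt_level: int = 3
    gd_step: float = 0.1  # gradient-descent correction step (beta)
    norm_mode: str = "euclidean"  # or "as_printed_sum"

    def validate(self) -> None:
        nyq = self.sample_rate / 2.0
        if not (0 < self.fc_low < nyq and 0 < self.fc_high < nyq):
            raise ValueError("cutoffs must lie strictly inside (0, Nyquist)")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.dwt_level < 1:
            raise ValueError("dwt_level must be >= 1")
        if self.norm_mode not in ("euclidean", "as_printed_sum"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


@dataclass(frozen=True)
class GravityModel:
    gm: float  # minimum gravity magnitude over the stationary interval
    ga: float  # average gravity magnitude
    g_vec: np.ndarray  # mean specific-force vector, sensor frame at rest

    def __post_init__(self):
        if not (0 < self.gm <= self.ga + 1e-12):
            raise ValueError("need 0 < gm <= ga")


@dataclass
class OrientationState:
    q: np.ndarray  # (n, 4) unit quaternions, body->world
    euler: np.ndarray  # (n, 3) = (Axz, Ayz, Axy) radians


def butterworth_split(x: np.ndarray, cfg: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase low-pass at fc_low and high-pass at fc_high."""
    cfg.validate()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    min_len = 3 * (2 * cfg.order + 1)
    if len(x) <= min_len:
        raise ValueError(
            f"series of length {len(x)} too short for order-{cfg.order} "
            f"zero-phase filtering (need > {min_len} samples)"
        )
    nyq = cfg.sample_rate / 2.0
    sos_lo = butter(cfg.order, cfg.fc_low / nyq, btype="low", output="sos")
    sos_hi = butter(cfg.order, cfg.fc_high / nyq, btype="high", output="sos")
    low = sosfiltfilt(sos_lo, x, padtype="even")
    high = sosfiltfilt(sos_hi, x, padtype="even")
    return low, high


def channel_norm(lpf: np.ndarray, hpf: np.ndarray, mode: str = "euclidean") -> np.ndarray:
    """Per-sample combined magnitude of the six filtered axis components.

    ``euclidean`` (default) is sqrt(sum of squares); ``as_printed_sum``
    is the plain sum of the six components.
    """
    lpf = np.atleast_2d(np.asarray(lpf, dtype=float))
    hpf = np.atleast_2d(np.asarray(hpf, dtype=float))
    if lpf.shape != hpf.shape:
        raise ValueError(f"shape mismatch: {lpf.shape} vs {hpf.shape}")
    if mode == "euclidean":
        return np.sqrt((lpf**2).sum(axis=0) + (hpf**2).sum(axis=0))
    if mode == "as_printed_sum":
        return lpf.sum(axis=0) + hpf.sum(axis=0)
    raise ValueError(f"unknown norm mode {mode!r}")


def estimate_gravity(accel: np.ndarray) -> GravityModel:
    """Gravity statistics over a stationary interval (e.g. lying down)."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3 or len(accel) == 0:
        raise ValueError("need a non-empty (n, 3) accelerometer slice")
    mags = np.linalg.norm(accel, axis=1)
    return GravityModel(gm=float(mags.min()), ga=float(mags.mean()),
                        g_vec=accel.mean(axis=0))


def remove_gravity(
    accel: np.ndarray,
    g: GravityModel,
    orientation: OrientationState,
    anchor_index: int | None = 0,
) -> np.ndarray:
    """Subtract the gravity vector, re-expressed in the sensor frame at
    each timestamp via the fused orientation.

    ``g.g_vec`` is the rest-pose measurement in the sensor frame at
    sample ``anchor_index``; the world-frame gravity is recovered by
    rotating it through the orientation at that sample.  With
    ``anchor_index=None`` the vector is taken to be world-frame already.
    """
    accel = np.asarray(accel, dtype=float)
    if orientation is None or orientation.q is None:
        raise ValueError("orientation required to project gravity")
    if len(orientation.q) != len(accel):
        raise ValueError("accel and orientation series are not aligned")
    if anchor_index is None:
        g_world = np.asarray(g.g_vec, dtype=float)
    else:
        g_world = quat.rotate(orientation.q[anchor_index], g.g_vec)
    out = np.empty_like(accel)
    for i in range(len(accel)):
        out[i] = accel[i] - quat.rotate_inv(orientation.q[i], g_world)
    return out


def remove_magnetic_error(mag: np.ndarray, reference_field: np.ndarray) -> np.ndarray:
    """Hard-iron correction against the Earth reference field.

    The clean measurement is the reference field rotated into the sensor
    frame, so it lives on a sphere of radius ``‖reference_field‖``
    centered at the origin; a constant (hard-iron) offset shifts that
    center.  On a window with attitude variety the center is recovered
    by a linear least-squares sphere fit.  On a (near-)static window the
    sphere is unobservable and the offset reduces to the per-axis mean
    minus the reference field itself.
    """
    ref = np.asarray(reference_field, dtype=float)
    if np.linalg.norm(ref) == 0:
        raise ValueError("reference field must be non-zero")
    mag = np.asarray(mag, dtype=float)
    spread = mag.std(axis=0).max()
    if spread < 1e-6 * max(np.linalg.norm(ref), 1.0):
        offset = mag.mean(axis=0) - ref
        return mag - offset
    # sphere fit: ‖m - c‖² = r²  →  2 m·c + (r² - ‖c‖²) = ‖m‖², linear in (c, d).
    # Damped toward zero offset so directions the attitude never explored
    # (underdetermined columns) do not produce runaway centers.
    n = len(mag)
    A = np.column_stack([2.0 * mag, np.ones(n)])
    b = (mag**2).sum(axis=1)
    damp = 1e-3 * np.sqrt(n) * np.sqrt((mag**2).sum(axis=1).mean())
    A_reg = np.vstack([A, np.hstack([damp * np.eye(3), np.zeros((3, 1))])])
    b_reg = np.concatenate([b, np.zeros(3)])
    sol, *_ = np.linalg.lstsq(A_reg, b_reg, rcond=None)
    center = sol[:3]
    return mag - center


def dwt_denoise(x: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Multilevel DWT, soft-threshold the details at the universal
    threshold, reconstruct.  Length preserved."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2**cfg.dwt_level:
        raise ValueError(
            f"series of length {len(x)} too short for a level-{cfg.dwt_level} DWT"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.dwt_level, mode="symmetric")
    # noise scale from the finest detail band (median absolute deviation)
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail)) / 0.6745 if len(detail) else 0.0
    thresh = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    if thresh <= 0:  # noise-free signal: nothing to shrink
        return x.copy()
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    out = pywt.waverec(denoised, cfg.wavelet_name, mode="symmetric")
    return out[: len(x)]


def _grad_correction(q: np.ndarray, v_world: np.ndarray, v_meas: np.ndarray) -> np.ndarray:
    """Gradient of ½‖R(q)ᵀ v_world − v_meas‖² with respect to q.

    Both vectors are expected normalized.  Used as the descent direction
    of the orientation correction step.
    """
    w, r = q[0], q[1:]
    v = v_world
    u = (w * w - r @ r) * v + 2.0 * (r @ v) * r - 2.0 * w * np.cross(r, v)
    f = u - v_meas
    grad = np.empty(4)
    grad[0] = f @ (2.0 * w * v - 2.0 * np.cross(r, v))
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        du = -2.0 * r[k] * v + 2.0 * v[k] * r + 2.0 * (r @ v) * e - 2.0 * w * np.cross(e, v)
        grad[1 + k] = f @ du
    return grad


def fuse_orientation(
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray | None,
    cfg: FilterConfig,
    q0: np.ndarray | None = None,
) -> OrientationState:
    """Track orientation: integrate q̇ = ½ q ⊗ (0, ω), then take one
    gradient-descent step of size gd_step toward agreement between the
    predicted and measured gravity (and field) directions; renormalize.
    """
    gyro = np.asarray(gyro, dtype=float)
    accel = np.asarray(accel, dtype=float)
    n = len(gyro)
    if accel.shape != (n, 3):
        raise ValueError("gyro and accel must be time-aligned (n, 3) arrays")
    if mag is not None:
        mag = np.asarray(mag, dtype=float)
        if mag.shape != (n, 3):
            raise ValueError("mag must be time-aligned with gyro")
    arrays = [gyro, accel] + ([mag] if mag is not None else [])
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("NaN or inf in fusion inputs")
    if q0 is None:
        # tilt initialization from the first accelerometer sample:
        # rotate the measured gravity direction onto world +z
        a0 = accel[0]
        if np.linalg.norm(a0) > 1e-9:
            a_hat = a0 / np.linalg.norm(a0)
            z = np.array([0.0, 0.0, 1.0])
            axis = np.cross(a_hat, z)
            s = np.linalg.norm(axis)
            angle = np.arctan2(s, a_hat @ z)
            q = quat.from_axis_angle(axis if s > 1e-12 else np.array([1.0, 0.0, 0.0]), angle)
        else:
            q = quat.IDENTITY.copy()
    else:
        q = np.asarray(q0, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("q0 must be a unit quaternion")
    dt = 1.0 / cfg.sample_rate
    g_dir = np.array([0.0, 0.0, 1.0])
    mag_dir = None
    if mag is not None:
        m0 = mag[0]
        if np.linalg.norm(m0) > 1e-9:
            # world-frame field direction implied by the initial pose
            mag_dir = quat.rotate(q, m0 / np.linalg.norm(m0))
    qs = np.empty((n, 4))
    for i in range(n):
        qdot = 0.5 * quat.multiply(q, np.concatenate([[0.0], gyro[i]]))
        grad = np.zeros(4)
        a_norm = np.linalg.norm(accel[i])
        if a_norm > 1e-9:
            grad += _grad_correction(q, g_dir, accel[i] / a_norm)
        if mag_dir is not None:
            m_norm = np.linalg.norm(mag[i])
            if m_norm > 1e-9:
                grad += _grad_correction(q, mag_dir, mag[i] / m_norm)
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e-12 and cfg.gd_step > 0:
            qdot = qdot - cfg.gd_step * grad / gnorm
        q = quat.normalize(q + qdot * dt)
        qs[i] = q
    eulers = np.empty((n, 3))
    for i in range(n):
        g_body = quat.rotate_inv(qs[i], g_dir)
        eulers[i] = euler_angles(g_body)
    return OrientationState(q=qs, euler=eulers)


def euler_angles(v: np.ndarray) -> np.ndarray:
    """(Axz, Ayz, Axy) = (atan2(z,x), atan2(z,y), atan2(y,x)).

    Values are mapped into (-pi, pi] (atan2 returns -pi at the branch
    cut).  The all-zero vector is rejected: atan2(0, 0) carries no
    directional information.
    """
    v = np.asarray(v, dtype=float)
    if np.allclose(v, 0.0):
        raise ValueError("euler angles undefined for the zero vector")
    x, y, z = v
    ang = np.array([np.arctan2(z, x), np.arctan2(z, y), np.arctan2(y, x)])
    ang[ang <= -np.pi] = np.pi
    return ang


def preprocess_motion(
    accel: np.ndarray,
    gyro: np.ndarray,
    mag: np.ndarray,
    cfg: FilterConfig,
    stationary_slice: slice | None = None,
    reference_field: np.ndarray | None = None,
) -> dict:
    """Full filtration chain for one recording's IMU stream.

    Returns a dict with the cleaned channels: gravity-free acceleration,
    denoised gyro, corrected magnetometer, the Euclidean norm channel of
    the Butterworth-split acceleration, fused orientation and Euler
    angles.
    """
    cfg.validate()
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    mag = np.asarray(mag, dtype=float)
    low = np.empty_like(accel)
    high = np.empty_like(accel)
    for k in range(3):
        low[:, k], high[:, k] = butterworth_split(accel[:, k], cfg)
    norm = channel_norm(low.T, high.T, mode=cfg.norm_mode)
    gyro_dn = np.column_stack([dwt_denoise(gyro[:, k], cfg) for k in range(3)])
    # constant gyro bias from the stationary interval; median is robust
    # to the entry transition at the start of the interval
    if stationary_slice is not None:
        gyro_dn = gyro_dn - np.median(gyro_dn[stationary_slice], axis=0)
    ref = reference_field if reference_field is not None else np.array([22.0, 5.0, -43.0])
    mag_clean = remove_magnetic_error(mag, ref)
    orientation = fuse_orientation(gyro_dn, accel, mag_clean, cfg)
    if stationary_slice is not None:
        g_model = estimate_gravity(accel[stationary_slice])
        anchor = (stationary_slice.stop or len(accel)) - 1  # fusion has settled by then
        lin_accel = remove_gravity(accel, g_model, orientation, anchor_index=anchor)
    else:
        # fused world frame has gravity along +z by construction
        g_model = GravityModel(gm=9.0, ga=9.81, g_vec=np.array([0.0, 0.0, 9.81]))
        lin_accel = remove_gravity(accel, g_model, orientation, anchor_index=None)
    return {
        "lin_accel": lin_accel,
        "gyro": gyro_dn,
        "mag": mag_clean,
        "norm": norm,
        "orientation": orientation,
        "gravity": g_model,
    }
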