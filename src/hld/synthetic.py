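"""Seeded synthetic multimodal recordings.

Emulates the structure of living-lab activity datasets: one subject per
session performs scripted activities while wearing a 9-axis IMU
(accelerometer, gyroscope, magnetometer), a handful of ambient binary
sensors fire as the subject crosses their zones, and a low-resolution
camera films an articulated stick figure on a static background.

The activity dynamics are a per-activity sinusoid bank plus an optional
world-frame yaw rate.  This keeps every downstream descriptor testable
against closed forms: the accelerometer oscillation has a known
per-axis variance, the gravity/magnetic vectors are exactly the world
references rotated by the scripted orientation, and the gyroscope is
exactly the angular velocity of the scripted quaternion series (plus a
constant bias and white noise).

Ground truth (labels, orientation quaternions, landmark pixel
coordinates, subject position) is stored alongside the signals so the
pipeline stages can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from . import quat

GRAVITY = 9.81  # m/s^2, world frame +z
MAG_REFERENCE = np.array([22.0, 5.0, -43.0])  # µT, world frame

LANDMARKS = [
    "head",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "torso",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
]

# (row fraction of figure height, col offset as fraction of figure height)
_POSE = {
    "head": (0.06, 0.0),
    "shoulder_l": (0.18, -0.12),
    "shoulder_r": (0.18, 0.12),
    "elbow_l": (0.32, -0.18),
    "elbow_r": (0.32, 0.18),
    "wrist_l": (0.46, -0.20),
    "wrist_r": (0.46, 0.20),
    "torso": (0.40, 0.0),
    "knee_l": (0.66, -0.10),
    "knee_r": (0.66, 0.10),
    "ankle_l": (0.92, -0.11),
    "ankle_r": (0.92, 0.11),
}

_LIMBS = [
    ("head", "torso"),
    ("shoulder_l", "shoulder_r"),
    ("shoulder_l", "elbow_l"),
    ("elbow_l", "wrist_l"),
    ("shoulder_r", "elbow_r"),
    ("elbow_r", "wrist_r"),
    ("torso", "knee_l"),
    ("torso", "knee_r"),
    ("knee_l", "ankle_l"),
    ("knee_r", "ankle_r"),
]


@dataclass(frozen=True)
class ActivityDynamics:
    """Sinusoid-bank parameters describing one activity."""

    amp: float  # m/s^2, base accelerometer oscillation amplitude
    freq: float  # Hz, fundamental gait/arm frequency
    speed: float  # corridor-fractions per second of translation
    yaw_rate: float = 0.0  # rad/s world-frame yaw
    roll: float = 0.0  # rad, static body roll (lying = pi/2)
    swing: float = 0.0  # limb swing amplitude (fraction of figure height)


#: Default vocabulary.  Amplitudes/frequencies are in the range reported
#: for human gait (walking cadence ~1.8 Hz, running ~2.6 Hz); the
#: "vacuuming" entry shares walking's amplitude but not its frequency so
#: that amplitude statistics alone cannot separate the pair.
ACTIVITY_DYNAMICS: dict[str, ActivityDynamics] = {
    "lying": ActivityDynamics(amp=0.0, freq=0.0, speed=0.0, roll=np.pi / 2),
    "sitting": ActivityDynamics(amp=0.15, freq=0.4, speed=0.0),
    "standing": ActivityDynamics(amp=0.25, freq=0.6, speed=0.0),
    "walking": ActivityDynamics(amp=1.5, freq=1.8, speed=0.08, swing=0.04),
    "vacuuming": ActivityDynamics(amp=1.5, freq=3.2, speed=0.04, swing=0.03),
    "running": ActivityDynamics(amp=3.0, freq=2.6, speed=0.18, swing=0.06),
    "turning": ActivityDynamics(amp=0.3, freq=1.0, speed=0.0, yaw_rate=0.6),
}

# oscillation is distributed across axes with fixed weights and phases
_AXIS_WEIGHTS = np.array([0.6, 0.3, 1.0])
_AXIS_PHASES = np.array([0.0, np.pi / 3, 2 * np.pi / 3])


@dataclass(frozen=True)
class ActivityScript:
    """Ordered, non-overlapping labelled activity intervals."""

    intervals: tuple[tuple[float, float, str], ...]
    sample_rate_imu: float = 50.0
    fps_video: float = 8.0

    def __init__(self, intervals, sample_rate_imu: float = 50.0, fps_video: float = 8.0):
        object.__setattr__(self, "intervals", tuple(tuple(iv) for iv in intervals))
        object.__setattr__(self, "sample_rate_imu", float(sample_rate_imu))
        object.__setattr__(self, "fps_video", float(fps_video))

    def validate(self, vocabulary=None) -> None:
        if not self.intervals:
            raise ValueError("activity script has no intervals")
        if self.sample_rate_imu <= 0 or self.fps_video <= 0:
            raise ValueError("sampling rates must be positive")
        vocab = set(vocabulary) if vocabulary is not None else set(ACTIVITY_DYNAMICS)
        prev_end = -np.inf
        for start, end, label in self.intervals:
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) has non-positive length")
            if start < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            if label not in vocab:
                raise ValueError(f"unknown activity label {label!r}")
            prev_end = end
        if self.duration <= 0:
            raise ValueError("script has zero duration")

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]

    def label_at(self, t: float) -> str:
        for start, end, label in self.intervals:
            if start <= t < end:
                return label
        return "none"


@dataclass(frozen=True)
class AmbientSensor:
    sensor_id: str
    sensor_type: str  # switch | PIR | infrared
    orientation: float  # degrees in [0, 360)
    neighbors: tuple[str, ...]
    zone: tuple[float, float]  # corridor interval in [0, 1]


@dataclass(frozen=True)
class AmbientLayout:
    sensors: tuple[AmbientSensor, ...]

    def __init__(self, sensors):
        object.__setattr__(self, "sensors", tuple(sensors))

    def validate(self) -> None:
        ids = [s.sensor_id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sensor ids")
        by_id = {s.sensor_id: s for s in self.sensors}
        for s in self.sensors:
            if s.sensor_type not in ("switch", "PIR", "infrared"):
                raise ValueError(f"unknown sensor type {s.sensor_type!r}")
            if not 0 <= s.orientation < 360:
                raise ValueError("orientation must lie in [0, 360)")
            for nb in s.neighbors:
                if nb not in by_id:
                    raise ValueError(f"neighbor {nb!r} of {s.sensor_id!r} not in layout")
                if s.sensor_id not in by_id[nb].neighbors:
                    raise ValueError(
                        f"asymmetric neighbor relation: {s.sensor_id!r} -> {nb!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "AmbientLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sensors = [
            AmbientSensor(
                sensor_id=d["sensor_id"],
                sensor_type=d["sensor_type"],
                orientation=float(d["orientation"]),
                neighbors=tuple(d.get("neighbors", ())),
                zone=tuple(d.get("zone", (0.0, 0.0))),
            )
            for d in raw["sensors"]
        ]
        layout = cls(sensors)
        layout.validate()
        return layout

    def to_yaml(self, path) -> None:
        data = {
            "sensors": [
                {
                    "sensor_id": s.sensor_id,
                    "sensor_type": s.sensor_type,
                    "orientation": float(s.orientation),
                    "neighbors": list(s.neighbors),
                    "zone": list(s.zone),
                }
                for s in self.sensors
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def default_layout() -> AmbientLayout:
    """Four sensors in a chain along the corridor."""
    zones = [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)]
    types = ["switch", "PIR", "PIR", "infrared"]
    orientations = [0.0, 90.0, 180.0, 270.0]
    ids = [f"s{i}" for i in range(4)]
    sensors = []
    for i in range(4):
        nbs = tuple(ids[j] for j in (i - 1, i + 1) if 0 <= j < 4)
        sensors.append(
            AmbientSensor(ids[i], types[i], orientations[i], nbs, zones[i])
        )
    return AmbientLayout(sensors)


@dataclass(frozen=True)
class NoiseConfig:
    """White-noise levels and constant offsets for the simulated sensors."""

    accel_std: float = 0.05  # m/s^2
    gyro_std: float = 0.01  # rad/s
    gyro_bias: tuple[float, float, float] = (0.005, -0.01, 0.008)  # rad/s
    mag_std: float = 0.3  # µT
    mag_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # hard iron, µT
    pixel_std: float = 0.0  # grey levels

    def validate(self) -> None:
        for name in ("accel_std", "gyro_std", "mag_std", "pixel_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, (0.0, 0.0, 0.0), 0.0, (0.0, 0.0, 0.0), 0.0)

    @classmethod
    def noisy(cls) -> "NoiseConfig":
        return cls(0.6, 0.12, (0.02, -0.03, 0.015), 1.5, (4.0, -2.0, 1.0), 4.0)


@dataclass
class MultimodalRecording:
    """One synchronized session of IMU + ambient + video with ground truth."""

    time_imu: np.ndarray  # (n,)
    accel: np.ndarray  # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) rad/s
    mag: np.ndarray  # (n, 3) µT
    imu_labels: np.ndarray  # (n,) str
    truth_quat: np.ndarray  # (n, 4) body->world
    truth_position: np.ndarray  # (n,) corridor fraction
    ambient_events: pd.DataFrame  # columns time_s, sensor_id, state
    frame_times: np.ndarray  # (T,)
    frames: np.ndarray  # (T, H, W, 3) uint8
    frame_labels: np.ndarray  # (T,) str
    truth_skeleton: np.ndarray  # (T, 12, 2) float (row, col)
    layout: AmbientLayout
    script: ActivityScript
    seed: int

    @property
    def sample_rate(self) -> float:
        return self.script.sample_rate_imu

    @property
    def fps(self) -> float:
        return self.script.fps_video


def _script_orientation(script: ActivityScript, times: np.ndarray) -> np.ndarray:
    """Per-sample truth quaternion: per-interval base pose, 0.5 s slerp
    transition from the previous pose, plus accumulated world-frame yaw."""
    quats = np.empty((len(times), 4))
    assigned = np.zeros(len(times), dtype=bool)
    prev_q = None
    for k, (start, end, label) in enumerate(script.intervals):
        dyn = ACTIVITY_DYNAMICS[label]
        q_base = quat.from_axis_angle(np.array([1.0, 0.0, 0.0]), dyn.roll)
        trans = 0.0 if k == 0 else min(0.5, 0.25 * (end - start))
        sel = (times >= start) & (times < end) if k < len(script.intervals) - 1 else (
            times >= start
        )
        idx = np.nonzero(sel)[0]
        for i in idx:
            t = times[i]
            if prev_q is not None and t < start + trans:
                q = quat.slerp(prev_q, q_base, (t - start) / trans)
            else:
                tau = max(0.0, t - start - trans)
                if dyn.yaw_rate != 0.0:
                    yaw = quat.from_axis_angle(
                        np.array([0.0, 0.0, 1.0]), dyn.yaw_rate * tau
                    )
                    q = quat.multiply(yaw, q_base)
                else:
                    q = q_base
            quats[i] = q
            assigned[i] = True
        if len(idx):
            prev_q = quats[idx[-1]]
    # gaps between intervals hold the last scripted pose
    last = quat.IDENTITY.copy()
    for i in range(len(times)):
        if assigned[i]:
            last = quats[i]
        else:
            quats[i] = last
    return quats


def _script_position(script: ActivityScript, times: np.ndarray) -> np.ndarray:
    """Corridor position in [0, 1]; ping-pongs off the walls."""
    pos = np.empty(len(times))
    x, direction = 0.1, 1.0
    prev_t = times[0] if len(times) else 0.0
    for i, t in enumerate(times):
        dt = t - prev_t
        dyn = ACTIVITY_DYNAMICS.get(script.label_at(t))
        v = dyn.speed if dyn is not None else 0.0
        x += direction * v * dt
        if x > 0.95:
            x, direction = 0.95 - (x - 0.95), -1.0
        elif x < 0.05:
            x, direction = 0.05 + (0.05 - x), 1.0
        pos[i] = x
        prev_t = t
    return pos


def _render_frame(
    H: int, W: int, background: np.ndarray, landmarks: np.ndarray
) -> np.ndarray:
    from skimage.draw import line

    img = background.copy()
    pts = np.round(landmarks).astype(int)
    by_name = {name: pts[i] for i, name in enumerate(LANDMARKS)}
    for a, b in _LIMBS:
        r0, c0 = by_name[a]
        r1, c1 = by_name[b]
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        img[rr[ok], cc[ok]] = 140
    for r, c in pts:  # 3x3 bright blob at every landmark
        r0, r1 = max(r - 1, 0), min(r + 2, H)
        c0, c1 = max(c - 1, 0), min(c + 2, W)
        img[r0:r1, c0:c1] = 255
    return img


def _pose_landmarks(
    label: str, t: float, position: float, H: int, W: int
) -> np.ndarray:
    """Pixel (row, col) of the 12 landmarks at time t."""
    dyn = ACTIVITY_DYNAMICS[label] if label in ACTIVITY_DYNAMICS else None
    height = 36.0
    top = H - 4 - height
    center = 8 + position * (W - 16)
    phase = np.sin(2 * np.pi * (dyn.freq if dyn else 0.0) * t)
    swing = dyn.swing if dyn else 0.0
    pts = np.empty((12, 2))
    for i, name in enumerate(LANDMARKS):
        yf, xf = _POSE[name]
        # antisymmetric limb swing, left/right out of phase; y kept fixed.
        # legs swing at half the arm amplitude so the markers stay disjoint
        part = name.split("_")[0]
        if part in ("elbow", "wrist", "knee", "ankle"):
            amp = swing * (0.5 if part in ("knee", "ankle") else 1.0)
            xf = xf - amp * phase if name.endswith("_l") else xf + amp * phase
        if dyn is not None and dyn.roll > 1.0:  # lying: figure horizontal
            row = H - 8 + xf * height * 0.5
            col = center + (yf - 0.5) * height
        else:
            row = top + yf * height
            col = center + xf * height
        pts[i] = (np.clip(row, 1, H - 2), np.clip(col, 1, W - 2))
    return pts


def _static_background(H: int, W: int) -> np.ndarray:
    rr, cc = np.mgrid[0:H, 0:W]
    bg = 18 + 10 * np.sin(2 * np.pi * cc / W) * np.cos(2 * np.pi * rr / H)
    bg[5:12, 5:15] = 40.0  # a "window"
    bg[H - 10 : H - 4, W - 20 : W - 6] = 32.0  # a "table"
    return np.clip(bg, 0, 255)


def generate_recording(
    script: ActivityScript,
    layout: AmbientLayout | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    frame_shape: tuple[int, int] = (48, 64),
) -> MultimodalRecording:
    """Simulate one session; identical arguments give bit-identical output."""
    layout = layout if layout is not None else default_layout()
    noise = noise if noise is not None else NoiseConfig()
    script.validate()
    layout.validate()
    noise.validate()
    rng = np.random.default_rng(seed)

    duration = script.duration
    fs = script.sample_rate_imu
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    labels = np.array([script.label_at(t) for t in times])

    quats = _script_orientation(script, times)
    position = _script_position(script, times)

    # gyroscope: exact angular velocity of the scripted orientation
    omega = np.zeros((n, 3))
    for i in range(n - 1):
        omega[i] = quat.body_angular_velocity(quats[i], quats[i + 1], 1.0 / fs)
    if n > 1:
        omega[-1] = omega[-2]

    g_world = np.array([0.0, 0.0, GRAVITY])
    accel = np.empty((n, 3))
    mag = np.empty((n, 3))
    for i in range(n):
        accel[i] = quat.rotate_inv(quats[i], g_world)
        mag[i] = quat.rotate_inv(quats[i], MAG_REFERENCE)
    for i, t in enumerate(times):
        dyn = ACTIVITY_DYNAMICS.get(labels[i])
        if dyn is not None and dyn.amp > 0:
            accel[i] += dyn.amp * _AXIS_WEIGHTS * np.sin(
                2 * np.pi * dyn.freq * t + _AXIS_PHASES
            )
    accel += rng.normal(0.0, noise.accel_std, (n, 3)) if noise.accel_std else 0.0
    gyro = omega + np.asarray(noise.gyro_bias)
    gyro += rng.normal(0.0, noise.gyro_std, (n, 3)) if noise.gyro_std else 0.0
    mag += np.asarray(noise.mag_offset)
    mag += rng.normal(0.0, noise.mag_std, (n, 3)) if noise.mag_std else 0.0

    # ambient: binary state = subject inside the sensor zone, scanned at 10 Hz
    scan = np.arange(0.0, duration, 0.1)
    scan_pos = np.interp(scan, times, position) if n else np.zeros(0)
    rows = []
    state = {s.sensor_id: 0 for s in layout.sensors}
    for t, x in zip(scan, scan_pos):
        for s in layout.sensors:
            new = int(s.zone[0] <= x < s.zone[1])
            if new != state[s.sensor_id] or (t == 0.0 and new == 1):
                rows.append((float(t), s.sensor_id, new))
                state[s.sensor_id] = new
    events = pd.DataFrame(rows, columns=["time_s", "sensor_id", "state"])

    # video
    H, W = frame_shape
    T = int(round(duration * script.fps_video))
    frame_times = np.arange(T) / script.fps_video
    bg = _static_background(H, W)
    frames = np.empty((T, H, W, 3), dtype=np.uint8)
    skeleton = np.empty((T, 12, 2))
    frame_labels = np.array([script.label_at(t) for t in frame_times])
    frame_pos = np.interp(frame_times, times, position) if n else np.zeros(T)
    for j, t in enumerate(frame_times):
        lab = frame_labels[j]
        lm = _pose_landmarks(lab if lab != "none" else "standing", t, frame_pos[j], H, W)
        skeleton[j] = lm
        img = _render_frame(H, W, bg, lm)
        if noise.pixel_std:
            img = img + rng.normal(0.0, noise.pixel_std, img.shape)
        frames[j] = np.repeat(np.clip(img, 0, 255).astype(np.uint8)[..., None], 3, axis=2)

    return MultimodalRecording(
        time_imu=times,
        accel=accel,
        gyro=gyro,
        mag=mag,
        imu_labels=labels,
        truth_quat=quats,
        truth_position=position,
        ambient_events=events,
        frame_times=frame_times,
        frames=frames,
        frame_labels=frame_labels,
        truth_skeleton=skeleton,
        layout=layout,
        script=script,
        seed=seed,
    )


def save_recording(rec: MultimodalRecording, path) -> None:
    """Persist a recording to HDF5 (groups /imu, /ambient, /frames, /truth)."""
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        imu = f.create_group("imu")
        imu.create_dataset("time_s", data=rec.time_imu)
        imu.create_dataset("accel", data=rec.accel)
        imu.create_dataset("gyro", data=rec.gyro)
        imu.create_dataset("mag", data=rec.mag)
        amb = f.create_group("ambient")
        amb.create_dataset("time_s", data=rec.ambient_events["time_s"].to_numpy())
        amb.create_dataset(
            "sensor_id",
            data=rec.ambient_events["sensor_id"].to_numpy().astype(object),
            dtype=str_dt,
        )
        amb.create_dataset("state", data=rec.ambient_events["state"].to_numpy())
        fr = f.create_group("frames")
        fr.create_dataset("time_s", data=rec.frame_times)
        fr.create_dataset("images", data=rec.frames, compression=None)
        tr = f.create_group("truth")
        tr.create_dataset("imu_labels", data=rec.imu_labels.astype(object), dtype=str_dt)
        tr.create_dataset(
            "frame_labels", data=rec.frame_labels.astype(object), dtype=str_dt
        )
        tr.create_dataset("quat", data=rec.truth_quat)
        tr.create_dataset("position", data=rec.truth_position)
        tr.create_dataset("skeleton", data=rec.truth_skeleton)
        f.attrs["seed"] = rec.seed
        f.attrs["sample_rate_imu"] = rec.script.sample_rate_imu
        f.attrs["fps_video"] = rec.script.fps_video
        f.attrs["script"] = yaml.safe_dump(
            [list(iv) for iv in rec.script.intervals]
        )
        f.attrs["layout"] = yaml.safe_dump(
            {
                "sensors": [
                    {
                        "sensor_id": s.sensor_id,
                        "sensor_type": s.sensor_type,
                        "orientation": float(s.orientation),
                        "neighbors": list(s.neighbors),
                        "zone": list(s.zone),
                    }
                    for s in rec.layout.sensors
                ]
            }
        )


def load_recording(path) -> MultimodalRecording:
    with h5py.File(path, "r") as f:
        script = ActivityScript(
            [tuple(iv) for iv in yaml.safe_load(f.attrs["script"])],
            sample_rate_imu=float(f.attrs["sample_rate_imu"]),
            fps_video=float(f.attrs["fps_video"]),
        )
        raw_layout = yaml.safe_load(f.attrs["layout"])
        layout = AmbientLayout(
            [
                AmbientSensor(
                    d["sensor_id"],
                    d["sensor_type"],
                    float(d["orientation"]),
                    tuple(d["neighbors"]),
                    tuple(d["zone"]),
                )
                for d in raw_layout["sensors"]
            ]
        )
        events = pd.DataFrame(
            {
                "time_s": f["ambient/time_s"][...],
                "sensor_id": [s.decode() for s in f["ambient/sensor_id"][...]],
                "state": f["ambient/state"][...],
            }
        )
        return MultimodalRecording(
            time_imu=f["imu/time_s"][...],
            accel=f["imu/accel"][...],
            gyro=f["imu/gyro"][...],
            mag=f["imu/mag"][...],
            imu_labels=np.array([s.decode() for s in f["truth/imu_labels"][...]]),
            truth_quat=f["truth/quat"][...],
            truth_position=f["truth/position"][...],
            ambient_events=events,
            frame_times=f["frames/time_s"][...],
            frames=f["frames/images"][...],
            frame_labels=np.array([s.decode() for s in f["truth/frame_labels"][...]]),
            truth_skeleton=f["truth/skeleton"][...],
            layout=layout,
            script=script,
            seed=int(f.attrs["seed"]),
        )


def write_ambient_csv(rec: MultimodalRecording, path) -> None:
    rec.ambient_events.to_csv(path, index=False)
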