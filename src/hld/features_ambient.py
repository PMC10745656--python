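"""Graph-based ambient descriptor R = (M, K) and per-window features.

Each binary ambient sensor (switch / PIR / infrared) is a node.  The
descriptor matrix M carries one row per sensor — type code, neighbor
count, mounting orientation — and K is the symmetric binary adjacency
matrix of the physical layout.  Per window the event stream is reduced
to a fixed-length vector: activation count and total active duration
per sensor, the rank of each sensor in the order of first activation,
and the number of layout edges whose both endpoints activated inside
the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AmbientLayout

TYPE_CODES = {"switch": 0, "PIR": 1, "infrared": 2}


@dataclass
class AmbientGraphDescriptor:
    sensor_ids: list
    M: np.ndarray  # (n, 3): type code, neighbor count, orientation degrees
    K: np.ndarray  # (n, n) binary adjacency

    def __post_init__(self):
        K = self.K
        if not np.array_equal(K, K.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(K) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(self.M[:, 1], K.sum(axis=1)):
            raise ValueError("neighbor counts in M must equal adjacency row sums")


def build_graph(layout: AmbientLayout) -> AmbientGraphDescriptor:
    """Deterministic (M, K) with rows ordered by sensor_id."""
    layout.validate()
    sensors = sorted(layout.sensors, key=lambda s: s.sensor_id)
    ids = [s.sensor_id for s in sensors]
    index = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n), dtype=int)
    for s in sensors:
        for nb in s.neighbors:
            K[index[s.sensor_id], index[nb]] = 1
    if not np.array_equal(K, K.T):
        bad = np.argwhere(K != K.T)[0]
        raise ValueError(
            f"asymmetric neighbor lists between {ids[bad[0]]!r} and {ids[bad[1]]!r}"
        )
    M = np.array(
        [
            [TYPE_CODES[s.sensor_type], len(s.neighbors), s.orientation]
            for s in sensors
        ],
        dtype=float,
    )
    return AmbientGraphDescriptor(sensor_ids=ids, M=M, K=K)


def ambient_window_features(
    events: pd.DataFrame,
    graph: AmbientGraphDescriptor,
    start_s: float,
    end_s: float,
) -> np.ndarray:
    """Fixed-length window vector of length 3*n_sensors + 1.

    Blocks: per-sensor 0->1 activation counts; per-sensor active
    duration in seconds (activations still open at the window end are
    truncated there); per-sensor first-activation order rank (1 = first,
    0 = never activated); and the count of adjacency edges with both
    endpoints activated in the window.
    """
    if end_s <= start_s:
        raise ValueError("window must have positive duration")
    t = events["time_s"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("event stream must be time-sorted")
    n = len(graph.sensor_ids)
    index = {sid: i for i, sid in enumerate(graph.sensor_ids)}
    counts = np.zeros(n)
    durations = np.zeros(n)
    first_activation = np.full(n, np.inf)
    # reconstruct each sensor's state over the window
    state = np.zeros(n, dtype=int)
    on_since = np.full(n, np.nan)
    for _, ev in events.iterrows():
        ts, sid, st = float(ev["time_s"]), ev["sensor_id"], int(ev["state"])
        if sid not in index:
            continue
        i = index[sid]
        if ts >= end_s:
            break
        if st == 1 and state[i] == 0:
            if ts >= start_s:
                counts[i] += 1
                first_activation[i] = min(first_activation[i], ts)
            on_since[i] = max(ts, start_s)
        elif st == 0 and state[i] == 1:
            if not np.isnan(on_since[i]) and ts > start_s:
                durations[i] += min(ts, end_s) - max(on_since[i], start_s)
            on_since[i] = np.nan
        state[i] = st
    # truncate still-open activations at the window end
    for i in range(n):
        if state[i] == 1 and not np.isnan(on_since[i]):
            durations[i] += end_s - max(on_since[i], start_s)
    ranks = np.zeros(n)
    order = np.argsort(first_activation, kind="stable")
    r = 1
    for i in order:
        if np.isfinite(first_activation[i]):
            ranks[i] = r
            r += 1
    activated = counts > 0
    iu = np.triu_indices(n, k=1)
    subgraph_edges = int(
        np.sum(graph.K[iu] * (activated[iu[0]] & activated[iu[1]]))
    )
    return np.concatenate([counts, durations, ranks, [subgraph_edges]])
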