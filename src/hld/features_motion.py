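"""Motion descriptors: GMRF window statistics and the MSST graph.

Two families are extracted per motion window:

* **GMRF descriptor** — the per-channel expectation and the cross-channel
  covariance of the windowed multichannel signal, treating the window as
  a draw from a Gaussian Markov random field.  Vectorized as the mean
  concatenated with the upper triangle of the covariance.

* **Spatial–temporal graph** — the window's short-time spectrum is
  sharpened by a multisynchrosqueezing transform (iterated reassignment
  of STFT energy toward the instantaneous-frequency estimate, at most
  two passes) and summarized as a six-node graph: one node per frequency
  band carrying its total energy, and edges weighting how often two
  bands are simultaneously active across time frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GMRFDescriptor:
    mu: np.ndarray  # (C,)
    sigma: np.ndarray  # (C, C), unbiased sample covariance

    def __post_init__(self):
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-8:
            raise ValueError("covariance must be positive semidefinite")

    @property
    def vectorized(self) -> np.ndarray:
        iu = np.triu_indices(len(self.mu))
        return np.concatenate([self.mu, self.sigma[iu]])


@dataclass
class STGraph:
    nodes: np.ndarray  # (6,) band center frequencies, Hz
    node_energy: np.ndarray  # (6,) nonnegative
    weights: np.ndarray  # (6, 6) symmetric co-activation weights

    N_NODES = 6

    def __post_init__(self):
        if len(self.nodes) != self.N_NODES:
            raise ValueError("spatial-temporal graph has exactly six nodes")
        if np.any(self.node_energy < 0) or np.any(self.weights < 0):
            raise ValueError("energies and weights must be nonnegative")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("edge weights must be symmetric")

    @property
    def vectorized(self) -> np.ndarray:
        iu = np.triu_indices(self.N_NODES)
        return np.concatenate([self.node_energy, self.weights[iu]])

    @classmethod
    def from_vector(cls, vec: np.ndarray, nodes: np.ndarray) -> "STGraph":
        k = cls.N_NODES
        energy = np.asarray(vec[:k], dtype=float)
        w = np.zeros((k, k))
        iu = np.triu_indices(k)
        w[iu] = vec[k:]
        w = w + w.T - np.diag(np.diag(w))
        return cls(nodes=np.asarray(nodes), node_energy=energy, weights=w)

    @property
    def edges(self) -> list:
        out = []
        for i in range(self.N_NODES):
            for j in range(i, self.N_NODES):
                if self.weights[i, j] > 0:
                    out.append((i, j, float(self.weights[i, j])))
        return out


def gmrf_descriptor(segment_data: np.ndarray) -> GMRFDescriptor:
    """Sample mean and unbiased cross-channel covariance of an (n, C)
    window."""
    X = np.asarray(segment_data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 2:
        raise ValueError("need at least 2 samples per channel for covariance")
    mu = X.mean(axis=0)
    sigma = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    # symmetrize against floating-point asymmetry before validation
    sigma = 0.5 * (sigma + sigma.T)
    return GMRFDescriptor(mu=mu, sigma=sigma)


def stft(x: np.ndarray, T: int, hop: int = 1, analytic: bool = False) -> np.ndarray:
    """Short-time Fourier transform with a rectangular window.

    Returns complex coefficients of shape (n_bins, n_frames) with
    ``n_bins = T//2 + 1`` one-sided bins.  With ``analytic=True`` the
    transform is taken of the analytic signal (Hilbert), which removes
    the negative-frequency image and is the form the synchrosqueezing
    reassignment assumes.
    """
    x = np.asarray(x, dtype=float)
    if T < 4:
        raise ValueError("window length T must be >= 4")
    if T > len(x):
        raise ValueError("window longer than the signal")
    if analytic:
        from scipy.signal import hilbert

        xa = hilbert(x)
        starts = range(0, len(x) - T + 1, hop)
        frames = np.stack([xa[s : s + T] for s in starts], axis=1)
        return np.fft.fft(frames, axis=0)[: T // 2 + 1]
    starts = range(0, len(x) - T + 1, hop)
    frames = np.stack([x[s : s + T] for s in starts], axis=1)
    return np.fft.rfft(frames, axis=0)


def periodogram(x: np.ndarray, T: int, hop: int | None = None) -> np.ndarray:
    """Short-time periodogram p(s, f) = |Y(s, f)|^2 / T.

    ``hop`` defaults to T (non-overlapping frames).
    """
    hop = T if hop is None else hop
    Y = stft(x, T, hop)
    return (np.abs(Y) ** 2) / T


def _instantaneous_frequency_bins(tfr: np.ndarray, T: int, hop: int = 1) -> np.ndarray:
    """Per-coefficient target bin: the bin nearest the instantaneous
    frequency estimated from the phase advance between adjacent time
    frames (first-order finite difference; unambiguous for hop=1).
    Coefficients with magnitude below 1e-12 keep their own bin.
    """
    n_bins, n_frames = tfr.shape
    targets = np.tile(np.arange(n_bins)[:, None], (1, n_frames))
    if n_frames < 2:
        return targets
    # phase advance over `hop` samples, in radians
    dphi = np.angle(tfr[:, 1:] * np.conj(tfr[:, :-1]))
    dphi = np.concatenate([dphi[:, :1], dphi], axis=1)
    freq_bin = np.mod(dphi, 2 * np.pi) / (2 * np.pi) * T / hop  # cycles per window
    cand = np.round(freq_bin).astype(int)
    ok = (np.abs(tfr) >= 1e-12) & (cand >= 0) & (cand < n_bins)
    targets[ok] = cand[ok]
    return targets


def msst(tfr: np.ndarray, M: int = 2, T: int | None = None, hop: int = 1) -> np.ndarray:
    """Multisynchrosqueezing: move each STFT coefficient's energy along
    the frequency axis to its instantaneous-frequency bin, iterated M
    times by composing the reassignment map.  Total energy is conserved
    exactly.  ``M=0`` is the identity and returns the input unchanged.
    """
    tfr = np.asarray(tfr)
    if M == 0:
        return tfr
    if M < 0:
        raise ValueError("iteration count must be >= 0")
    if not np.any(tfr):
        return tfr
    n_bins, n_frames = tfr.shape
    T_eff = T if T is not None else 2 * (n_bins - 1)
    base = _instantaneous_frequency_bins(tfr, T_eff, hop)
    # compose the per-frame bin->bin map M times
    targets = np.arange(n_bins)[:, None] * np.ones((1, n_frames), dtype=int)
    for _ in range(M):
        for t in range(n_frames):
            targets[:, t] = base[targets[:, t], t]
    energy = np.abs(tfr) ** 2
    out = np.zeros((n_bins, n_frames))
    for t in range(n_frames):
        np.add.at(out[:, t], targets[:, t], energy[:, t])
    return out


def st_graph(
    msst_matrix: np.ndarray,
    band_edges: np.ndarray,
    sample_rate: float | None = None,
) -> STGraph:
    """Six-node spatial–temporal graph from a (n_bins, n_frames) energy
    matrix.

    ``band_edges`` are 7 increasing bin-fraction edges covering [0, 1]
    of the one-sided frequency axis.  Node i carries the total energy in
    band i; the edge (i, j) weight is the fraction of time frames where
    both bands are simultaneously "active", i.e. at or above their own
    median energy over time (bands whose median is zero are never
    active).
    """
    E = np.abs(np.asarray(msst_matrix, dtype=float))
    edges = np.asarray(band_edges, dtype=float)
    if len(edges) != STGraph.N_NODES + 1:
        raise ValueError("need 7 band edges for a six-band partition")
    if np.any(np.diff(edges) <= 0) or edges[0] != 0.0 or abs(edges[-1] - 1.0) > 1e-9:
        raise ValueError("band edges must increase from 0 to 1")
    n_bins, n_frames = E.shape
    bounds = np.round(edges * n_bins).astype(int)
    band_ts = np.zeros((STGraph.N_NODES, n_frames))
    for i in range(STGraph.N_NODES):
        band_ts[i] = E[bounds[i] : max(bounds[i + 1], bounds[i] + 1)].sum(axis=0)
    node_energy = band_ts.sum(axis=1)
    med = np.median(band_ts, axis=1)
    active = (band_ts >= med[:, None]) & (med[:, None] > 0)
    weights = (active[:, None, :] & active[None, :, :]).mean(axis=2)
    nyq = 0.5 * (sample_rate if sample_rate is not None else 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:]) * nyq
    return STGraph(nodes=centers, node_energy=node_energy, weights=weights)


def equal_band_edges() -> np.ndarray:
    """Default six equal-width bands over [0, Nyquist]."""
    return np.linspace(0.0, 1.0, STGraph.N_NODES + 1)


def motion_graph_descriptor(
    x: np.ndarray, sample_rate: float, T: int = 64, M: int = 2,
    band_edges: np.ndarray | None = None,
) -> STGraph:
    """Full chain for one scalar motion window: STFT -> MSST -> graph."""
    T = min(T, len(x))
    tfr = stft(x, T, hop=1, analytic=True)
    sq = msst(tfr, M=M, T=T, hop=1)
    edges = band_edges if band_edges is not None else equal_band_edges()
    return st_graph(sq, edges, sample_rate=sample_rate)
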