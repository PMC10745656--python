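"""GMM codebook with EM fitting and Gaussian mixture regression.

One mixture model is fitted per descriptor family by
expectation–maximization: the E-step computes responsibilities
γ(z_kj | x_j) of every component for every descriptor, and the M-step
re-estimates weights, means and (ridge-regularized) covariances from
the responsibility-weighted data.  A fitted model encodes a segment's
descriptor set as a soft-assignment histogram over components, plus the
GMR "generalized signal": the mixture's conditional mean of the output
dimensions given the input dimension, evaluated on a fixed query grid,
which summarizes how the descriptors evolve across the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus


@dataclass
class GMMModel:
    weights: np.ndarray  # (K,), sums to 1
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d), symmetric PD after ridge
    log_likelihood_trace: list = field(default_factory=list)
    ridge: float = 1e-6

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = len(mean)
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = (sol**2).sum(axis=0)
    log_det = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + log_det + maha)


def _log_resp(model: GMMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log responsibilities (n, K) and per-sample log-likelihood (n,)."""
    lp = np.stack(
        [
            np.log(model.weights[k]) + _log_gauss(X, model.means[k], model.covariances[k])
            for k in range(model.K)
        ],
        axis=1,
    )
    norm = logsumexp(lp, axis=1)
    return lp - norm[:, None], norm


def responsibilities(model: GMMModel, X: np.ndarray) -> np.ndarray:
    lr, _ = _log_resp(model, np.atleast_2d(np.asarray(X, dtype=float)))
    return np.exp(lr)


def gmm_fit(
    X: np.ndarray,
    K: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    ridge: float = 1e-6,
    seed: int = 0,
) -> GMMModel:
    """Fit a K-component full-covariance GMM by EM with k-means++
    initialization.  The log-likelihood trace is recorded per iteration
    and is non-decreasing; a component whose weight collapses below
    1e-8 is re-seeded to a random data point once, after which a second
    collapse raises."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if K > n:
        raise ValueError(f"cannot fit {K} components to {n} points")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix contains non-finite values")
    rng = np.random.default_rng(seed)
    if K == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    weights = np.full(K, 1.0 / K)
    means = centers.astype(float)
    base_cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1)) if n > 1 else np.eye(d)
    base_cov = 0.5 * (base_cov + base_cov.T) + max(ridge, 1e-10) * np.eye(d)
    covariances = np.stack([base_cov.copy() for _ in range(K)])
    model = GMMModel(weights, means, covariances, [], ridge)
    reseeded = set()
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_r, log_norm = _log_resp(model, X)
        ll = float(log_norm.sum())
        model.log_likelihood_trace.append(ll)
        resp = np.exp(log_r)
        nk = resp.sum(axis=0)
        for k in range(K):
            if nk[k] / n < 1e-8:
                if k in reseeded:
                    raise RuntimeError(f"component {k} collapsed twice during EM")
                reseeded.add(k)
                model.means[k] = X[rng.integers(n)]
                model.covariances[k] = base_cov.copy()
                nk[k] = max(nk[k], 1e-8 * n)
        model.weights = nk / nk.sum()
        model.means = (resp.T @ X) / nk[:, None]
        for k in range(K):
            diff = X - model.means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            model.covariances[k] = 0.5 * (cov + cov.T) + ridge * np.eye(d)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    # final log-likelihood under the last parameter update
    _, log_norm = _log_resp(model, X)
    model.log_likelihood_trace.append(float(log_norm.sum()))
    return model


def gmr_generalize(
    model: GMMModel,
    input_dims,
    output_dims,
    query_points: np.ndarray,
) -> np.ndarray:
    """Conditional mean of the output dims given input dims, per query.

    At each query x_I the prediction is the responsibility-weighted sum
    of the per-component affine regressions
    μ_k^O + Σ_k^{OI} (Σ_k^{II})^{-1} (x_I − μ_k^I); the weights are the
    input-marginal responsibilities h_k(x_I).
    """
    input_dims = np.asarray(input_dims, dtype=int)
    output_dims = np.asarray(output_dims, dtype=int)
    if set(input_dims) & set(output_dims):
        raise ValueError("input and output dims must be disjoint")
    if len(set(input_dims) | set(output_dims)) != model.dim:
        raise ValueError("input and output dims must cover the model dimensions")
    Q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if Q.shape[1] != len(input_dims):
        Q = Q.reshape(-1, len(input_dims))
    K = model.K
    di = input_dims
    do = output_dims
    log_h = np.empty((len(Q), K))
    preds = np.empty((len(Q), K, len(do)))
    for k in range(K):
        mu_i = model.means[k][di]
        mu_o = model.means[k][do]
        S = model.covariances[k]
        S_ii = S[np.ix_(di, di)]
        S_oi = S[np.ix_(do, di)]
        try:
            L = np.linalg.cholesky(S_ii)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular input-marginal covariance") from exc
        log_h[:, k] = np.log(model.weights[k]) + _log_gauss(Q, mu_i, S_ii)
        gain = S_oi @ np.linalg.inv(S_ii)
        preds[:, k, :] = mu_o + (Q - mu_i) @ gain.T
    log_h = log_h - logsumexp(log_h, axis=1)[:, None]
    h = np.exp(log_h)
    return (h[:, :, None] * preds).sum(axis=1)


@dataclass
class CodebookEncoding:
    histogram: np.ndarray  # (K,) soft-assignment counts, sums to n descriptors
    gmr_signal: np.ndarray  # (Q, d_out) generalized signal on the query grid

    @property
    def vectorized(self) -> np.ndarray:
        return np.concatenate([self.histogram, self.gmr_signal.ravel()])


def encode_segments(
    model: GMMModel,
    descriptor_sets: list,
    query_points: np.ndarray | None = None,
    time_dim: int = 0,
) -> list[CodebookEncoding]:
    """Encode each segment's descriptor set against a fitted model.

    Descriptors are expected time-augmented: column ``time_dim`` is the
    within-segment normalized time, the remaining columns the
    descriptor.  The GMR block conditions the descriptor on time at
    ``query_points`` (default three points across the segment).  An
    empty descriptor set yields a zero histogram and the unconditioned
    mixture mean at every query.
    """
    if query_points is None:
        query_points = np.array([0.0, 0.5, 1.0])
    out_dims = [j for j in range(model.dim) if j != time_dim]
    encodings = []
    uncond_mean = (model.weights[:, None] * model.means).sum(axis=0)[out_dims]
    for X in descriptor_sets:
        X = np.atleast_2d(np.asarray(X, dtype=float)) if np.size(X) else np.zeros((0, model.dim))
        if X.size and X.shape[1] != model.dim:
            raise ValueError(
                f"descriptor dimension {X.shape[1]} does not match model {model.dim}"
            )
        if len(X) == 0:
            hist = np.zeros(model.K)
            signal = np.tile(uncond_mean, (len(query_points), 1))
        else:
            hist = responsibilities(model, X).sum(axis=0)
            signal = gmr_generalize(model, [time_dim], out_dims, query_points)
        encodings.append(CodebookEncoding(histogram=hist, gmr_signal=signal))
    return encodings
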