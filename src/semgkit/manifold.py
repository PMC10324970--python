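"""Strategy 2 front end: nonlinear dimensionality reduction.

Two reducers operate on one feature row per trial:

* **LTSA** (local tangent space alignment) — aligns per-point tangent-space
  coordinates obtained from local PCA through a global alignment matrix and
  reads the embedding off its bottom eigenvectors.
* **LLC** (locally linear coordination) — fits a mixture of probabilistic
  PCA models by EM and aligns the responsibility-weighted local coordinates
  through the LLE-style generalized eigenproblem.

The default trial-to-row mapping concatenates classic per-channel amplitude
descriptors (RMS, variance, waveform length, zero crossings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .trials import Trial, TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "trial_summary_features",
    "TrialSummaryFeatures",
    "EmbeddingResult",
    "LocalModelMixture",
    "ltsa",
    "LTSA",
    "llc_fit_mixture",
    "llc_align",
    "LLC",
]


# ---------------------------------------------------------------------------
# Per-trial summary features (the P matrix rows)
# ---------------------------------------------------------------------------

def trial_summary_features(trial: Trial) -> np.ndarray:
    """RMS, variance, waveform length and zero-crossing count per channel."""
    X = trial.samples
    rms = np.sqrt(np.mean(X**2, axis=0))
    var = np.var(X, axis=0)
    wl = np.sum(np.abs(np.diff(X, axis=0)), axis=0)
    zc = np.sum(np.diff(np.signbit(X), axis=0) != 0, axis=0).astype(float)
    return np.concatenate([rms, var, wl, zc])


class TrialSummaryFeatures(BaseEstimator, TransformerMixin):
    """TrialSet -> (n_trials, 4 * n_channels) summary feature matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: TrialSet | list[Trial]) -> np.ndarray:
        return np.array([trial_summary_features(t) for t in X])


# ---------------------------------------------------------------------------
# LTSA
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates (defined up to orthogonal transform)."""

    Q: np.ndarray
    method: str
    params: dict


def ltsa(P: np.ndarray, d: int, k: int) -> EmbeddingResult:
    """Local tangent space alignment embedding of the rows of ``P``.

    Per point: the k-nearest neighbourhood is centered and its top-``d``
    left singular vectors give the tangent coordinates; the alignment
    matrix accumulates ``I - G G^T`` over neighbourhoods (with ``G``
    spanning the constant vector and the tangent coordinates); the
    embedding consists of the eigenvectors of the symmetrized alignment
    matrix for the ``d`` smallest nonzero eigenvalues.
    """
    P = np.asarray(P, dtype=float)
    n, D = P.shape
    if k <= d:
        raise ValueError(f"neighbourhood size k={k} must exceed d={d}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    # neighbourhood = the point itself plus its k nearest others, so every
    # point is constrained by at least its own neighbourhood
    nn = NearestNeighbors(n_neighbors=k + 1).fit(P)
    _, idx = nn.kneighbors(P)
    m = k + 1
    A = np.zeros((n, n))
    for i in range(n):
        Si = idx[i]
        Xi = P[Si]
        Xc = Xi - Xi.mean(axis=0)
        # top-d left singular vectors of the centered neighbourhood
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        if s[min(d, len(s)) - 1] < 1e-12 * max(s[0], 1e-300):
            logger.warning("near-duplicate neighbourhood at point %d", i)
        G = np.hstack([np.full((m, 1), 1.0 / np.sqrt(m)), U[:, :d]])
        A[np.ix_(Si, Si)] += np.eye(m) - G @ G.T
    A = 0.5 * (A + A.T)
    evals, evecs = sla.eigh(A)
    order = np.argsort(evals)
    # the constant vector spans the guaranteed null direction; deflate it
    # from the d+1 bottom eigenvectors (the null space is degenerate on
    # exactly flat data, so eigenvalue order alone cannot isolate it)
    B = evecs[:, order[:d + 1]]
    B = B - B.mean(axis=0, keepdims=True)
    U2, s2, _ = np.linalg.svd(B, full_matrices=False)
    Q = U2[:, :d]
    return EmbeddingResult(Q=Q, method="LTSA", params={"k": k, "d": d})


class LTSA(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper; embedding is defined on the fitted data only."""

    def __init__(self, n_components: int = 10, n_neighbors: int = 12):
        self.n_components = n_components
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        self.embedding_ = ltsa(X, self.n_components, self.n_neighbors).Q
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        raise NotImplementedError(
            "LTSA has no out-of-sample extension; use fit_transform"
        )


# ---------------------------------------------------------------------------
# LLC: mixture of probabilistic PCA models + alignment
# ---------------------------------------------------------------------------

@dataclass
class LocalModelMixture:
    """Fitted mixture of local linear (probabilistic PCA) models."""

    responsibilities: np.ndarray   # (n, m), rows sum to 1
    local_coords: np.ndarray       # (m, n, d) posterior latent means
    means: np.ndarray              # (m, D)
    loglik_trace: np.ndarray

    @property
    def n_models(self) -> int:
        return self.responsibilities.shape[1]


def _ppca_closed_form(S: np.ndarray, d: int) -> tuple[np.ndarray, float]:
    """Maximum-likelihood PPCA parameters from a covariance matrix."""
    D = S.shape[0]
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    if D > d:
        sigma2 = float(np.mean(evals[d:]))
    else:
        sigma2 = 0.0
    sigma2 = max(sigma2, 1e-10)
    W = evecs[:, :d] @ np.diag(np.sqrt(np.maximum(evals[:d] - sigma2, 1e-12)))
    return W, sigma2


def _gaussian_logpdf(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    D = len(mu)
    cov = cov + 1e-9 * np.eye(D)
    L = np.linalg.cholesky(cov)
    diff = X - mu
    sol = sla.solve_triangular(L, diff.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (D * np.log(2 * np.pi) + logdet + maha)


def llc_fit_mixture(P: np.ndarray, m: int, d: int, seed: int = 0,
                    max_iter: int = 100, tol: float = 1e-6,
                    n_restarts: int = 3) -> LocalModelMixture:
    """EM fit of a mixture of ``m`` probabilistic PCA models with latent
    dimension ``d``; deterministic given ``seed``, log-likelihood
    non-decreasing per iteration."""
    P = np.asarray(P, dtype=float)
    n, D = P.shape
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < m * (d + 1):
        raise ValueError(f"need n >= m*(d+1) = {m * (d + 1)} samples, got {n}")

    last_err = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        km = KMeans(n_clusters=m, n_init=3,
                    random_state=int(rng.integers(2**31 - 1))).fit(P)
        means = km.cluster_centers_.copy()
        pis = np.full(m, 1.0 / m)
        Ws, sigma2s = [], []
        for j in range(m):
            mask = km.labels_ == j
            Xj = P[mask] if mask.sum() > d else P
            S = np.cov(Xj, rowvar=False, bias=True) + 1e-6 * np.eye(D)
            W, s2 = _ppca_closed_form(S, d)
            Ws.append(W)
            sigma2s.append(s2)
        trace = []
        R = None
        try:
            prev_ll = -np.inf
            for _ in range(max_iter):
                logp = np.empty((n, m))
                for j in range(m):
                    cov = Ws[j] @ Ws[j].T + sigma2s[j] * np.eye(D)
                    logp[:, j] = np.log(pis[j] + 1e-300) + _gaussian_logpdf(P, means[j], cov)
                mx = logp.max(axis=1, keepdims=True)
                lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
                ll = float(lse.sum())
                R = np.exp(logp - lse[:, np.newaxis])
                trace.append(ll)
                Nj = R.sum(axis=0)
                if Nj.min() < 1e-6:
                    raise RuntimeError("empty mixture component")
                for j in range(m):
                    means[j] = (R[:, j] @ P) / Nj[j]
                    diff = P - means[j]
                    S = (diff * R[:, j, np.newaxis]).T @ diff / Nj[j]
                    Ws[j], sigma2s[j] = _ppca_closed_form(S, d)
                pis = Nj / n
                if ll - prev_ll < tol * max(abs(ll), 1.0) and ll > -np.inf:
                    if ll >= prev_ll - 1e-8:
                        break
                prev_ll = ll
            coords = np.empty((m, n, d))
            for j in range(m):
                M = Ws[j].T @ Ws[j] + sigma2s[j] * np.eye(d)
                coords[j] = np.linalg.solve(M, Ws[j].T @ (P - means[j]).T).T
            return LocalModelMixture(responsibilities=R, local_coords=coords,
                                     means=means, loglik_trace=np.array(trace))
        except RuntimeError as exc:
            last_err = exc
            logger.warning("LLC mixture restart %d: %s", restart, exc)
            continue
    raise RuntimeError(f"mixture fitting failed after {n_restarts} restarts: {last_err}")


def _lle_weights(P: np.ndarray, k: int, reg: float = 1e-3) -> np.ndarray:
    """LLE reconstruction weight matrix; rows sum to 1."""
    n = P.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(P)
    _, idx = nn.kneighbors(P)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = idx[i][idx[i] != i][:k]
        Z = P[nbrs] - P[i]
        G = Z @ Z.T
        G = G + reg * np.trace(G) / len(nbrs) * np.eye(len(nbrs)) if np.trace(G) > 0 \
            else G + reg * np.eye(len(nbrs))
        w = np.linalg.solve(G, np.ones(len(nbrs)))
        W[i, nbrs] = w / w.sum()
    return W


def llc_align(P: np.ndarray, mix: LocalModelMixture, d: int,
              k: int = 12) -> EmbeddingResult:
    """Align the local models into a global embedding.

    Builds LLE weights W (rows summing to 1), the alignment matrix
    ``M = (I - W)^T (I - W)``, and the responsibility-weighted block matrix
    ``U`` with blocks ``u_ij = r_ij * [y_ij; 1]``; solves the generalized
    eigenproblem ``(U^T M U) L = lambda (U^T U) L`` for the ``d`` smallest
    nonzero eigenvalues and returns ``Q = U L``.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    m = mix.n_models
    dd = mix.local_coords.shape[2]
    W = _lle_weights(P, k)
    I_minus_W = np.eye(n) - W
    M = I_minus_W.T @ I_minus_W
    U = np.empty((n, m * (dd + 1)))
    for j in range(m):
        block = np.hstack([mix.local_coords[j], np.ones((n, 1))])
        U[:, j * (dd + 1):(j + 1) * (dd + 1)] = mix.responsibilities[:, j:j + 1] * block
    B = U.T @ M @ U
    A = U.T @ U
    try:
        evals, evecs = sla.eigh(B, A)
    except np.linalg.LinAlgError:
        eps = 1e-10 * np.trace(A) / A.shape[0]
        logger.warning("singular U^T U; ridge %.3g added", eps)
        evals, evecs = sla.eigh(B, A + eps * np.eye(A.shape[0]))
    # drop the null space (constant embedding), keep the d smallest nonzero
    tol = 1e-10 * max(np.trace(B), 1e-300)
    nonzero = np.where(evals > tol)[0]
    L = evecs[:, nonzero[:d]]
    Q = U @ L
    return EmbeddingResult(Q=Q, method="LLC",
                           params={"k": k, "d": d, "m": m, "L": L,
                                   "eigenvalues": evals[nonzero[:d]]})


class LLC(BaseEstimator, TransformerMixin):
    """Mixture-of-PPCA fit followed by LLE-style alignment."""

    def __init__(self, n_components: int = 10, n_neighbors: int = 12,
                 n_models: int = 8, local_dim: int | None = None,
                 random_state: int = 0):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.n_models = n_models
        self.local_dim = local_dim
        self.random_state = random_state

    def fit(self, X, y=None):
        dd = self.local_dim if self.local_dim is not None else self.n_components
        self.mixture_ = llc_fit_mixture(X, self.n_models, dd,
                                        seed=self.random_state)
        self.embedding_ = llc_align(X, self.mixture_, self.n_components,
                                    k=self.n_neighbors).Q
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        raise NotImplementedError(
            "LLC has no out-of-sample extension; use fit_transform"
        )
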