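"""Strategy 4: local mean decomposition, fuzzy C-means and the hybrid-kernel
least-squares SVM.

Local mean decomposition (LMD) splits each channel into *product functions*
— smooth envelope times pure frequency-modulated carrier — whose envelope
and instantaneous-frequency statistics form the trial features.  Fuzzy
C-means encodes each trial by its soft cluster memberships, and the
classifier is an LS-SVM whose kernel is the convex combination of an RBF
(local) and a polynomial (global) kernel::

    K_hybrid = a K_rbf + (1 - a) K_poly,   a in [0, 1]

Both summands satisfy the Mercer condition, so the hybrid does too.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics.pairwise import polynomial_kernel, rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .dbn_elm import PSOConfig, pso_minimize
from .errors import NumericalError
from .trials import Trial, TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProductFunction",
    "lmd_decompose",
    "lmd_features",
    "LMDFeatures",
    "FCMResult",
    "fuzzy_cmeans",
    "fcm_memberships",
    "fcm_encode",
    "FCMEncoder",
    "HybridKernel",
    "hybrid_kernel",
    "hybrid_gram",
    "LSSVMClassifier",
    "lssvm_fit",
    "tune_lssvm",
]


# ---------------------------------------------------------------------------
# Local mean decomposition
# ---------------------------------------------------------------------------

@dataclass
class ProductFunction:
    """One LMD component: ``pf = envelope * fm`` elementwise, with
    ``envelope >= 0`` and ``fm`` in [-1, 1]."""

    pf: np.ndarray
    envelope: np.ndarray
    fm: np.ndarray


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of strict sign changes of the first difference (interior
    extrema); plateaus contribute their first sample."""
    d = np.diff(x)
    # collapse zero differences onto the preceding trend
    trend = d.copy()
    for i in range(1, len(trend)):
        if trend[i] == 0:
            trend[i] = trend[i - 1]
    sign = np.sign(trend)
    idx = np.where(sign[1:] * sign[:-1] < 0)[0] + 1
    return idx


def _piecewise_mean_mag(x: np.ndarray, ext: np.ndarray,
                        span: int) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant local mean and magnitude between successive
    extrema, smoothed by a moving average of width ``span``."""
    n = len(x)
    anchors = np.concatenate([[0], ext, [n - 1]])
    m = np.empty(n)
    a = np.empty(n)
    for k in range(len(anchors) - 1):
        lo, hi = anchors[k], anchors[k + 1]
        v1, v2 = x[lo], x[hi]
        m[lo:hi + 1] = 0.5 * (v1 + v2)
        a[lo:hi + 1] = 0.5 * abs(v1 - v2)
    m = uniform_filter1d(m, size=span, mode="nearest")
    a = uniform_filter1d(a, size=span, mode="nearest")
    return m, np.maximum(a, 1e-12)


def lmd_decompose(x: np.ndarray, max_pf: int = 8,
                  smooth_span: int | None = None, sift_tol: float = 1e-2,
                  max_sift: int = 30) -> tuple[list[ProductFunction], np.ndarray]:
    """Decompose ``x`` into product functions plus a residual.

    Each product function is obtained by sifting: subtract the smoothed
    local mean, divide by the smoothed local magnitude, and repeat until
    the magnitude function is within ``sift_tol`` of unity; the envelope is
    the running product of the magnitude functions.  Components are
    subtracted in turn, so ``sum(pf) + residual == x`` exactly by
    construction.  Decomposition stops when the residual has fewer than
    three local extrema or ``max_pf`` is reached.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ValueError("need at least 32 samples")
    if smooth_span is None:
        smooth_span = max(3, (len(x) // 100) | 1)
    residual = x.copy()
    pfs: list[ProductFunction] = []
    for _ in range(max_pf):
        ext = _local_extrema(residual)
        if len(ext) < 3:
            break
        s = residual.copy()
        env = np.ones_like(x)
        converged = False
        prev_dev = np.inf
        for sift in range(max_sift):
            ext_s = _local_extrema(s)
            if len(ext_s) < 3:
                break
            m, a = _piecewise_mean_mag(s, ext_s, smooth_span)
            # relative floor keeps the division from amplifying flat regions
            a = np.maximum(a, 0.05 * np.max(a))
            dev = float(np.max(np.abs(a - 1.0)))
            if sift > 0 and dev < sift_tol:
                converged = True
                break
            if sift > 0 and dev >= prev_dev:
                break  # sifting stopped improving; accept current iterate
            prev_dev = dev
            s = (s - m) / a
            env = env * a
        if not converged and max_sift > 1:
            logger.debug("sifting stopped before tolerance; accepting iterate")
        # keep fm in [-1, 1] without changing the product
        peak = max(1.0, float(np.max(np.abs(s))))
        fm = s / peak
        envelope = env * peak
        pf = envelope * fm
        pfs.append(ProductFunction(pf=pf, envelope=envelope, fm=fm))
        residual = residual - pf
    return pfs, residual


def _instantaneous_frequency(fm: np.ndarray, fs: float,
                             trim: float = 0.05) -> np.ndarray:
    phase = np.unwrap(np.angle(hilbert(fm)))
    inst = np.diff(phase) * fs / (2 * np.pi)
    k = int(len(inst) * trim)
    return inst[k:len(inst) - k] if len(inst) > 2 * k + 2 else inst


def lmd_features(trial: Trial, n_pf: int = 3,
                 smooth_span: int | None = None) -> np.ndarray:
    """Per channel and retained product function: energy, envelope mean and
    SD, instantaneous-frequency mean and SD (edges trimmed 5 %); missing
    product functions are zero-padded.  Length ``n_channels * n_pf * 5``."""
    fs = trial.fs
    if smooth_span is None:
        smooth_span = max(3, int(np.ceil(fs / 100)) | 1)
    feats = []
    for ch in range(trial.n_channels):
        x = trial.samples[:, ch]
        if np.ptp(x) == 0:
            feats.append(np.zeros(n_pf * 5))
            continue
        pfs, _ = lmd_decompose(x, max_pf=n_pf, smooth_span=smooth_span)
        block = np.zeros(n_pf * 5)
        for i, p in enumerate(pfs[:n_pf]):
            inst = _instantaneous_frequency(p.fm, fs)
            block[i * 5:(i + 1) * 5] = [
                float(np.sum(p.pf**2)),
                float(p.envelope.mean()),
                float(p.envelope.std()),
                float(inst.mean()),
                float(inst.std()),
            ]
        if len(pfs) < n_pf:
            logger.debug("channel %d: %d/%d product functions, zero-padded",
                         ch, len(pfs), n_pf)
        feats.append(block)
    return np.concatenate(feats)


class LMDFeatures(BaseEstimator, TransformerMixin):
    """TrialSet -> LMD feature matrix (one row per trial)."""

    def __init__(self, n_pf: int = 3):
        self.n_pf = n_pf

    def fit(self, X, y=None):
        return self

    def transform(self, X: TrialSet | list[Trial]) -> np.ndarray:
        return np.array([lmd_features(t, n_pf=self.n_pf) for t in X])


# ---------------------------------------------------------------------------
# Fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass
class FCMResult:
    """Fuzzy C-means fit: centers, row-stochastic memberships, fuzzifier
    and the (non-increasing) objective trace."""

    centers: np.ndarray       # (C, d)
    memberships: np.ndarray   # (N, C)
    m_exp: float
    objective: np.ndarray


def _fcm_memberships(D2: np.ndarray, m_exp: float) -> np.ndarray:
    """Membership update from squared distances; coincident points get a
    crisp membership (the standard limit)."""
    N, C = D2.shape
    U = np.empty((N, C))
    zero = D2 <= 1e-300
    any_zero = zero.any(axis=1)
    power = 1.0 / (m_exp - 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = (1.0 / D2) ** power
        U = inv / inv.sum(axis=1, keepdims=True)  # NaN rows fixed below
    for i in np.where(any_zero)[0]:
        U[i] = zero[i] / zero[i].sum()
    return U


def fuzzy_cmeans(X: np.ndarray, C: int, m_exp: float = 2.0,
                 tol: float = 1e-6, max_iter: int = 300,
                 seed: int = 0) -> FCMResult:
    """Alternating optimization of the fuzzy C-means objective
    ``J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2`` from a random
    row-normalized membership matrix; stops when ``|dJ| < tol``."""
    X = np.asarray(X, dtype=float)
    N, d = X.shape
    if C < 2:
        raise ValueError("C must be >= 2")
    if m_exp <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if N <= C:
        raise ValueError("need more samples than clusters")
    rng = np.random.default_rng(seed)
    U = rng.random((N, C))
    U /= U.sum(axis=1, keepdims=True)
    trace = []
    prev_J = np.inf
    centers = None
    for _ in range(max_iter):
        Um = U**m_exp
        centers = (Um.T @ X) / Um.sum(axis=0)[:, np.newaxis]
        D2 = ((X[:, np.newaxis, :] - centers[np.newaxis, :, :]) ** 2).sum(axis=2)
        U = _fcm_memberships(D2, m_exp)
        J = float(np.sum(U**m_exp * D2))
        trace.append(J)
        if abs(prev_J - J) < tol:
            break
        prev_J = J
    return FCMResult(centers=centers, memberships=U, m_exp=m_exp,
                     objective=np.array(trace))


def fcm_memberships(X: np.ndarray, fcm: FCMResult) -> np.ndarray:
    """Membership degrees of new points under frozen centers."""
    X = np.asarray(X, dtype=float)
    D2 = ((X[:, np.newaxis, :] - fcm.centers[np.newaxis, :, :]) ** 2).sum(axis=2)
    return _fcm_memberships(D2, fcm.m_exp)


def fcm_encode(features: np.ndarray, fcm: FCMResult,
               mode: str = "concat") -> np.ndarray:
    """Encode rows by their cluster memberships (frozen centers); in
    ``concat`` mode the memberships are appended to the raw row."""
    if mode not in ("concat", "memberships"):
        raise ValueError("mode must be 'concat' or 'memberships'")
    features = np.asarray(features, dtype=float)
    if features.shape[1] != fcm.centers.shape[1]:
        raise ValueError(
            f"feature dim {features.shape[1]} != centers dim {fcm.centers.shape[1]}"
        )
    U = fcm_memberships(features, fcm)
    return np.hstack([features, U]) if mode == "concat" else U


class DimScaler(BaseEstimator, TransformerMixin):
    """Scale rows by ``1/sqrt(n_features)`` so inner products are O(1).

    Puts the polynomial and RBF summands of the hybrid kernel on a common
    scale without changing either kernel's definition.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        return np.asarray(X, dtype=float) / np.sqrt(self.n_features_in_)


class FCMEncoder(BaseEstimator, TransformerMixin):
    """Fit fuzzy C-means on training rows; transform appends (or replaces
    rows by) membership degrees.  Output width is ``d + C`` in concat mode."""

    def __init__(self, n_clusters: int = 8, m_exp: float = 2.0,
                 mode: str = "concat", random_state: int = 0):
        self.n_clusters = n_clusters
        self.m_exp = m_exp
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fcm_ = fuzzy_cmeans(np.asarray(X, dtype=float), self.n_clusters,
                                 m_exp=self.m_exp, seed=self.random_state)
        return self

    def transform(self, X):
        check_is_fitted(self, "fcm_")
        return fcm_encode(np.asarray(X, dtype=float), self.fcm_, mode=self.mode)


# ---------------------------------------------------------------------------
# Hybrid kernel and LS-SVM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridKernel:
    """Convex RBF/polynomial mixture: ``a`` the RBF weight, ``sigma2`` the
    RBF width, ``order`` the polynomial degree."""

    a: float = 0.5
    sigma2: float = 1.0
    order: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("mix weight a must lie in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.order < 1:
            raise ValueError("polynomial order must be >= 1")


def hybrid_gram(P: np.ndarray, Q: np.ndarray, k: HybridKernel) -> np.ndarray:
    """Gram matrix of the hybrid kernel between row sets P and Q."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    out = np.zeros((P.shape[0], Q.shape[0]))
    if k.a > 0:
        out += k.a * rbf_kernel(P, Q, gamma=1.0 / (2.0 * k.sigma2))
    if k.a < 1:
        out += (1.0 - k.a) * polynomial_kernel(P, Q, degree=k.order,
                                               gamma=1.0, coef0=1.0)
    return out


def hybrid_kernel(p: np.ndarray, q: np.ndarray, k: HybridKernel) -> float:
    """Scalar kernel value ``a exp(-||p-q||^2 / 2 sigma^2)
    + (1-a) ((p.q) + 1)^O``."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("p and q must have equal dimension")
    return float(hybrid_gram(p[np.newaxis], q[np.newaxis], k)[0, 0])


def _solve_lssvm(K: np.ndarray, y: np.ndarray,
                 gamma_reg: float) -> tuple[np.ndarray, float, float]:
    """Solve the LS-SVM KKT system [[0, 1^T], [1, K + I/gamma]] [b; alpha]
    = [0; y]; returns (alpha, b, relative KKT residual)."""
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma_reg
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(A[1:, 1:])
        logger.warning("singular KKT system; jitter %.3g added", jitter)
        A[1:, 1:] += jitter * np.eye(n)
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"KKT system unsolvable: {exc}") from None
    resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    return sol[1:], float(sol[0]), float(resid)


class _BinaryLSSVM:
    """Equality-constrained SVM on +-1 labels solved as one linear system."""

    def __init__(self, kernel_fn, gamma_reg: float):
        self.kernel_fn = kernel_fn
        self.gamma_reg = gamma_reg

    def fit(self, X: np.ndarray, y_pm: np.ndarray) -> "_BinaryLSSVM":
        self.X_ = X
        K = self.kernel_fn(X, X)
        self.alpha_, self.b_, self.kkt_residual_ = _solve_lssvm(
            K, y_pm.astype(float), self.gamma_reg)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.kernel_fn(X, self.X_) @ self.alpha_ + self.b_


class LSSVMClassifier(BaseEstimator, ClassifierMixin):
    """Least-squares SVM with the convex hybrid kernel.

    Binary problems solve the single KKT linear system
    ``[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]`` with decision
    ``sign(sum_t alpha_t K(x_t, x) + b)``; multi-class problems use
    one-vs-one majority vote with ties broken by summed decision values.

    Parameters
    ----------
    kernel : {'hybrid', 'rbf', 'poly', 'linear'}
        'hybrid' mixes RBF and polynomial with weight ``mix_weight``.
    mix_weight, sigma2, degree : hybrid-kernel parameters.
    gamma_reg : float
        LS-SVM regularization (large = hard fit).
    """

    def __init__(self, kernel: str = "hybrid", mix_weight: float = 0.5,
                 sigma2: float = 1.0, degree: int = 2,
                 gamma_reg: float = 10.0):
        self.kernel = kernel
        self.mix_weight = mix_weight
        self.sigma2 = sigma2
        self.degree = degree
        self.gamma_reg = gamma_reg

    def _kernel_fn(self):
        if self.kernel == "hybrid":
            k = HybridKernel(self.mix_weight, self.sigma2, self.degree)
            return lambda P, Q: hybrid_gram(P, Q, k)
        if self.kernel == "rbf":
            k = HybridKernel(1.0, self.sigma2, 1)
            return lambda P, Q: hybrid_gram(P, Q, k)
        if self.kernel == "poly":
            k = HybridKernel(0.0, self.sigma2, self.degree)
            return lambda P, Q: hybrid_gram(P, Q, k)
        if self.kernel == "linear":
            return lambda P, Q: np.atleast_2d(P) @ np.atleast_2d(Q).T
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        fn = self._kernel_fn()
        self.machines_ = {}
        for (ci, cj) in itertools.combinations(range(len(self.classes_)), 2):
            mask = (y == self.classes_[ci]) | (y == self.classes_[cj])
            y_pm = np.where(y[mask] == self.classes_[ci], 1.0, -1.0)
            self.machines_[(ci, cj)] = _BinaryLSSVM(fn, self.gamma_reg).fit(
                X[mask], y_pm)
        return self

    def decision_function(self, X):
        """Summed pairwise decision values per class (used for tie-breaks)."""
        check_is_fitted(self, "machines_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.zeros((X.shape[0], len(self.classes_)))
        for (ci, cj), machine in self.machines_.items():
            d = machine.decision(X)
            scores[:, ci] += d
            scores[:, cj] -= d
        return scores

    def predict(self, X):
        check_is_fitted(self, "machines_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((X.shape[0], len(self.classes_)))
        scores = np.zeros((X.shape[0], len(self.classes_)))
        for (ci, cj), machine in self.machines_.items():
            d = machine.decision(X)
            votes[:, ci] += d > 0
            votes[:, cj] += d <= 0
            scores[:, ci] += d
            scores[:, cj] -= d
        # majority vote; ties broken by the summed decision values
        best = np.empty(X.shape[0], dtype=int)
        for i in range(X.shape[0]):
            top = votes[i].max()
            tied = np.where(votes[i] == top)[0]
            best[i] = tied[np.argmax(scores[i, tied])]
        return self.classes_[best]


def lssvm_fit(X, y, k: HybridKernel | None = None,
              gamma_reg: float = 10.0) -> LSSVMClassifier:
    """Functional wrapper over :class:`LSSVMClassifier` (hybrid kernel)."""
    k = k or HybridKernel()
    return LSSVMClassifier(kernel="hybrid", mix_weight=k.a, sigma2=k.sigma2,
                           degree=k.order, gamma_reg=gamma_reg).fit(X, y)


class TunedLSSVMClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid-kernel LS-SVM whose (a, sigma2, gamma, order) are selected by
    PSO on inner cross-validation at fit time (see :func:`tune_lssvm`)."""

    def __init__(self, swarm_size: int = 6, iterations: int = 8,
                 folds: int = 3, random_state: int = 0):
        self.swarm_size = swarm_size
        self.iterations = iterations
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        cfg = PSOConfig(swarm_size=self.swarm_size,
                        iterations=self.iterations, seed=self.random_state)
        self.model_, self.best_params_ = tune_lssvm(X, y, cfg=cfg,
                                                    folds=self.folds)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)


def tune_lssvm(X, y, cfg: PSOConfig | None = None,
               bounds: dict | None = None, folds: int = 3):
    """PSO search over (a, log sigma2, log gamma, order) minimizing
    stratified k-fold CV error; returns (refit model, best params)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cfg = cfg or PSOConfig(swarm_size=10, iterations=15)
    bounds = bounds or {"a": (0.0, 1.0), "log_sigma2": (-3.0, 5.0),
                        "log_gamma": (-2.0, 5.0), "order": (1.0, 4.0)}
    box = [bounds["a"], bounds["log_sigma2"], bounds["log_gamma"],
           bounds["order"]]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))

    def decode(z) -> dict:
        return {"mix_weight": float(np.clip(z[0], 0, 1)),
                "sigma2": float(np.exp(z[1])),
                "gamma_reg": float(np.exp(z[2])),
                "degree": int(np.clip(round(z[3]), 1, 10))}

    def objective(z) -> float:
        params = decode(z)
        errs = []
        for tr, te in splits:
            try:
                model = LSSVMClassifier(kernel="hybrid", **params).fit(
                    X[tr], y[tr])
                errs.append(float(np.mean(model.predict(X[te]) != y[te])))
            except (ValueError, NumericalError):
                return np.inf
        return float(np.mean(errs))

    best_z, best_f, _ = pso_minimize(objective, box, cfg)
    params = decode(best_z)
    model = LSSVMClassifier(kernel="hybrid", **params).fit(X, y)
    logger.info("tuned LS-SVM params %s (CV error %.4f)", params, best_f)
    return model, params
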