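"""Strategy 3: empirical wavelet transform, differential entropy and
high-order fuzzy cognitive maps.

Each channel is boundary-padded (nearest-neighbour forecasting), decomposed
into adaptive spectral bands by a Meyer-type empirical wavelet filter bank,
and summarized by windowed differential-entropy (DE) time series.  A
high-order fuzzy cognitive map (HFCM) — a tanh-squashed linear recurrence
over ``h`` lags with the bands as nodes — is fitted to the DE series per
channel; the HFCM weights together with per-band DE statistics form the
feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError
from .trials import Trial, TrialSet, WindowPlan, plan_windows

logger = logging.getLogger(__name__)

__all__ = [
    "knn_pad",
    "ewt_boundaries",
    "EWTBank",
    "DecompositionResult",
    "ewt_decompose",
    "differential_entropy",
    "HFCM",
    "hfcm_predict",
    "hfcm_fit",
    "de_hfcm_ewt_features",
    "DEHFCMEWTFeatures",
]


# ---------------------------------------------------------------------------
# Boundary padding by nearest-neighbour forecasting
# ---------------------------------------------------------------------------

def knn_pad(x: np.ndarray, pad: int, k: int = 5) -> np.ndarray:
    """Extend both ends of ``x`` by ``pad`` samples of k-NN forecasts.

    Each appended sample is the mean successor of the ``k`` length-``k``
    history windows of ``x`` most similar (Euclidean) to the current end
    history.  The interior of the output equals ``x`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if pad > len(x):
        raise ValueError(f"pad {pad} exceeds series length {len(x)}")
    if k < 1 or len(x) <= k:
        raise ValueError("need len(x) > k >= 1")
    if pad == 0:
        return x.copy()

    def extend(series: np.ndarray) -> np.ndarray:
        n = len(series)
        windows = np.lib.stride_tricks.sliding_window_view(series[:-1], k)
        successors = series[k:]
        out = list(series)
        hist = np.array(out[-k:])
        for _ in range(pad):
            dist = np.linalg.norm(windows - hist, axis=1)
            nearest = np.argsort(dist, kind="stable")[:k]
            nxt = float(successors[nearest].mean())
            out.append(nxt)
            hist = np.array(out[-k:])
        return np.array(out[n:])

    right = extend(x)
    left = extend(x[::-1])[::-1]
    return np.concatenate([left, x, right])


# ---------------------------------------------------------------------------
# Empirical wavelet transform
# ---------------------------------------------------------------------------

def ewt_boundaries(x: np.ndarray, fs: float, n_bands: int | str = "auto",
                   rel_threshold: float = 0.10) -> np.ndarray:
    """Detect band boundaries from the magnitude spectrum.

    The smoothed FFT magnitude spectrum is scanned for local maxima (modes);
    the ``n_bands`` largest modes are kept (or, for ``"auto"``, all modes
    exceeding ``rel_threshold`` of the maximum) and each boundary is placed
    at the spectrum minimum between two adjacent retained modes.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("need at least 64 samples for boundary detection")
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    span = max(3, (len(mag) // 100) | 1)
    kernel = np.ones(span) / span
    smooth = np.convolve(mag, kernel, mode="same")
    peaks, props = sps.find_peaks(smooth, height=0)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
        props = {"peak_heights": np.array([smooth[peaks[0]]])}
    heights = props["peak_heights"]
    if n_bands == "auto":
        keep = peaks[heights >= rel_threshold * heights.max()]
    else:
        n_bands = int(n_bands)
        if n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if n_bands == 1:
            return np.array([])
        if len(peaks) < n_bands:
            raise ValueError(
                f"only {len(peaks)} spectral modes found; request fewer bands"
            )
        keep = peaks[np.argsort(heights)[::-1][:n_bands]]
    keep = np.sort(keep)
    bounds = []
    for a, b in zip(keep[:-1], keep[1:]):
        valley = a + int(np.argmin(smooth[a:b + 1]))
        bounds.append(freqs[valley])
    return np.array(bounds)


def _meyer_beta(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35 - 84 * x + 70 * x**2 - 20 * x**3)


@dataclass
class EWTBank:
    """Meyer-type empirical wavelet filter bank on an FFT grid.

    ``filters[0]`` is the scaling (low-pass) function; subsequent rows are
    wavelets.  The construction is a tight frame: the squared responses sum
    to one on the whole grid.
    """

    boundaries: np.ndarray
    gamma: float
    filters: np.ndarray   # (n_bands, n_rfft), real-valued in [0, 1]
    freqs: np.ndarray

    def frame_identity_error(self) -> float:
        return float(np.max(np.abs((self.filters**2).sum(axis=0) - 1.0)))


@dataclass
class DecompositionResult:
    """Ordered components (plus residual for LMD) reconstructing the input."""

    components: list[np.ndarray]
    method: str
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.components, axis=0) + self.residual


def _build_bank(n: int, fs: float, boundaries: np.ndarray,
                gamma: float) -> EWTBank:
    nyq = fs / 2.0
    omega = np.sort(np.asarray(boundaries, dtype=float))
    if len(omega) and (omega[0] <= 0 or omega[-1] >= nyq):
        raise ValueError("boundaries must lie strictly inside (0, fs/2)")
    ext = np.concatenate([omega, [nyq]])
    for a, b in zip(ext[:-1], ext[1:]):
        if gamma >= (b - a) / (b + a):
            raise ValueError(
                f"gamma={gamma} too large: transition zones of boundaries "
                f"{a:.3g} and {b:.3g} Hz overlap"
            )
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    n_bands = len(omega) + 1
    filters = np.zeros((n_bands, len(freqs)))

    def rise(f, w):  # sin transition entering a band at boundary w
        tau = gamma * w
        out = np.zeros_like(f)
        out[f >= w + tau] = 1.0
        zone = (f > w - tau) & (f < w + tau)
        out[zone] = np.sin(np.pi / 2 * _meyer_beta((f[zone] - w + tau) / (2 * tau)))
        return out

    def fall(f, w):  # cos transition leaving a band at boundary w
        tau = gamma * w
        out = np.zeros_like(f)
        out[f <= w - tau] = 1.0
        zone = (f > w - tau) & (f < w + tau)
        out[zone] = np.cos(np.pi / 2 * _meyer_beta((f[zone] - w + tau) / (2 * tau)))
        return out

    if n_bands == 1:
        filters[0] = 1.0
    else:
        filters[0] = fall(freqs, omega[0])
        for i in range(1, n_bands - 1):
            filters[i] = rise(freqs, omega[i - 1]) * fall(freqs, omega[i])
        filters[-1] = rise(freqs, omega[-1])
    return EWTBank(boundaries=omega, gamma=gamma, filters=filters, freqs=freqs)


def ewt_decompose(x: np.ndarray, fs: float, boundaries: np.ndarray,
                  gamma: float = 0.2) -> tuple[DecompositionResult, EWTBank]:
    """Decompose ``x`` into spectral-band components.

    The bank's squared responses form a partition of unity (tight frame),
    and each component is the inverse FFT of the spectrum multiplied by one
    squared response, so the components sum back to ``x`` exactly up to FFT
    round-off.
    """
    x = np.asarray(x, dtype=float)
    bank = _build_bank(len(x), fs, boundaries, gamma)
    X = np.fft.rfft(x)
    comps = [np.fft.irfft(X * f**2, n=len(x)) for f in bank.filters]
    result = DecompositionResult(components=comps, method="EWT",
                                 residual=np.zeros_like(x))
    return result, bank


# ---------------------------------------------------------------------------
# Differential entropy
# ---------------------------------------------------------------------------

def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy ``0.5 ln(2 pi e var(x))`` in nats,
    with the variance taken as the mean squared deviation (energy / N)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    var = float(np.var(x))
    if var <= 0:
        raise DegenerateInputError("constant series has divergent entropy")
    return 0.5 * np.log(2 * np.pi * np.e * var)


# ---------------------------------------------------------------------------
# High-order fuzzy cognitive map
# ---------------------------------------------------------------------------

@dataclass
class HFCM:
    """Tanh-squashed linear recurrence over ``order`` lags of node states.

    ``weights[i, j, l]`` is the influence of node j at lag l+1 on node i;
    ``bias[i]`` the per-node offset.  Predicted states lie in (-1, 1).
    """

    weights: np.ndarray   # (Nc, Nc, order)
    bias: np.ndarray      # (Nc,)

    @property
    def order(self) -> int:
        return self.weights.shape[2]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def hfcm_predict(model: HFCM, history: np.ndarray) -> np.ndarray:
    """One-step state prediction from the last ``order`` state vectors.

    ``history`` has shape (>= order, Nc) with the most recent state in the
    last row; lag l uses ``history[-l]``.
    """
    history = np.atleast_2d(np.asarray(history, dtype=float))
    h = model.order
    if history.shape[0] < h:
        raise ValueError(f"need at least {h} past states, got {history.shape[0]}")
    if history.shape[1] != model.n_nodes:
        raise ValueError("history width does not match node count")
    pre = model.bias.copy()
    for lag in range(1, h + 1):
        pre = pre + model.weights[:, :, lag - 1] @ history[-lag]
    return np.tanh(pre)


def _hfcm_design(series: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    T, nc = series.shape
    rows, targets = [], []
    for t in range(h - 1, T - 1):
        lagged = [series[t - lag + 1] for lag in range(1, h + 1)]
        rows.append(np.concatenate(lagged))
        targets.append(series[t + 1])
    return np.array(rows), np.array(targets)


def hfcm_fit(series_matrix, h: int, ridge: float = 1e-3) -> HFCM:
    """Fit HFCM weights by ridge least squares on the artanh-linearized
    recurrence.

    ``series_matrix`` is a (T, Nc) state matrix with entries in (-1, 1), or
    a list of such trajectories (pooled into one regression).  The bias
    column is not penalized, so as ridge grows the weights shrink to zero
    and the bias tends to the mean artanh target.
    """
    if isinstance(series_matrix, np.ndarray) and series_matrix.ndim == 2:
        series_list = [series_matrix]
    else:
        series_list = [np.asarray(s, dtype=float) for s in series_matrix]
    nc = series_list[0].shape[1]
    designs, targets = [], []
    for s in series_list:
        if s.shape[0] < h + 2:
            raise ValueError(f"trajectory too short for order {h}")
        d, t = _hfcm_design(s, h)
        designs.append(d)
        targets.append(t)
    X = np.vstack(designs)
    Y = np.vstack(targets)
    clipped = np.clip(Y, -1 + 1e-6, 1 - 1e-6)
    if np.any(np.abs(Y) >= 1):
        logger.info("states at +-1 clipped before artanh")
    Z = np.arctanh(clipped)
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    penalty = np.eye(Xb.shape[1]) * ridge
    penalty[-1, -1] = 0.0  # bias unpenalized
    coef = np.linalg.solve(Xb.T @ Xb + penalty, Xb.T @ Z)
    weights = np.empty((nc, nc, h))
    for lag in range(h):
        weights[:, :, lag] = coef[lag * nc:(lag + 1) * nc, :].T
    return HFCM(weights=weights, bias=coef[-1, :].copy())


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

_ABLATIONS = {
    "full": {"de", "fcm", "ewt"},
    "de": {"de"},
    "fcm": {"fcm"},
    "ewt": {"ewt"},
    "de-fcm": {"de", "fcm"},
    "de-ewt": {"de", "ewt"},
    "fcm-ewt": {"fcm", "ewt"},
}


def _windowed_de(x: np.ndarray, plan: WindowPlan) -> np.ndarray:
    out = np.empty(plan.n_intervals)
    for i, sl in enumerate(plan.slices()):
        seg = x[sl]
        var = float(np.var(seg))
        out[i] = 0.5 * np.log(2 * np.pi * np.e * max(var, 1e-300))
    return out


def _rescale_unit(v: np.ndarray, lim: float = 0.9) -> np.ndarray:
    span = np.ptp(v)
    if span <= 0:
        return np.zeros_like(v)
    return (2.0 * (v - v.min()) / span - 1.0) * lim


def de_hfcm_ewt_features(trial: Trial, n_bands: int = 5, gamma: float = 0.2,
                         h: int = 2, window_plan: WindowPlan | None = None,
                         pad: int | None = None, knn_k: int = 5,
                         ridge: float = 1e-3,
                         ablation: str = "full") -> np.ndarray:
    """Feature vector for one trial (see module docstring).

    With the full configuration the length is
    ``n_channels * (n_bands**2 * h + n_bands + 2 * n_bands)``
    (HFCM weights + biases, then DE mean and SD per band).
    """
    if ablation not in _ABLATIONS:
        raise ValueError(f"unknown ablation {ablation!r}; "
                         f"choose from {sorted(_ABLATIONS)}")
    parts = _ABLATIONS[ablation]
    n = trial.n_samples
    fs = trial.fs
    if window_plan is None:
        w = max(16, n // 10)
        window_plan = plan_windows(n, w, max(1, w // 2))
    if pad is None:
        pad = window_plan.window_length
    feats: list[np.ndarray] = []
    for ch in range(trial.n_channels):
        x = trial.samples[:, ch]
        if "ewt" in parts:
            padded = knn_pad(x, pad, k=knn_k)
            try:
                bounds = ewt_boundaries(padded, fs, n_bands)
            except ValueError:
                # broad/flat spectrum: fall back to evenly spaced boundaries
                lo, hi = 0.02 * fs, 0.45 * fs
                bounds = np.linspace(lo, hi, n_bands + 1)[1:-1]
                logger.debug("channel %d: uniform boundary fallback", ch)
            bounds = np.unique(bounds)
            # gamma is subject to the admissibility bound of the detected
            # boundary layout (transition zones must not overlap)
            ext = np.concatenate([bounds, [fs / 2.0]])
            ratios = [(b - a) / (b + a) for a, b in zip(ext[:-1], ext[1:])]
            gamma_eff = min(gamma, 0.5 * min(ratios)) if ratios else gamma
            result, _bank = ewt_decompose(padded, fs, bounds, max(gamma_eff, 0.0))
            comps = [c[pad:pad + n] for c in result.components]
        else:
            comps = [x]
        de_series = np.column_stack([_windowed_de(c, window_plan) for c in comps])
        if "fcm" in parts:
            states = np.column_stack([_rescale_unit(de_series[:, j])
                                      for j in range(de_series.shape[1])])
            model = hfcm_fit(states, h, ridge=ridge)
            feats.append(model.weights.ravel())
            feats.append(model.bias)
        if "de" in parts:
            feats.append(de_series.mean(axis=0))
            feats.append(de_series.std(axis=0))
        if not parts & {"de", "fcm"}:
            energies = np.array([float(np.sum(c**2)) for c in comps])
            total = energies.sum() + 1e-300
            feats.append(energies / total)
            feats.append(np.log(energies + 1e-300))
    return np.concatenate(feats)


class DEHFCMEWTFeatures(BaseEstimator, TransformerMixin):
    """TrialSet -> DE/HFCM/EWT feature matrix (one row per trial)."""

    def __init__(self, n_bands: int = 5, gamma: float = 0.2, order: int = 2,
                 ablation: str = "full", knn_k: int = 5, ridge: float = 1e-3):
        self.n_bands = n_bands
        self.gamma = gamma
        self.order = order
        self.ablation = ablation
        self.knn_k = knn_k
        self.ridge = ridge

    def fit(self, X, y=None):
        return self

    def transform(self, X: TrialSet | list[Trial]) -> np.ndarray:
        return np.array([
            de_hfcm_ewt_features(t, n_bands=self.n_bands, gamma=self.gamma,
                                 h=self.order, knn_k=self.knn_k,
                                 ridge=self.ridge, ablation=self.ablation)
            for t in X
        ])
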