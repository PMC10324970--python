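"""Strategy 1: dynamic graph construction and graph-entropy features.

For each time interval of a trial, a weighted graph over the channels is
built.  Edge weights are *spurious correlation coefficients*: 1 when the
Granger causality test between the two channels does not reject the null
(no causal relation), and ``1 - |PCC|`` when it does.  Entropy of the
resulting weighted graphs (per vertex and per interval) forms the feature
vector handed to ordinary classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError
from .trials import Trial, TrialSet, WindowPlan, plan_windows

__all__ = [
    "CausalityResult",
    "SpuriousGraph",
    "DynamicGraph",
    "EntropyFeatures",
    "granger_causal",
    "spurious_coefficient",
    "build_dynamic_graph",
    "vertex_entropy",
    "graph_entropy",
    "entropy_features",
    "GraphEntropyFeatures",
    "DynamicGraphWeights",
]


@dataclass(frozen=True)
class CausalityResult:
    """Outcome of one directed Granger test: p-value, binary indicator,
    and the autoregressive lag order used."""

    prob: float
    C: int
    lag: int


@dataclass(frozen=True)
class SpuriousGraph:
    """Weighted adjacency over channels for one time interval.

    Entries lie in [0, 1]; the diagonal is zero by convention.
    """

    R: np.ndarray
    interval_index: int

    @property
    def n_vertices(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class DynamicGraph:
    """Ordered sequence of interval graphs sharing a vertex set."""

    graphs: tuple[SpuriousGraph, ...]

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_vertices(self) -> int:
        return self.graphs[0].n_vertices


@dataclass(frozen=True)
class EntropyFeatures:
    """Graph entropies per interval plus vertex entropies (T x n_channels)."""

    per_interval: np.ndarray
    per_vertex: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        """Fixed-length feature vector: interval block then vertex block."""
        return np.concatenate([self.per_interval, self.per_vertex.ravel()])


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def _lag_design(y: np.ndarray, x: np.ndarray | None, lag: int,
                burn: int) -> tuple[np.ndarray, np.ndarray]:
    """Regression design for y[t] on a constant, own lags and (optionally)
    lags of x, dropping the first ``burn`` samples."""
    n = len(y)
    rows = np.arange(burn, n)
    cols = [np.ones(len(rows))]
    for l in range(1, lag + 1):
        cols.append(y[rows - l])
    if x is not None:
        for l in range(1, lag + 1):
            cols.append(x[rows - l])
    return np.column_stack(cols), y[rows]


def _ssr(design: np.ndarray, target: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid)


def _select_lag_bic(y: np.ndarray, max_lag: int) -> int:
    """BIC order selection on the restricted (own-lags-only) autoregression.

    Using only the target series makes the selection independent of the
    candidate cause, which preserves the F-test's type-I calibration.
    """
    n_eff = len(y) - max_lag
    best_lag, best_bic = 1, np.inf
    for lag in range(1, max_lag + 1):
        design, target = _lag_design(y, None, lag, burn=max_lag)
        ssr = _ssr(design, target)
        bic = n_eff * np.log(max(ssr, 1e-300) / n_eff) + (lag + 1) * np.log(n_eff)
        if bic < best_bic:
            best_bic, best_lag = bic, lag
    return best_lag


def granger_causal(x: np.ndarray, y: np.ndarray, max_lag: int = 8,
                   alpha: float = 0.05, lag: int | None = None) -> CausalityResult:
    """Directed Granger causality test x -> y.

    Fits the restricted OLS (y on its own lags) and the unrestricted OLS
    (y on own lags plus lags of x) and compares their sums of squared
    residuals with an F-test::

        F = ((SSR_r - SSR_u) / lag) / (SSR_u / (n - 2 lag - 1))

    The lag order is selected by BIC over ``1..max_lag`` on the restricted
    model unless ``lag`` is given explicitly.  The binary indicator ``C``
    is 1 iff the p-value is below ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < 10 * max_lag:
        raise ValueError(f"series too short: need >= {10 * max_lag} samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant series has no causal structure")
    if lag is None:
        lag = _select_lag_bic(y, max_lag)
    prob = _granger_pvalue(x, y, lag)
    return CausalityResult(prob=prob, C=int(prob < alpha), lag=lag)


def _granger_pvalue(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    design_r, target = _lag_design(y, None, lag, burn=lag)
    design_u, _ = _lag_design(y, x, lag, burn=lag)
    ssr_r = _ssr(design_r, target)
    ssr_u = _ssr(design_u, target)
    n_eff = len(target)
    df_denom = n_eff - 2 * lag - 1
    if df_denom <= 0:
        raise ValueError("series too short for the selected lag order")
    if ssr_u <= 0:
        return 0.0
    f_stat = ((ssr_r - ssr_u) / lag) / (ssr_u / df_denom)
    return float(stats.f.sf(max(f_stat, 0.0), lag, df_denom))


def spurious_coefficient(c: CausalityResult, pcc: float) -> float:
    """Edge weight from a causality indicator and a Pearson correlation:
    1 when no causality; ``1 - |PCC|`` otherwise."""
    if abs(pcc) > 1 + 1e-12:
        raise ValueError(f"|PCC| must be <= 1, got {pcc}")
    if c.C == 0:
        return 1.0
    return float(c.C - min(abs(pcc), 1.0))


# ---------------------------------------------------------------------------
# Dynamic graph
# ---------------------------------------------------------------------------

def _decimate_trial(samples: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    if target_fs is None or fs <= target_fs:
        return samples, fs
    factor = int(round(fs / target_fs))
    if factor < 2 or abs(fs / factor - target_fs) > 1e-6:
        return samples, fs
    out = sps.decimate(samples, factor, axis=0, zero_phase=True)
    return out, fs / factor


def build_dynamic_graph(trial: Trial, plan: WindowPlan, max_lag: int = 8,
                        alpha: float = 0.05, edge_mode: str = "mean",
                        decimate_to: float | None = None) -> DynamicGraph:
    """Per-interval spurious-correlation graphs for one trial.

    For each interval and each ordered channel pair the directed Granger
    test and the Pearson correlation are computed on the windowed segments;
    the undirected edge weight is the mean (or min) of the two directed
    spurious coefficients.  ``edge_mode='directed'`` keeps the asymmetric
    matrix.  The restricted-model fit and BIC lag choice depend only on the
    target channel, so they are computed once per (interval, channel).
    """
    if edge_mode not in ("mean", "min", "directed"):
        raise ValueError("edge_mode must be one of mean|min|directed")
    samples, _fs = _decimate_trial(trial.samples, trial.fs, decimate_to)
    n_ch = samples.shape[1]
    graphs = []
    for t_idx, sl in enumerate(plan.slices()):
        seg = samples[sl]
        lags = np.empty(n_ch, dtype=int)
        ssr_r = np.empty(n_ch)
        for j in range(n_ch):
            if np.ptp(seg[:, j]) == 0:
                raise DegenerateInputError(
                    f"interval {t_idx}, channel {j}: constant segment"
                )
            lags[j] = _select_lag_bic(seg[:, j], max_lag)
            design, target = _lag_design(seg[:, j], None, lags[j], burn=lags[j])
            ssr_r[j] = _ssr(design, target)
        corr = np.corrcoef(seg, rowvar=False)
        S = np.zeros((n_ch, n_ch))  # directed spurious coefficient i -> j
        for j in range(n_ch):
            lag = int(lags[j])
            design_r, target = _lag_design(seg[:, j], None, lag, burn=lag)
            n_eff = len(target)
            df_denom = n_eff - 2 * lag - 1
            for i in range(n_ch):
                if i == j:
                    continue
                design_u, _ = _lag_design(seg[:, j], seg[:, i], lag, burn=lag)
                ssr_u = _ssr(design_u, target)
                if ssr_u <= 0:
                    prob = 0.0
                else:
                    f_stat = ((ssr_r[j] - ssr_u) / lag) / (ssr_u / df_denom)
                    prob = float(stats.f.sf(max(f_stat, 0.0), lag, df_denom))
                c = CausalityResult(prob=prob, C=int(prob < alpha), lag=lag)
                S[i, j] = spurious_coefficient(c, corr[i, j])
        if edge_mode == "directed":
            R = S
        elif edge_mode == "mean":
            R = 0.5 * (S + S.T)
        else:
            R = np.minimum(S, S.T)
        np.fill_diagonal(R, 0.0)
        graphs.append(SpuriousGraph(R=R, interval_index=t_idx))
    return DynamicGraph(graphs=tuple(graphs))


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def _neg_wlogw(w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w)
    pos = w > 0
    out[pos] = -w[pos] * np.log(w[pos])
    return out


def vertex_entropy(g: SpuriousGraph, i: int) -> float:
    """Entropy of vertex i: ``-sum_j R(i,j) ln R(i,j)`` over incident edges,
    with the limit convention ``0 ln 0 := 0`` (natural log)."""
    if not (0 <= i < g.n_vertices):
        raise ValueError(f"vertex index {i} out of range")
    row = np.delete(g.R[i], i)
    return float(_neg_wlogw(row).sum())


def graph_entropy(g: SpuriousGraph) -> float:
    """Graph entropy: sum of vertex entropies over all vertices."""
    R = g.R.copy()
    np.fill_diagonal(R, 0.0)
    return float(_neg_wlogw(R).sum())


def entropy_features(dg: DynamicGraph) -> EntropyFeatures:
    """Per-interval graph entropies plus per-vertex entropies.

    The flattened vector has length ``T * (1 + n_channels)``.
    """
    T = len(dg)
    n = dg.n_vertices
    per_interval = np.empty(T)
    per_vertex = np.empty((T, n))
    for t, g in enumerate(dg.graphs):
        per_interval[t] = graph_entropy(g)
        for i in range(n):
            per_vertex[t, i] = vertex_entropy(g, i)
    return EntropyFeatures(per_interval=per_interval, per_vertex=per_vertex)


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------

class _DynamicGraphBase(BaseEstimator, TransformerMixin):
    def __init__(self, window_s: float = 0.25, hop_s: float | None = None,
                 max_lag: int = 8, alpha: float = 0.05,
                 edge_mode: str = "mean", decimate_to: float | None = 1000.0):
        self.window_s = window_s
        self.hop_s = hop_s
        self.max_lag = max_lag
        self.alpha = alpha
        self.edge_mode = edge_mode
        self.decimate_to = decimate_to

    def fit(self, X, y=None):
        return self

    def _graph(self, trial: Trial) -> DynamicGraph:
        samples, fs = _decimate_trial(trial.samples, trial.fs, self.decimate_to)
        w = int(round(self.window_s * fs))
        hop = w if self.hop_s is None else int(round(self.hop_s * fs))
        plan = plan_windows(samples.shape[0], w, hop)
        dec_trial = Trial(samples=samples, fs=fs, label=trial.label,
                          subject=trial.subject)
        return build_dynamic_graph(dec_trial, plan, max_lag=self.max_lag,
                                   alpha=self.alpha, edge_mode=self.edge_mode,
                                   decimate_to=None)


class GraphEntropyFeatures(_DynamicGraphBase):
    """Trial -> graph-entropy feature vector of length ``T * (1 + n_channels)``.

    The analysis signal is decimated (anti-aliased) to ``decimate_to`` Hz to
    keep the per-window OLS fits well conditioned; the default window is a
    quarter second with non-overlapping hops.
    """

    def transform(self, X: TrialSet | list[Trial]) -> np.ndarray:
        return np.array([entropy_features(self._graph(t)).vector for t in X])


class DynamicGraphWeights(_DynamicGraphBase):
    """Trial -> flattened upper-triangular edge weights per interval
    (the raw dynamic-graph representation, without the entropy stage)."""

    def transform(self, X: TrialSet | list[Trial]) -> np.ndarray:
        rows = []
        for t in X:
            dg = self._graph(t)
            iu = np.triu_indices(dg.n_vertices, k=1)
            rows.append(np.concatenate([g.R[iu] for g in dg.graphs]))
        return np.array(rows)
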