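"""Trial data model, CSV I/O, windowing and ICA artifact removal.

A *trial* is one multichannel surface-EMG recording (samples x channels) with a
sampling rate and an integer gesture label.  A :class:`TrialSet` is an ordered,
labelled collection of trials sharing a sampling rate, and is the universal
input to every feature-extraction strategy in this package.

On disk a trial set is one headerless numeric CSV per trial (rows = samples,
columns = channels) plus a manifest CSV with columns
``trial_path,subject_id,label``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import FormatError, NumericalError, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "TrialSet",
    "WindowPlan",
    "plan_windows",
    "read_trialset",
    "write_trialset",
    "ica_preprocess",
    "ICACleaner",
]


@dataclass
class Trial:
    """One multichannel recording with its gesture label.

    Parameters
    ----------
    samples : ndarray of shape (n_samples, n_channels)
        Raw signal values (volts or arbitrary units); must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : int
        0-based class index.
    subject : str
        Opaque subject identifier.
    """

    samples: np.ndarray
    fs: float
    label: int
    subject: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise StructureError("trial samples must be a 2-D (samples x channels) array")
        n_samples, n_channels = self.samples.shape
        if n_samples < 2 or n_channels < 1:
            raise StructureError(
                f"trial needs >= 2 samples and >= 1 channel, got {self.samples.shape}"
            )
        if not np.isfinite(self.samples).all():
            raise StructureError("trial contains non-finite sample values")
        if not self.fs > 0:
            raise StructureError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class TrialSet:
    """Ordered collection of trials with a shared sampling rate."""

    trials: list[Trial]
    n_classes: int
    channel_names: Sequence[str] | None = None
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trials:
            fs0 = self.trials[0].fs
            nch0 = self.trials[0].n_channels
            for i, tr in enumerate(self.trials):
                if tr.fs != fs0:
                    raise StructureError(f"trial {i}: fs {tr.fs} != {fs0}")
                if tr.n_channels != nch0:
                    raise StructureError(
                        f"trial {i}: {tr.n_channels} channels, expected {nch0}"
                    )
                if not (0 <= tr.label < self.n_classes):
                    raise StructureError(
                        f"trial {i}: label {tr.label} outside [0, {self.n_classes})"
                    )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window geometry over a trial.

    The i-th window covers the half-open sample range
    ``[i * hop, i * hop + window_length)``; ``n_intervals`` (T) is
    ``floor((n_samples - window_length) / hop) + 1``.
    """

    window_length: int
    hop: int
    n_intervals: int

    def slices(self) -> list[slice]:
        return [
            slice(i * self.hop, i * self.hop + self.window_length)
            for i in range(self.n_intervals)
        ]


def plan_windows(n_samples: int, window_length: int, hop: int) -> WindowPlan:
    """Plan non-ragged sliding windows over a signal of length ``n_samples``."""
    if window_length < 2:
        raise ValueError(f"window_length must be >= 2, got {window_length}")
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    if window_length > n_samples:
        raise ValueError(
            f"window_length {window_length} exceeds signal length {n_samples}"
        )
    n_intervals = (n_samples - window_length) // hop + 1
    return WindowPlan(window_length=window_length, hop=hop, n_intervals=n_intervals)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _load_trial_csv(path: Path) -> np.ndarray:
    if not path.exists():
        raise IOError(f"trial file not found: {path}")
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path}: row {lineno} has {len(parts)} columns, expected {width}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno} is not numeric: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: empty trial file")
    return np.array(rows, dtype=float)


def read_trialset(manifest_path: str | Path, fs: float = 4000.0) -> TrialSet:
    """Load a trial set from a manifest CSV.

    Labels found in the manifest are mapped to a contiguous 0-based index in
    sorted order; the mapping is recorded on the returned set.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"trial_path", "subject_id", "label"}
    if not required.issubset(manifest.columns):
        raise FormatError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    if "fs" in manifest.columns and len(manifest):
        fs = float(manifest["fs"].iloc[0])
    raw_labels = sorted(manifest["label"].unique().tolist())
    mapping = {lab: i for i, lab in enumerate(raw_labels)}
    trials: list[Trial] = []
    n_channels = None
    for _, row in manifest.iterrows():
        path = manifest_path.parent / str(row["trial_path"])
        samples = _load_trial_csv(path)
        if n_channels is None:
            n_channels = samples.shape[1]
        elif samples.shape[1] != n_channels:
            raise StructureError(
                f"{path}: {samples.shape[1]} channels, expected {n_channels}"
            )
        trials.append(
            Trial(samples=samples, fs=fs, label=mapping[row["label"]],
                  subject=str(row["subject_id"]))
        )
    return TrialSet(trials=trials, n_classes=len(mapping) if mapping else 0,
                    label_mapping=mapping)


def write_trialset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write one CSV per trial plus a manifest; inverse of :func:`read_trialset`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, tr in enumerate(ts.trials):
        name = f"trial_{i:04d}.csv"
        np.savetxt(out_dir / name, tr.samples, delimiter=",", fmt="%.17g")
        records.append({"trial_path": name, "subject_id": tr.subject,
                        "label": tr.label, "fs": tr.fs})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(records, columns=["trial_path", "subject_id", "label", "fs"]).to_csv(
        manifest_path, index=False
    )
    return manifest_path


# ---------------------------------------------------------------------------
# ICA preprocessing
# ---------------------------------------------------------------------------

class ICACleaner(BaseEstimator, TransformerMixin):
    """Artifact removal by fixed-point ICA with symmetric decorrelation.

    Each trial is centered, whitened and unmixed by FastICA (parallel /
    symmetric decorrelation); independent components whose absolute excess
    kurtosis exceeds ``kurtosis_threshold`` are zeroed before re-projection
    to channel space.  With ``kurtosis_threshold = inf`` the transform is an
    identity up to reconstruction round-off, so the step degrades gracefully.

    Stateless across trials (ICA is per-trial); ``fit`` is a no-op.
    """

    def __init__(self, kurtosis_threshold: float = 8.0,
                 n_components: int | str = "all",
                 max_iter: int = 500, random_state: int = 0):
        self.kurtosis_threshold = kurtosis_threshold
        self.n_components = n_components
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def _clean_trial(self, trial: Trial) -> Trial:
        X = trial.samples
        if trial.n_channels == 1:
            logger.info("single-channel trial left unchanged by ICA")
            return trial
        if trial.n_samples <= trial.n_channels:
            raise ValueError(
                "ICA requires more samples than channels per trial"
            )
        n_comp = trial.n_channels if self.n_components == "all" else int(self.n_components)
        if n_comp > trial.n_channels:
            raise ValueError("n_components cannot exceed n_channels")
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc.T @ Xc) < n_comp:
            raise NumericalError(
                "rank-deficient channel covariance; request fewer components"
            )
        ica = FastICA(n_components=n_comp, whiten="unit-variance",
                      algorithm="parallel", max_iter=self.max_iter,
                      random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            with np.errstate(all="ignore"):
                S = ica.fit_transform(X)
        kurt = stats.kurtosis(S, axis=0, fisher=True)
        keep = np.abs(kurt) <= self.kurtosis_threshold
        if not keep.all():
            logger.info("ICA zeroed %d/%d components (|kurtosis| > %.3g)",
                        int((~keep).sum()), n_comp, self.kurtosis_threshold)
        S_clean = S * keep[np.newaxis, :]
        X_clean = ica.inverse_transform(S_clean)
        return Trial(samples=X_clean, fs=trial.fs, label=trial.label,
                     subject=trial.subject)

    def transform(self, X: TrialSet | Sequence[Trial]) -> TrialSet:
        trials = list(X)
        cleaned = [self._clean_trial(t) for t in trials]
        n_classes = X.n_classes if isinstance(X, TrialSet) else (
            int(max(t.label for t in trials)) + 1
        )
        return TrialSet(trials=cleaned, n_classes=n_classes)


def ica_preprocess(ts: TrialSet, n_components: int | str = "all",
                   kurtosis_threshold: float = 8.0, seed: int = 0) -> TrialSet:
    """Functional wrapper over :class:`ICACleaner`."""
    return ICACleaner(kurtosis_threshold=kurtosis_threshold,
                      n_components=n_components,
                      random_state=seed).transform(ts)
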