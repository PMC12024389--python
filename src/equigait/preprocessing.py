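"""Windowing and scaling: annotated streams → model-ready datasets.

The classifiers are trained on *pure* windows: fixed-length segments lying
entirely inside one single-gait bout, so each window carries exactly one
superclass label.  Streams recorded at 50 Hz are decimated to lower rates by
plain subsampling (all grid rates divide 50, so no interpolation is needed),
and windows are normalised per channel by removing the median and dividing by
the interquartile range fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import RobustScaler as _SkRobustScaler
from sklearn.utils.validation import check_is_fitted

from .io import UNLABELLED, AccelStream, SessionRecord, annotate

__all__ = [
    "SUPERCLASSES",
    "WINDOW_SIZES_S",
    "RATES_HZ",
    "WindowConfig",
    "WindowedDataset",
    "to_superclass",
    "window_length",
    "extract_pure_windows",
    "decimate",
    "RobustWindowScaler",
    "fit_scaler",
    "apply_scaler",
]

SUPERCLASSES: tuple[str, ...] = ("halt", "walk", "trot", "canter")

#: The grid of window sizes (seconds) and resampled rates (Hz) studied.
WINDOW_SIZES_S: tuple[float, ...] = (
    0.6, 1, 1.2, 1.6, 2, 2.2, 2.6, 3, 3.2, 3.6, 4, 5, 6,
)
RATES_HZ: tuple[int, ...] = (5, 10, 25, 50)


def to_superclass(activity: str) -> str:
    """Collapse one of the 11 fine activity labels to its gait superclass.

    ``halt`` maps to itself; collected/medium/normal variants of walk, trot
    and canter map to the bare gait name.
    """
    if activity == "halt":
        return "halt"
    parts = activity.split()
    if (
        len(parts) == 2
        and parts[0] in ("collected", "medium", "normal")
        and parts[1] in ("walk", "trot", "canter")
    ):
        return parts[1]
    raise ValueError(f"unknown activity label: {activity!r}")


def window_length(window_s: float, rate_hz: float) -> int:
    """Samples per window: ``window_s * rate_hz``, which must be integral."""
    n = window_s * rate_hz
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"window of {window_s}s at {rate_hz}Hz gives non-integer length {n}"
        )
    return int(round(n))


@dataclass
class WindowConfig:
    """Window extraction settings.

    ``overlap_fraction`` is the fraction of each window shared with its
    successor; 0 (the default) means non-overlapping windows, which avoids
    leaking shared samples between training and validation.
    """

    window_s: float
    rate_hz: float
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        window_length(self.window_s, self.rate_hz)  # validates integrality
        if 50 % self.rate_hz != 0:
            raise ValueError(f"rate {self.rate_hz} Hz does not divide 50 Hz")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return window_length(self.window_s, self.rate_hz)

    @property
    def step_samples(self) -> int:
        return max(1, int(round(self.n_samples * (1 - self.overlap_fraction))))


@dataclass
class WindowedDataset:
    """Pure windows plus labels and per-window provenance.

    ``X`` has shape (n, L, 3); ``y`` holds one superclass per window; ``meta``
    is a DataFrame with columns horse_id, location, session_id (length n).
    """

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    window_s: float = np.nan
    rate_hz: float = np.nan

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 3 or self.X.shape[2] != 3:
            raise ValueError("X must have shape (n, L, 3)")
        if not (len(self.X) == len(self.y) == len(self.meta)):
            raise ValueError("X, y and meta must have equal length")
        bad = set(self.y) - set(SUPERCLASSES)
        if bad:
            raise ValueError(f"labels outside superclass vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.y)

    @staticmethod
    def concat(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowedDataset(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
            window_s=parts[0].window_s,
            rate_hz=parts[0].rate_hz,
        )


def decimate(x: np.ndarray, from_hz: int, to_hz: int, axis: int = 0) -> np.ndarray:
    """Resample by keeping every ``from_hz // to_hz``-th sample from index 0.

    No filtering or interpolation: valid only when ``to_hz`` divides
    ``from_hz`` (the grid rates are all divisors of 50 Hz for this reason).
    A length-n input yields ``ceil(n / factor)`` samples.
    """
    if from_hz % to_hz != 0:
        raise ValueError(f"{to_hz} Hz does not divide {from_hz} Hz")
    factor = int(from_hz // to_hz)
    sl = [slice(None)] * np.ndim(x)
    sl[axis] = slice(None, None, factor)
    return np.asarray(x)[tuple(sl)]


def extract_pure_windows(
    session: SessionRecord, config: WindowConfig
) -> WindowedDataset:
    """Cut non-boundary-crossing single-gait windows from one session.

    The stream is decimated from its native rate to ``config.rate_hz`` first;
    samples are then labelled by superclass and grouped into maximal
    single-superclass runs (bouts).  A run of ``m`` samples yields
    ``floor((m - L) / step) + 1`` windows of length ``L``, none if ``m < L``;
    unlabelled spans yield nothing.
    """
    native = int(round(session.stream.rate_hz))
    if native % int(config.rate_hz) != 0:
        raise ValueError(
            f"stream rate {native} Hz not an integer multiple of {config.rate_hz} Hz"
        )
    t = decimate(session.stream.t, native, int(config.rate_hz))
    a = decimate(session.stream.a, native, int(config.rate_hz))
    sub = AccelStream(t=t, a=a, rate_hz=config.rate_hz)
    fine = annotate(sub, session.labels)
    supers = np.array(
        [to_superclass(lab) if lab != UNLABELLED else None for lab in fine],
        dtype=object,
    )

    L = config.n_samples
    step = config.step_samples
    windows, labels, starts = [], [], []
    # maximal single-superclass runs
    start = 0
    n = len(supers)
    for i in range(1, n + 1):
        if i == n or supers[i] != supers[start]:
            lab = supers[start]
            m = i - start
            if lab is not None and m >= L:
                for w0 in range(start, i - L + 1, step):
                    windows.append(a[w0 : w0 + L])
                    labels.append(lab)
                    starts.append(w0)
            start = i

    X = np.stack(windows) if windows else np.empty((0, L, 3))
    meta = pd.DataFrame(
        {
            "horse_id": [session.horse_id] * len(labels),
            "location": [session.location] * len(labels),
            "session_id": [session.session_id] * len(labels),
            "start_idx": starts,  # index into the decimated stream
        }
    )
    return WindowedDataset(
        X=X,
        y=np.array(labels, dtype=object),
        meta=meta,
        window_s=config.window_s,
        rate_hz=config.rate_hz,
    )


class RobustWindowScaler(TransformerMixin, BaseEstimator):
    """Per-channel robust scaling of windowed signals.

    Pools all samples of all training windows per channel, removes the median
    and divides by the interquartile range (25th–75th percentile).  A constant
    channel (zero IQR) is left unscaled (divisor 1).  Fit on the training
    split only and applied unchanged to validation data.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        sk = _SkRobustScaler().fit(X.reshape(-1, X.shape[2]))
        self.center_ = sk.center_
        self.scale_ = sk.scale_
        self.n_channels_ = X.shape[2]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = self._check(X)
        return (X - self.center_) / self.scale_

    # median/IQR aliases for reporting
    @property
    def median_(self):
        check_is_fitted(self)
        return self.center_

    @property
    def iqr_(self):
        check_is_fitted(self)
        return self.scale_

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected windows of shape (n, L, channels)")
        if X.shape[0] == 0:
            raise ValueError("empty window set")
        return X


def fit_scaler(train: WindowedDataset | np.ndarray) -> RobustWindowScaler:
    """Fit a :class:`RobustWindowScaler` on training windows."""
    X = train.X if isinstance(train, WindowedDataset) else train
    return RobustWindowScaler().fit(X)


def apply_scaler(
    scaler: RobustWindowScaler, data: WindowedDataset | np.ndarray
):
    """Apply fitted scaling; returns the same container type as the input."""
    if isinstance(data, WindowedDataset):
        return WindowedDataset(
            X=scaler.transform(data.X),
            y=data.y,
            meta=data.meta,
            window_s=data.window_s,
            rate_hz=data.rate_hz,
        )
    return scaler.transform(data)
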