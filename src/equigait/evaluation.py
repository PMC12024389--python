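"""The study procedure: grid search over (model × window × rate × location)
with a fixed validation horse, parameter selection rules, and horse-exclusive
leave-one-subject-out cross-validation (LOSOCV).

The full grid is 8 models × 13 window sizes × 4 rates × 4 sensor locations =
1664 configurations.  Each configuration trains on every horse except a
designated validation horse and is scored on that horse's windows.  General
parameters (e.g. the model) are selected by *average* accuracy across all
configurations sharing the value; parameters dependent on an already-fixed
choice (e.g. the rate for a given model) by *maximum* accuracy.  The selected
configuration is then validated with LOSOCV: each sufficiently represented
horse serves once as the entire validation set, with all of its sessions
removed from training; horses below a minimum data share are never validated
on but always remain in training.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UNLABELLED, LOCATIONS, SessionRecord, annotate
from .metrics import accuracy, confusion_matrix, macro_f1
from .models import ARCH_IDS, TrainConfig, train_model
from .preprocessing import (
    RATES_HZ,
    WINDOW_SIZES_S,
    WindowConfig,
    WindowedDataset,
    apply_scaler,
    extract_pure_windows,
    fit_scaler,
)

__all__ = [
    "GridAxes",
    "GridResult",
    "CVReport",
    "enumerate_grid",
    "fixed_validation_split",
    "run_grid",
    "grid_results_frame",
    "select_optimal",
    "losocv",
    "losocv_splits",
    "aggregate_folds",
    "config_seed",
]


@dataclass
class GridAxes:
    """Axes of the configuration grid; defaults are the full study grid."""

    models: tuple = ARCH_IDS
    window_sizes: tuple = WINDOW_SIZES_S
    rates: tuple = RATES_HZ
    locations: tuple = LOCATIONS

    def __post_init__(self) -> None:
        for name in ("models", "window_sizes", "rates", "locations"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValueError(f"axis {name!r} is empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"axis {name!r} has duplicates")
            setattr(self, name, vals)


@dataclass
class GridResult:
    """Validation metrics for one configuration (percent scale)."""

    arch: str
    window_s: float
    rate_hz: float
    location: str
    val_accuracy: float = np.nan
    val_f1: float = np.nan
    n_train: int = 0
    n_val: int = 0
    error: str | None = None

    @property
    def config(self):
        return (self.arch, self.window_s, self.rate_hz, self.location)


@dataclass
class CVReport:
    """LOSOCV outcome: per-fold metrics and unweighted fold means."""

    folds: list  # (horse_id, accuracy, f1)
    excluded_horses: list  # (horse_id, fraction_of_samples)
    mean_accuracy: float
    mean_f1: float
    mean_accuracy_excluding: dict
    config: tuple = ()


def enumerate_grid(axes: GridAxes) -> list[tuple]:
    """Cartesian product in deterministic (model, window, rate, location) order."""
    return [
        (m, w, r, loc)
        for m in axes.models
        for w in axes.window_sizes
        for r in axes.rates
        for loc in axes.locations
    ]


def fixed_validation_split(
    cohort: list[SessionRecord], held_out_horse: str
) -> tuple[list[SessionRecord], list[SessionRecord]]:
    """All sessions of one horse become validation; the rest train."""
    horses = {s.horse_id for s in cohort}
    if held_out_horse not in horses:
        raise ValueError(f"horse {held_out_horse!r} not in cohort {sorted(horses)}")
    if len(horses) < 2:
        raise ValueError("cannot split: held-out horse is the only horse")
    train = [s for s in cohort if s.horse_id != held_out_horse]
    val = [s for s in cohort if s.horse_id == held_out_horse]
    return train, val


def config_seed(master_seed: int, config: tuple) -> int:
    """Stable per-configuration seed (< 2^31), order-independent across the grid."""
    key = f"{master_seed}|" + "|".join(str(c) for c in config)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _windows_for(
    sessions: list[SessionRecord], window_s: float, rate_hz: float, location: str
) -> WindowedDataset | None:
    parts = [
        extract_pure_windows(s, WindowConfig(window_s, rate_hz))
        for s in sessions
        if s.location == location
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return None
    return WindowedDataset.concat(parts)


def _evaluate_config(
    train_sessions, val_sessions, arch, window_s, rate_hz, location, train_config
) -> GridResult:
    res = GridResult(arch, window_s, rate_hz, location)
    train_ds = _windows_for(train_sessions, window_s, rate_hz, location)
    val_ds = _windows_for(val_sessions, window_s, rate_hz, location)
    if train_ds is None or val_ds is None:
        res.error = "no windows extracted for this configuration"
        return res
    scaler = fit_scaler(train_ds)
    train_ds = apply_scaler(scaler, train_ds)
    val_ds = apply_scaler(scaler, val_ds)
    clf = train_model(arch, train_ds, train_config)
    cm = confusion_matrix(val_ds.y, clf.predict(val_ds.X))
    res.val_accuracy = round(accuracy(cm), 2)
    res.val_f1 = round(macro_f1(cm), 2)
    res.n_train, res.n_val = len(train_ds), len(val_ds)
    return res


def run_grid(
    cohort: list[SessionRecord],
    axes: GridAxes,
    train_config: TrainConfig | None = None,
    validation_horse: str | None = None,
    verbose: bool = False,
) -> list[GridResult]:
    """Train and score every configuration against the fixed validation horse.

    Per-configuration seeds are derived from ``train_config.seed`` and the
    configuration tuple, so results do not depend on grid order.  A failing
    configuration is returned with its ``error`` set instead of aborting the
    sweep.
    """
    train_config = train_config or TrainConfig()
    if validation_horse is None:
        validation_horse = sorted({s.horse_id for s in cohort})[0]
    train_sessions, val_sessions = fixed_validation_split(cohort, validation_horse)
    results = []
    for cfg in enumerate_grid(axes):
        arch, w, r, loc = cfg
        cfg_tc = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            dropout_p=train_config.dropout_p,
            seed=config_seed(train_config.seed, cfg),
        )
        try:
            res = _evaluate_config(
                train_sessions, val_sessions, arch, w, r, loc, cfg_tc
            )
        except Exception as exc:  # flagged, never aborts the grid
            res = GridResult(arch, w, r, loc, error=f"{type(exc).__name__}: {exc}")
        if verbose:
            print(f"{cfg}: acc={res.val_accuracy} f1={res.val_f1} err={res.error}")
        results.append(res)
    return results


def grid_results_frame(results: list[GridResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "arch": [r.arch for r in results],
            "window_s": [r.window_s for r in results],
            "rate_hz": [r.rate_hz for r in results],
            "location": [r.location for r in results],
            "val_accuracy": [r.val_accuracy for r in results],
            "val_f1": [r.val_f1 for r in results],
            "n_train": [r.n_train for r in results],
            "n_val": [r.n_val for r in results],
            "error": [r.error for r in results],
        }
    )


_PARAM_FIELDS = {
    "model": "arch",
    "window_s": "window_s",
    "rate": "rate_hz",
    "location": "location",
}


def select_optimal(
    results: list[GridResult],
    parameter: str,
    mode: str = "average",
    fixed: dict | None = None,
):
    """Pick the best value of one grid parameter.

    ``mode="average"`` maximises the mean accuracy over all configurations
    sharing the value (for general parameters such as the model);
    ``mode="maximum"`` maximises the best single accuracy (for parameters
    dependent on an already-fixed choice), optionally restricted by ``fixed``
    (e.g. ``{"model": "conv_lstm"}``).  Ties break toward the value appearing
    first in grid order.
    """
    if mode not in ("average", "maximum"):
        raise ValueError("mode must be 'average' or 'maximum'")
    if parameter not in _PARAM_FIELDS:
        raise ValueError(f"parameter must be one of {sorted(_PARAM_FIELDS)}")
    field_name = _PARAM_FIELDS[parameter]
    pool = [r for r in results if r.error is None and np.isfinite(r.val_accuracy)]
    for key, val in (fixed or {}).items():
        pool = [r for r in pool if getattr(r, _PARAM_FIELDS[key]) == val]
    if not pool:
        raise ValueError("no successful results to select from")
    order: list = []
    groups: dict = {}
    for r in pool:
        v = getattr(r, field_name)
        if v not in groups:
            groups[v] = []
            order.append(v)
        groups[v].append(r.val_accuracy)
    agg = np.mean if mode == "average" else np.max
    scores = {v: float(agg(groups[v])) for v in order}
    return max(order, key=lambda v: scores[v])  # max is stable: first wins ties


def _horse_sample_fractions(cohort: list[SessionRecord]) -> pd.Series:
    """Per-horse share of labelled samples, pooled over sessions."""
    counts: dict[str, int] = {}
    for s in cohort:
        labs = annotate(s.stream, s.labels)
        counts[s.horse_id] = counts.get(s.horse_id, 0) + int(
            np.sum(labs != UNLABELLED)
        )
    ser = pd.Series(counts, dtype=float)
    return ser / ser.sum()


def losocv_splits(
    cohort: list[SessionRecord], min_fraction: float = 0.07
) -> tuple[list[tuple], list[tuple]]:
    """Fold plan for :func:`losocv`.

    Returns ``(folds, excluded)`` where ``folds`` is a list of
    ``(horse, train_sessions, val_sessions)`` — one per horse holding at
    least ``min_fraction`` of all labelled samples — and ``excluded`` lists
    ``(horse, fraction)`` for horses never used for validation (they stay in
    every training set).
    """
    if not 0 <= min_fraction < 0.5:
        raise ValueError("min_fraction must be in [0, 0.5)")
    horses = sorted({s.horse_id for s in cohort})
    if len(horses) < 3:
        raise ValueError("LOSOCV needs at least 3 horses")
    fractions = _horse_sample_fractions(cohort)
    eligible = [h for h in horses if fractions.get(h, 0.0) >= min_fraction]
    excluded = [
        (h, float(fractions.get(h, 0.0))) for h in horses if h not in eligible
    ]
    if len(eligible) < 2:
        raise ValueError("fewer than 2 horses eligible as validation folds")
    folds = []
    for horse in eligible:
        train_sessions, val_sessions = fixed_validation_split(cohort, horse)
        folds.append((horse, train_sessions, val_sessions))
    return folds, excluded


def losocv(
    cohort: list[SessionRecord],
    config: tuple,
    train_config: TrainConfig | None = None,
    min_fraction: float = 0.07,
) -> CVReport:
    """Horse-exclusive cross-validation of one configuration.

    ``config`` is ``(arch, window_s, rate_hz, location)``.  Horses holding
    less than ``min_fraction`` of all labelled samples never serve as a
    validation fold (too little data to score on) but stay in every training
    set.  Fold metrics are scored on the held-out horse's windows; the
    report's means are unweighted arithmetic means over folds, and
    ``mean_accuracy_excluding[h]`` re-averages with fold ``h`` dropped.
    """
    train_config = train_config or TrainConfig()
    arch, window_s, rate_hz, location = config
    splits, excluded = losocv_splits(cohort, min_fraction)

    folds = []
    for horse, train_sessions, val_sessions in splits:
        cfg_tc = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            dropout_p=train_config.dropout_p,
            seed=config_seed(train_config.seed, (*config, horse)),
        )
        train_ds = _windows_for(train_sessions, window_s, rate_hz, location)
        val_ds = _windows_for(val_sessions, window_s, rate_hz, location)
        if train_ds is None or val_ds is None:
            raise ValueError(f"no windows for fold {horse!r}")
        assert horse not in set(train_ds.meta["horse_id"])  # subject exclusivity
        scaler = fit_scaler(train_ds)
        clf = train_model(arch, apply_scaler(scaler, train_ds), cfg_tc)
        val_scaled = apply_scaler(scaler, val_ds)
        cm = confusion_matrix(val_scaled.y, clf.predict(val_scaled.X))
        folds.append((horse, round(accuracy(cm), 2), round(macro_f1(cm), 2)))

    accs = [a for _, a, _ in folds]
    f1s = [f for _, _, f in folds]
    mean_excluding = {
        h: aggregate_folds([a for hh, a, _ in folds if hh != h]) for h, _, _ in folds
    }
    return CVReport(
        folds=folds,
        excluded_horses=excluded,
        mean_accuracy=aggregate_folds(accs),
        mean_f1=aggregate_folds(f1s),
        mean_accuracy_excluding=mean_excluding,
        config=config,
    )


def aggregate_folds(values) -> float:
    """Unweighted arithmetic mean of fold percentages, to 2 decimals."""
    values = list(values)
    if not values:
        raise ValueError("no fold values to aggregate")
    return round(float(np.mean(values)), 2)
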