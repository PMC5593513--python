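"""Stage-restricted epoch selection and sliding-window connectivity dynamics.

Sleep runs are cut into contiguous stage epochs from the hypnogram; NREM-2
epochs longer than 50 volumes (strictly) are concatenated per condition, both
conditions truncated to the shared available length capped at 600 volumes,
and a 100-volume window slid in 50-volume steps (11 windows over 600 volumes
at TR 2.16 s, i.e. 216 s per window).  The per-window statistic is either the
connectivity index or the mean ROI-to-pattern Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BoldRun, SpatialPattern
from .connectivity_index import normalize_run, spatial_regression
from .synthetic_data import Hypnogram

__all__ = [
    "EpochSet",
    "WindowedSeries",
    "select_epochs",
    "longest_segment",
    "concatenate_and_truncate",
    "n_windows",
    "window_starts",
    "sliding_ci",
    "sliding_roi_fc",
    "window_robustness",
]


@dataclass
class EpochSet:
    """Sorted, disjoint half-open volume intervals of one stage family."""

    intervals: list[tuple[int, int]]
    stages: tuple[str, ...]
    min_len: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"bad interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = e

    @property
    def n_volumes(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def _stage_runs(labels: np.ndarray, stages: set[str]) -> list[tuple[int, int]]:
    """Maximal runs of volumes whose label is in ``stages``.

    Artifact volumes never qualify, so they always break a segment.
    """
    member = np.array([lab in stages and lab != "artifact" for lab in labels])
    runs = []
    start = None
    for i, m in enumerate(member):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(member)))
    return runs


def select_epochs(
    hypnogram: Hypnogram, stages, min_len: int = 50
) -> EpochSet:
    """Stage epochs of strictly more than ``min_len`` volumes.

    Returns an empty set (flagged by a warning) when nothing qualifies.
    """
    stages = {stages} if isinstance(stages, str) else set(stages)
    runs = [
        (s, e)
        for s, e in _stage_runs(np.asarray(hypnogram.labels), stages)
        if e - s > min_len
    ]
    if not runs:
        warnings.warn(
            f"no epochs of {sorted(stages)} longer than {min_len} volumes",
            RuntimeWarning,
        )
    return EpochSet(intervals=runs, stages=tuple(sorted(stages)), min_len=min_len)


def longest_segment(hypnogram: Hypnogram, stages) -> tuple[int, int] | None:
    """Longest contiguous qualifying segment; ties broken by earliest start."""
    stages = {stages} if isinstance(stages, str) else set(stages)
    runs = _stage_runs(np.asarray(hypnogram.labels), stages)
    if not runs:
        return None
    return max(runs, key=lambda r: (r[1] - r[0], -r[0]))


def concatenate_and_truncate(
    runs_by_condition: dict[str, BoldRun],
    epoch_sets: dict[str, EpochSet],
    cap: int = 600,
) -> dict[str, BoldRun]:
    """Concatenate each condition's epochs and equalize lengths.

    Within a condition, epoch volumes are concatenated in temporal order; all
    conditions are then truncated to the first ``min(available..., cap)``
    volumes so that between-condition contrasts are not confounded by
    differing amounts of data.
    """
    avail = {}
    for cond, run in runs_by_condition.items():
        es = epoch_sets[cond]
        for s, e in es.intervals:
            if e > run.n_volumes:
                raise ValueError(f"epoch ({s}, {e}) exceeds run length for {cond}")
        avail[cond] = es.n_volumes
    t_use = min(min(avail.values()), cap)
    if t_use < 1:
        raise ValueError("no volumes left after truncation")
    out = {}
    for cond, run in runs_by_condition.items():
        parts = [
            run.data[..., s:e] for s, e in epoch_sets[cond].intervals
        ]
        concat = np.concatenate(parts, axis=3)[..., :t_use]
        out[cond] = run.with_data(concat, session=f"{run.session or 'concat'}")
    return out


def n_windows(total: int, window: int, step: int) -> int:
    """floor((T - w) / s) + 1 complete windows; partial tails are discarded."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if total < window:
        raise ValueError(f"series of {total} volumes shorter than window {window}")
    return (total - window) // step + 1


def window_starts(total: int, window: int, step: int) -> np.ndarray:
    return np.arange(n_windows(total, window, step)) * step


@dataclass
class WindowedSeries:
    """Per-window statistic trajectory with its windowing metadata."""

    values: np.ndarray
    window: int
    step: int
    total_length: int
    starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def times(self, tr: float) -> np.ndarray:
        """Window-center times in seconds."""
        return (self.starts + self.window / 2.0) * tr


def sliding_ci(
    run: BoldRun,
    pattern: SpatialPattern,
    window: int = 100,
    step: int = 50,
    normalize: bool = True,
) -> WindowedSeries:
    """Connectivity index per sliding window.

    The spatial regression is per-volume, so eta(t) is computed once on the
    (normalized) full series and each window's CI is the variance of its eta
    values; a window equal to the whole series reproduces the full-series CI
    exactly.
    """
    if normalize:
        run = normalize_run(run)
    coef = spatial_regression(run, pattern)
    starts = window_starts(run.n_volumes, window, step)
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        eta = coef.eta[s : s + window]
        eta = eta[np.isfinite(eta)]
        if eta.size < 2:
            raise ValueError(f"window at {s} has too few defined eta values")
        values[i] = np.var(eta, ddof=1)
    return WindowedSeries(
        values=values,
        window=window,
        step=step,
        total_length=run.n_volumes,
        starts=starts,
    )


def sliding_roi_fc(
    run: BoldRun,
    roi_mask: np.ndarray,
    pattern_mask: np.ndarray,
    window: int = 100,
    step: int = 50,
) -> WindowedSeries:
    """Mean ROI-to-pattern Pearson correlation per sliding window.

    Target voxels are the pattern support minus the ROI voxels; per window the
    correlation between the ROI mean series and each target voxel series is
    averaged over targets.
    """
    targets = pattern_mask & ~roi_mask & run.mask
    if not targets.any():
        raise ValueError("no target voxels after excluding the ROI")
    roi = run.data[roi_mask & run.mask].mean(axis=0)
    y = run.data[targets]
    starts = window_starts(run.n_volumes, window, step)
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        rw = roi[s : s + window]
        yw = y[:, s : s + window]
        rc = rw - rw.mean()
        yc = yw - yw.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (yc @ rc) / denom, 0.0)
        values[i] = float(r.mean())
    return WindowedSeries(
        values=values,
        window=window,
        step=step,
        total_length=run.n_volumes,
        starts=starts,
    )


def window_robustness(
    run: BoldRun,
    pattern: SpatialPattern,
    sizes=range(50, 301, 50),
    normalize: bool = True,
) -> pd.DataFrame:
    """Early-vs-late CI contrast across window sizes.

    For each size n, the CI over the first n and the last n volumes of the
    series; sizes exceeding the series length are skipped with a warning.
    """
    if normalize:
        run = normalize_run(run)
    coef = spatial_regression(run, pattern)
    eta = coef.eta
    T = run.n_volumes
    rows = []
    for n in sizes:
        if n > T:
            warnings.warn(f"window size {n} exceeds series length {T}; skipped")
            continue
        first = eta[:n]
        last = eta[T - n :]
        rows.append(
            {
                "size": int(n),
                "first_ci": float(np.nanvar(first, ddof=1)),
                "last_ci": float(np.nanvar(last, ddof=1)),
            }
        )
    return pd.DataFrame(rows)
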