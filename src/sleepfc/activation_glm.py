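"""Task-activation GLM with speed-weighted block regressors.

The task regressor is a boxcar over the practice blocks whose per-block
height is proportional to the block's performance speed (normalized to unit
mean weight so equal speeds reproduce the plain boxcar), convolved with a
canonical double-gamma hemodynamic response function.  Six motion confounds
and an intercept complete the design.  Group difference maps (MSL - CTL) are
thresholded at Z > 3.5 to form the spatial patterns the connectivity index
consumes, and activation volume is broken down into cortical and subcortical
compartments in cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._inference import one_sample_t, t_to_z
from .containers import BoldRun, SpatialPattern, StatMap

__all__ = [
    "double_gamma_hrf",
    "DesignMatrix",
    "build_weighted_design",
    "fit_run_glm",
    "group_difference_pattern",
    "volume_breakdown",
]

# canonical double-gamma constants (SPM/Glover-style defaults):
# response gamma shape 6, undershoot gamma shape 16, both scale 1 s,
# undershoot ratio 1/6
HRF_PEAK_SHAPE = 6.0
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_SCALE = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical difference-of-gammas kernel sampled at TR, peak-normalized to 1."""
    if tr <= 0:
        raise ValueError("tr must be > 0")
    t = np.arange(0.0, duration + 1e-9, tr)
    h = stats.gamma.pdf(t, HRF_PEAK_SHAPE, scale=HRF_SCALE)
    h = h - HRF_UNDERSHOOT_RATIO * stats.gamma.pdf(
        t, HRF_UNDERSHOOT_SHAPE, scale=HRF_SCALE
    )
    return h / h.max()


@dataclass
class DesignMatrix:
    """Volume x regressor design: task column first, then confounds, intercept."""

    matrix: np.ndarray
    names: list = field(default_factory=list)
    task_col: int = 0

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_weighted_design(
    onsets,
    durations,
    speeds,
    motion: np.ndarray | None,
    tr: float,
    n_volumes: int,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Speed-weighted block design convolved with the HRF.

    Per-block boxcar height is the block's speed weight normalized to unit
    mean (performance speed is inversely related to block duration, so faster
    blocks get taller, narrower epochs).  Block overlap with each TR interval
    is fractional, so block edges need not be TR-aligned.  Pass
    ``hrf=np.array([1.0])`` for an identity (no-convolution) kernel.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if not (len(onsets) == len(durations) == len(speeds)):
        raise ValueError("onsets, durations and speeds must align")
    if np.any(speeds <= 0):
        raise ValueError("block speeds must be > 0")
    order = np.argsort(onsets)
    onsets, durations, speeds = onsets[order], durations[order], speeds[order]
    ends = onsets + durations
    if np.any(onsets[1:] < ends[:-1]):
        raise ValueError("overlapping blocks")
    if ends[-1] > n_volumes * tr + 1e-9:
        raise ValueError("blocks extend past the end of the run")
    weights = speeds / speeds.mean()
    boxcar = np.zeros(n_volumes)
    vol_starts = np.arange(n_volumes) * tr
    for on, end, w in zip(onsets, ends, weights):
        overlap = np.clip(
            np.minimum(end, vol_starts + tr) - np.maximum(on, vol_starts), 0.0, tr
        )
        boxcar += w * overlap / tr
    kernel = double_gamma_hrf(tr) if hrf is None else np.asarray(hrf, dtype=float)
    task = np.convolve(boxcar, kernel)[:n_volumes]
    cols = [task]
    names = ["task"]
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        mc = motion - motion.mean(axis=0)
        for j in range(mc.shape[1]):
            cols.append(mc[:, j])
            names.append(f"motion{j + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names, task_col=0)


def fit_run_glm(run: BoldRun, design: DesignMatrix) -> StatMap:
    """Voxelwise OLS; effect is the task-column coefficient.

    Effect variance is the residual mean square times the task diagonal of
    (D'D)^-1; Z is the t statistic mapped through the normal quantile.
    """
    d = design.matrix
    if d.shape[0] != run.n_volumes:
        raise ValueError("design rows must equal run volumes")
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        offenders = [
            design.names[j]
            for j in range(d.shape[1])
            if np.linalg.matrix_rank(np.delete(d, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {offenders}")
    y = run.in_mask().T  # time x voxels
    coefs, *_ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ coefs
    dof = d.shape[0] - d.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    inv_term = np.linalg.inv(d.T @ d)[design.task_col, design.task_col]
    effect = coefs[design.task_col]
    var = sigma2 * inv_term
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    z = t_to_z(t, dof)
    out = {}
    for name, flat in (("effect", effect), ("variance", var), ("z", z)):
        vol = np.zeros(run.grid_shape)
        vol[run.mask] = flat
        out[name] = vol
    return StatMap(mask=run.mask, affine=run.affine, **out)


def group_difference_pattern(
    statmaps_msl: list,
    statmaps_ctl: list,
    mask: np.ndarray,
    z_threshold: float = 3.5,
    binarize: bool = False,
    pattern_id: str = "pattern",
) -> SpatialPattern:
    """Thresholded group Z map of the paired MSL - CTL effect contrast.

    A voxelwise paired t on the subject effect maps is converted to Z; voxels
    with Z > z_threshold (one-sided, MSL greater) form the pattern, carrying
    their Z values as weights (or 1 with ``binarize``).
    """
    if len(statmaps_msl) != len(statmaps_ctl):
        raise ValueError("unpaired subject maps")
    n = len(statmaps_msl)
    if n < 3:
        raise ValueError("need at least three paired subjects")
    get = lambda m: (m.effect if isinstance(m, StatMap) else np.asarray(m))[mask]
    diffs = np.asarray(
        [get(a) - get(b) for a, b in zip(statmaps_msl, statmaps_ctl)]
    )
    t = one_sample_t(diffs)
    z = t_to_z(t, n - 1)
    z3d = np.zeros(mask.shape)
    z3d[mask] = z
    weights = np.where(z3d > z_threshold, 1.0 if binarize else z3d, 0.0)
    return SpatialPattern(weights, pattern_id=pattern_id)


def volume_breakdown(
    pattern: SpatialPattern,
    cortical_mask: np.ndarray,
    subcortical_mask: np.ndarray,
    voxel_volume_mm3: float,
) -> dict[str, float]:
    """Activated volume in cm^3: total, cortical and subcortical compartments."""
    if cortical_mask.shape != pattern.data.shape or (
        subcortical_mask.shape != pattern.data.shape
    ):
        raise ValueError("mask grids do not match the pattern")
    if np.any(cortical_mask & subcortical_mask):
        warnings.warn("cortical and subcortical masks overlap", RuntimeWarning)
    active = pattern.support
    to_cm3 = voxel_volume_mm3 / 1000.0
    return {
        "total": float(active.sum()) * to_cm3,
        "cortical": float((active & cortical_mask).sum()) * to_cm3,
        "subcortical": float((active & subcortical_mask).sum()) * to_cm3,
    }
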