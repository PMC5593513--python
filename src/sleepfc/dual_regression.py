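"""Dual regression: localize which voxels drive within-network connectivity.

Stage 1 regresses each volume spatially on the group pattern (the same GLM the
connectivity index uses), producing one time series per run; the series is
z-scored and entered as the predictor of a stage-2 temporal regression fitted
per voxel, yielding a subject-level spatial map of coupling with the pattern's
co-activation.  Group contrasts on those maps use sign-flip permutation with
maximum cluster-mass correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._inference import cluster_table, one_sample_t, signflip_max_cluster_mass, t_to_z
from .containers import BoldRun, SpatialPattern, default_affine
from .connectivity_index import normalize_run, spatial_regression
from .stats_core import pearson_r

__all__ = [
    "SubjectDualMap",
    "GroupContrastResult",
    "dual_regress_subject",
    "group_dualreg_contrast",
    "cluster_fc_behavior_correlation",
]


@dataclass
class SubjectDualMap:
    """Stage-2 coefficient map (and its variance map) for one run."""

    coef: np.ndarray
    variance: np.ndarray
    mask: np.ndarray
    pattern_id: str = "pattern"
    affine: np.ndarray = field(default_factory=default_affine)
    stage1: np.ndarray | None = None


def dual_regress_subject(
    run: BoldRun,
    group_pattern: SpatialPattern | list[SpatialPattern],
    normalize: bool = True,
) -> SubjectDualMap | list[SubjectDualMap]:
    """Two-stage regression of a run against one or more group patterns.

    With a single pattern the stage-1 series equals the connectivity-index
    beta(t); multiple patterns are entered jointly in the spatial stage
    (multivariate fit) and each gets its own stage-2 map.
    """
    patterns = (
        group_pattern if isinstance(group_pattern, list) else [group_pattern]
    )
    if normalize:
        run = normalize_run(run)
    y = run.in_mask()
    n_vox, T = y.shape
    if len(patterns) == 1:
        betas = [spatial_regression(run, patterns[0]).beta]
    else:
        x = np.column_stack([p.data[run.mask] for p in patterns] + [np.ones(n_vox)])
        coefs, *_ = np.linalg.lstsq(x, y, rcond=None)
        betas = [coefs[i] for i in range(len(patterns))]

    out = []
    for pat, series in zip(patterns, betas):
        sd = series.std(ddof=1)
        if sd <= 1e-12 * max(1.0, float(np.abs(series).max())):
            raise ValueError(
                f"stage-1 series for {pat.pattern_id} has zero variance"
            )
        z = (series - series.mean()) / sd
        # stage 2: per-voxel OLS of the voxel series on [z, intercept]
        zz = float((z**2).sum())
        yc = y - y.mean(axis=1, keepdims=True)
        coef = (yc @ z) / zz
        resid = yc - np.outer(coef, z)
        dof = T - 2
        sigma2 = (resid**2).sum(axis=1) / dof
        var = sigma2 / zz
        coef3 = np.zeros(run.grid_shape)
        var3 = np.zeros(run.grid_shape)
        coef3[run.mask] = coef
        var3[run.mask] = var
        out.append(
            SubjectDualMap(
                coef=coef3,
                variance=var3,
                mask=run.mask,
                pattern_id=pat.pattern_id,
                affine=run.affine,
                stage1=z,
            )
        )
    return out if isinstance(group_pattern, list) else out[0]


@dataclass
class GroupContrastResult:
    """Voxelwise paired contrast with permutation cluster correction."""

    z: np.ndarray
    clusters: pd.DataFrame
    cluster_labels: np.ndarray
    null_max_mass: np.ndarray
    mask: np.ndarray

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.cluster_labels == label

    def top_cluster_mask(self) -> np.ndarray:
        if not len(self.clusters):
            raise ValueError("no suprathreshold clusters")
        return self.cluster_mask(int(self.clusters.iloc[0]["label"]))


def _as_coef_array(maps, mask) -> np.ndarray:
    rows = []
    for m in maps:
        arr = m.coef if isinstance(m, SubjectDualMap) else np.asarray(m)
        rows.append(arr[mask])
    return np.asarray(rows)


def group_dualreg_contrast(
    maps_a: list,
    maps_b: list,
    mask: np.ndarray,
    cluster_z: float = 2.3,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GroupContrastResult:
    """Paired group contrast (condition A - condition B) on subject maps.

    ``maps_a[i]`` and ``maps_b[i]`` must come from the same subject.  For the
    repeated-measures interaction across resting conditions, pass per-subject
    difference maps (e.g. RS3 - RS1 within each condition); the paired
    contrast of those differences is the interaction.  Inference is by
    sign-flip permutation of the subject difference maps with max cluster-mass
    correction at the given cluster-forming Z.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("unpaired inputs: condition lists differ in length")
    n = len(maps_a)
    if n < 3:
        raise ValueError("need at least three paired subjects")
    diffs = _as_coef_array(maps_a, mask) - _as_coef_array(maps_b, mask)
    t = one_sample_t(diffs)
    z3d = np.zeros(mask.shape)
    z3d[mask] = t_to_z(t, n - 1)
    rng = np.random.default_rng(seed)
    null = signflip_max_cluster_mass(
        diffs, mask, cluster_z, n_permutations, rng
    )
    labels, clusters = cluster_table(z3d, cluster_z, null)
    return GroupContrastResult(
        z=z3d, clusters=clusters, cluster_labels=labels, null_max_mass=null, mask=mask
    )


def cluster_fc_behavior_correlation(
    subject_maps: list, cluster_mask: np.ndarray, gains
) -> tuple[float, float]:
    """Pearson correlation between per-subject cluster connectivity and gains.

    The per-subject scalar is the mean stage-2 coefficient inside the cluster.
    """
    gains = np.asarray(gains, dtype=float)
    if len(subject_maps) != gains.size:
        raise ValueError("one gain per subject map is required")
    if gains.size < 4:
        raise ValueError("need at least four subjects")
    scalars = np.array(
        [
            (m.coef if isinstance(m, SubjectDualMap) else np.asarray(m))[
                cluster_mask
            ].mean()
            for m in subject_maps
        ]
    )
    return pearson_r(scalars, gains)
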