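"""Seed-based functional connectivity with nuisance regression.

Each region of interest (ROI) is a 6 mm (default) sphere around a mm-space
coordinate.  The subject-level model regresses every voxel's series on the
ROI mean series plus its temporal derivative and nine nuisance regressors
(white matter, CSF, global signal, six motion parameters) with an intercept;
the ROI coefficient is the connectivity value.  Group maps regress paired
condition differences on each subject's overnight behavioral gain, with
permutation cluster correction and Bonferroni control over the ROI family
(alpha / 12 for the canonical 12-seed set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._inference import cluster_table, one_sample_t, t_to_z
from .containers import BoldRun, default_affine
from .stats_core import pearson_r

__all__ = [
    "ROISpec",
    "FCMap",
    "GroupSeedResult",
    "make_sphere_roi",
    "roi_fc_map",
    "group_seed_map",
    "bonferroni_alpha",
    "deltafc_behavior_correlation",
    "read_roi_table",
    "default_roi_table",
]


@dataclass
class ROISpec:
    """A spherical seed: label, center in mm, radius in mm."""

    label: str
    center: tuple[float, float, float]
    radius: float = 6.0
    provenance: str = "both"  # learning / consolidated / both

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.provenance not in ("learning", "consolidated", "both"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def read_roi_table(path) -> list[ROISpec]:
    """Read a TSV seed table with columns label, x, y, z, radius[, provenance]."""
    t = pd.read_csv(path, sep="\t")
    return [
        ROISpec(
            label=row["label"],
            center=(row["x"], row["y"], row["z"]),
            radius=row.get("radius", 6.0),
            provenance=row.get("provenance", "both"),
        )
        for _, row in t.iterrows()
    ]


def default_roi_table() -> list[ROISpec]:
    """Twelve canonical 6 mm seeds, six per pattern, for interface realism.

    The labels follow the sensorimotor regions such studies report (motor and
    premotor cortex, SMA, parietal cortex, putamen, cerebellum); the
    coordinates are synthetic MNI-plausible placeholders, not measured peaks,
    and should be replaced with study-specific activation peaks.
    """
    rows = [
        ("M1_left", (-38, -22, 54), "learning"),
        ("PMd_left", (-26, -8, 58), "learning"),
        ("SMA", (-4, -6, 56), "learning"),
        ("SPL_left", (-28, -52, 62), "learning"),
        ("aIPS_right", (36, -44, 52), "learning"),
        ("cerebellum_V_right", (18, -52, -22), "learning"),
        ("putamen_left", (-26, -2, 2), "consolidated"),
        ("putamen_right", (28, 0, 0), "consolidated"),
        ("cerebellum_VI_left", (-22, -58, -24), "consolidated"),
        ("thalamus_left", (-12, -18, 8), "consolidated"),
        ("M1_hand_left", (-36, -24, 58), "consolidated"),
        ("parietal_oper_left", (-48, -28, 22), "consolidated"),
    ]
    return [ROISpec(lab, ctr, 6.0, prov) for lab, ctr, prov in rows]


def make_sphere_roi(
    spec: ROISpec, grid_shape: tuple[int, int, int], affine: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` of the seed.

    Voxel centers are mapped to mm through the affine; membership is the
    closed ball (distance <= radius).
    """
    if affine is None:
        affine = default_affine()
    inv = np.linalg.inv(affine)
    center_ijk = (inv @ np.append(spec.center, 1.0))[:3]
    if np.any(center_ijk < -0.5) or np.any(
        center_ijk > np.asarray(grid_shape) - 0.5
    ):
        raise ValueError(f"seed {spec.label} center lies outside the grid")
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    ijk = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    mm = (ijk @ affine.T)[:, :3]
    d2 = ((mm - np.asarray(spec.center)) ** 2).sum(axis=1)
    mask = (d2 <= spec.radius**2).reshape(grid_shape)
    if not mask.any():
        raise ValueError(f"seed {spec.label} produced an empty mask")
    return mask


@dataclass
class FCMap:
    """Per-voxel ROI connectivity coefficients and the nuisance design used."""

    coef: np.ndarray
    mask: np.ndarray
    roi_label: str = "roi"
    regressor_names: list = field(default_factory=list)
    affine: np.ndarray = field(default_factory=default_affine)


def _check_collinear(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by dropping each in turn
        offenders = []
        for j in range(design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                offenders.append(names[j])
        raise ValueError(f"collinear nuisance set; offending columns: {offenders}")


def roi_fc_map(
    run: BoldRun,
    roi_mask: np.ndarray,
    motion: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    roi_label: str = "roi",
) -> FCMap:
    """Nuisance-regressed connectivity of every brain voxel with the ROI.

    Tissue masks and motion default to the ones carried by the run; passing
    none at all fits the plain [ROI, derivative, intercept] model.  The ROI
    temporal derivative (first difference, zero-padded first sample) absorbs
    regional hemodynamic latency differences.
    """
    if roi_mask.shape != run.grid_shape:
        raise ValueError("ROI mask grid does not match the run")
    wm_mask = wm_mask if wm_mask is not None else run.wm_mask
    csf_mask = csf_mask if csf_mask is not None else run.csf_mask
    motion = motion if motion is not None else run.motion

    roi = run.data[roi_mask].mean(axis=0)
    deriv = np.concatenate([[0.0], np.diff(roi)])
    cols = [roi - roi.mean(), deriv - deriv.mean()]
    names = ["roi", "roi_derivative"]
    if wm_mask is not None:
        cols.append(run.data[wm_mask].mean(axis=0))
        names.append("wm")
    if csf_mask is not None:
        cols.append(run.data[csf_mask].mean(axis=0))
        names.append("csf")
    if wm_mask is not None or csf_mask is not None or motion is not None:
        cols.append(run.in_mask().mean(axis=0))
        names.append("global")
    if motion is not None:
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion{j + 1}")
    cols = [c - c.mean() for c in cols[:1]] + cols[1:]
    design = np.column_stack(cols + [np.ones(run.n_volumes)])
    names = names + ["intercept"]
    # center all non-intercept columns so coefficients are comparable
    design[:, :-1] -= design[:, :-1].mean(axis=0)
    _check_collinear(design, names)
    y = run.in_mask().T  # time x voxels
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    fc = np.zeros(run.grid_shape)
    fc[run.mask] = coefs[0]
    return FCMap(
        coef=fc,
        mask=run.mask,
        roi_label=roi_label,
        regressor_names=names,
        affine=run.affine,
    )


def bonferroni_alpha(alpha: float = 0.05, n_rois: int = 12) -> float:
    """Per-ROI threshold controlling the family of seed analyses."""
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    return alpha / n_rois


@dataclass
class GroupSeedResult:
    z: np.ndarray
    slope: np.ndarray
    clusters: pd.DataFrame
    cluster_labels: np.ndarray
    null_max_mass: np.ndarray
    mask: np.ndarray
    degenerate_gains: bool = False

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.cluster_labels == label


def group_seed_map(
    fc_maps_msl: list,
    fc_maps_ctl: list,
    gains,
    mask: np.ndarray,
    cluster_z: float = 2.7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GroupSeedResult:
    """Regress paired FC differences on behavioral gains across subjects.

    The voxelwise model is ``diff_i(v) = a(v) + s(v) * gain_i``; the slope map
    weights the condition difference by each subject's overnight improvement.
    Significance is by permutation of the gain labels with max cluster-mass
    correction.  If the gains are (numerically) constant the regressor is
    degenerate; the analysis then falls back to the paired mean contrast with
    sign-flip permutation, flagged on the result.
    """
    if len(fc_maps_msl) != len(fc_maps_ctl):
        raise ValueError("unpaired FC maps")
    gains = np.asarray(gains, dtype=float)
    n = len(fc_maps_msl)
    if gains.size != n:
        raise ValueError(
            f"gains length {gains.size} does not match {n} subject pairs"
        )
    get = lambda m: (m.coef if isinstance(m, FCMap) else np.asarray(m))[mask]
    diffs = np.asarray([get(a) - get(b) for a, b in zip(fc_maps_msl, fc_maps_ctl)])
    rng = np.random.default_rng(seed)
    df = n - 2
    if np.std(gains) <= 1e-12 * max(1.0, np.abs(gains).max()) or df < 1:
        warnings.warn(
            "behavioral gains are constant; falling back to mean contrast",
            RuntimeWarning,
        )
        t = one_sample_t(diffs)
        z3d = np.zeros(mask.shape)
        z3d[mask] = t_to_z(t, n - 1)
        from ._inference import signflip_max_cluster_mass

        null = signflip_max_cluster_mass(diffs, mask, cluster_z, n_permutations, rng)
        labels, clusters = cluster_table(z3d, cluster_z, null)
        slope = np.zeros(mask.shape)
        slope[mask] = diffs.mean(axis=0)
        return GroupSeedResult(
            z3d, slope, clusters, labels, null, mask, degenerate_gains=True
        )

    def _slope_t(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gc = g - g.mean()
        sxx = float((gc**2).sum())
        slope = (gc @ diffs) / sxx
        fitted = diffs.mean(axis=0)[None, :] + np.outer(gc, slope)
        sigma2 = ((diffs - fitted) ** 2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sigma2 > 0, slope / np.sqrt(sigma2 / sxx), 0.0)
        return slope, t

    slope, t = _slope_t(gains)
    z3d = np.zeros(mask.shape)
    z3d[mask] = t_to_z(t, df)
    null = np.empty(n_permutations)
    ztmp = np.zeros(mask.shape)
    from ._inference import _cluster_masses

    for p in range(n_permutations):
        _, tp = _slope_t(rng.permutation(gains))
        ztmp[mask] = t_to_z(tp, df)
        _, info = _cluster_masses(ztmp, cluster_z)
        null[p] = max((c["mass"] for c in info), default=0.0)
        ztmp[mask] = 0.0
    labels, clusters = cluster_table(z3d, cluster_z, null)
    slope3 = np.zeros(mask.shape)
    slope3[mask] = slope
    return GroupSeedResult(z3d, slope3, clusters, labels, null, mask)


def deltafc_behavior_correlation(
    fc_by_key: dict,
    cluster_mask: np.ndarray,
    gains: dict,
    contrast: tuple[str, str],
) -> tuple[float, float]:
    """Correlate per-subject connectivity changes with overnight gains.

    ``fc_by_key`` maps ``(subject, condition_or_session)`` to an FC map; the
    per-subject change in functional connectivity is the mean coefficient in
    the cluster under ``contrast[0]`` minus that under ``contrast[1]`` (e.g.
    ("RS3", "RS1") or ("MSL", "CTL")).  ``gains`` maps subject to overnight
    behavioral gain.
    """
    subjects = sorted(gains)
    a, b = contrast
    missing = [
        (s, c) for s in subjects for c in (a, b) if (s, c) not in fc_by_key
    ]
    if missing:
        raise ValueError(f"missing runs for contrast {contrast}: {missing}")
    get = lambda m: (m.coef if isinstance(m, FCMap) else np.asarray(m))
    delta = np.array(
        [
            get(fc_by_key[(s, a)])[cluster_mask].mean()
            - get(fc_by_key[(s, b)])[cluster_mask].mean()
            for s in subjects
        ]
    )
    gain_vec = np.array([gains[s] for s in subjects], dtype=float)
    return pearson_r(delta, gain_vec)
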