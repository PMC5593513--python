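"""Core in-memory containers shared by every analysis module.

A :class:`BoldRun` holds one 4D BOLD-like acquisition (voxels x time) together
with its brain mask, repetition time, motion traces and labels.  A
:class:`SpatialPattern` is a 3D weight map on the same grid (e.g. a thresholded
group Z map).  Both carry an affine so voxel indices map to mm coordinates the
way nibabel images do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoldRun",
    "SpatialPattern",
    "CoefSeries",
    "ConnectivityIndexValue",
    "StatMap",
    "default_affine",
]


def default_affine(voxel_size: float = 3.0) -> np.ndarray:
    """Isotropic scanner-style affine with the origin at the grid corner."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size)
    return aff


@dataclass
class BoldRun:
    """One 4D functional run: ``data[x, y, z, t]``.

    Parameters
    ----------
    data:
        4D intensity array; time is the last axis.
    tr:
        Repetition time in seconds per volume.
    mask:
        3D boolean brain mask on the same grid.
    motion:
        Optional ``(n_volumes, 6)`` rigid-body motion traces (3 translations,
        3 rotations), used as confound regressors downstream.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    motion: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=default_affine)
    subject: str | None = None
    condition: str | None = None
    session: str | None = None
    wm_mask: np.ndarray | None = None
    csf_mask: np.ndarray | None = None
    norm_scale: float = 1.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"run data must be 4D, got shape {self.data.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.grid_shape}"
            )
        if self.motion is not None:
            self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
            if self.motion.shape[0] != self.n_volumes:
                raise ValueError("motion trace length must equal the volume count")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def in_mask(self) -> np.ndarray:
        """Return the in-mask data as a ``(n_voxels, n_volumes)`` 2D array."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray, **kwargs) -> "BoldRun":
        """Copy of this run with replaced data (and any other fields)."""
        return replace(self, data=data, **kwargs)

    @property
    def key(self) -> tuple:
        return (self.subject, self.condition, self.session)


@dataclass
class SpatialPattern:
    """A 3D weight map X(v) on the analysis grid.

    Voxels with weight zero are outside the pattern's support.
    """

    data: np.ndarray
    pattern_id: str = "pattern"
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("pattern must be a 3D map")

    @property
    def support(self) -> np.ndarray:
        return self.data != 0

    @property
    def n_support(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass
class CoefSeries:
    """Per-volume spatial-regression outputs.

    ``beta[t]`` is the pattern coefficient for volume ``t``, ``resid_sd[t]``
    the cross-voxel residual SD, and ``eta[t] = beta[t] / resid_sd[t]`` the
    residual-normalized coefficient.  Volumes where the residual SD vanishes
    (a volume exactly proportional to the pattern) are flagged ``degenerate``
    and carry ``eta = nan``.
    """

    beta: np.ndarray
    resid_sd: np.ndarray
    eta: np.ndarray
    degenerate: np.ndarray
    pattern_id: str = "pattern"
    n_voxels: int = 0

    def __len__(self) -> int:
        return len(self.beta)

    def valid_eta(self) -> np.ndarray:
        """Eta values for non-degenerate volumes."""
        return self.eta[~self.degenerate]


@dataclass
class ConnectivityIndexValue:
    """Connectivity index: variance over time of the normalized coefficients."""

    ci: float
    pattern_id: str = "pattern"
    n_volumes_used: int = 0
    run_key: tuple | None = None

    def __post_init__(self) -> None:
        if self.ci < 0:
            raise ValueError("a variance cannot be negative")

    def __float__(self) -> float:
        return float(self.ci)


@dataclass
class StatMap:
    """Voxelwise GLM outputs: effect estimate, its variance, and a Z score."""

    effect: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        if np.any(self.variance[self.mask] < 0):
            raise ValueError("variance map must be non-negative inside the mask")
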