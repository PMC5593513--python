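"""Shared voxelwise group inference: t/Z maps, clusters, permutation nulls.

Group significance uses sign-flip (or label-permutation) maximum cluster-mass
correction: clusters are formed at a fixed Z threshold, each cluster's mass is
the sum of suprathreshold |Z| excess, and the familywise-corrected p value of
a cluster compares its mass with the permutation distribution of the maximum
cluster mass over the image.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "t_to_z",
    "one_sample_t",
    "cluster_table",
    "signflip_max_cluster_mass",
]


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to equivalent standard-normal Z, sign-preserving."""
    t = np.asarray(t, dtype=float)
    # work on |t| through the upper tail for numerical symmetry
    z = stats.norm.isf(stats.t.sf(np.abs(t), df))
    z = np.clip(z, 0.0, 38.0)  # isf underflow guard
    return np.sign(t) * z


def one_sample_t(diffs: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t across subjects: ``diffs`` is (n_subjects, n_voxels)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _cluster_masses(z3d: np.ndarray, threshold: float) -> tuple[np.ndarray, list]:
    """Label two-sided suprathreshold clusters; return (labels, cluster info).

    Mass of a cluster is ``sum(|z| - threshold)`` over its voxels.  Positive
    and negative excursions form separate clusters.
    """
    labels = np.zeros(z3d.shape, dtype=int)
    info = []
    next_label = 1
    for sign in (1, -1):
        excess = sign * z3d - threshold
        lab, n = ndimage.label(excess > 0)
        for i in range(1, n + 1):
            sel = lab == i
            labels[sel] = next_label
            mass = float(excess[sel].sum())
            peak_flat = np.flatnonzero(sel.ravel())[np.argmax((sign * z3d)[sel])]
            peak = np.unravel_index(peak_flat, z3d.shape)
            com = tuple(float(c) for c in np.argwhere(sel).mean(axis=0))
            info.append(
                {
                    "label": next_label,
                    "sign": sign,
                    "n_voxels": int(sel.sum()),
                    "mass": mass,
                    "peak_z": float(z3d[peak]),
                    "peak_ijk": tuple(int(c) for c in peak),
                    "center_of_mass": com,
                }
            )
            next_label += 1
    return labels, info


def cluster_table(
    z3d: np.ndarray, threshold: float, null_max_mass: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cluster labels and table for a Z map; p values from a max-mass null."""
    labels, info = _cluster_masses(z3d, threshold)
    df = pd.DataFrame(
        info,
        columns=[
            "label",
            "sign",
            "n_voxels",
            "mass",
            "peak_z",
            "peak_ijk",
            "center_of_mass",
        ],
    )
    if null_max_mass is not None and len(df):
        n_perm = len(null_max_mass)
        df["p"] = [
            (1.0 + float((null_max_mass >= m).sum())) / (n_perm + 1.0)
            for m in df["mass"]
        ]
    df = df.sort_values("mass", ascending=False).reset_index(drop=True)
    return labels, df


def signflip_max_cluster_mass(
    diffs: np.ndarray,
    mask: np.ndarray,
    cluster_z: float,
    n_permutations: int,
    rng: np.random.Generator,
    stat_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Null distribution of the maximum cluster mass under sign flipping.

    ``diffs`` is (n_subjects, n_voxels) of paired difference images (in-mask).
    ``stat_rows`` optionally supplies precomputed per-permutation sign matrices.
    """
    n, v = diffs.shape
    df = n - 1
    signs = (
        stat_rows
        if stat_rows is not None
        else rng.choice([-1.0, 1.0], size=(n_permutations, n))
    )
    sq = (diffs**2).sum(axis=0)  # invariant under sign flips
    null = np.empty(len(signs))
    z3d = np.zeros(mask.shape)
    for p, s in enumerate(signs):
        mean = (s @ diffs) / n
        var = (sq - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
        z3d[mask] = t_to_z(t, df)
        _, info = _cluster_masses(z3d, cluster_z)
        null[p] = max((c["mass"] for c in info), default=0.0)
        z3d[mask] = 0.0
    return null
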