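"""File I/O: NIfTI images via nibabel, TSV tables via pandas."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldRun, SpatialPattern
from .synthetic_data import Hypnogram

__all__ = [
    "save_run",
    "load_run",
    "save_pattern",
    "load_pattern",
    "save_hypnogram",
    "load_hypnogram",
    "save_keypresses",
    "load_keypresses",
]


def save_run(run: BoldRun, prefix: str | Path) -> None:
    """Write ``<prefix>.nii.gz`` (4D data), ``<prefix>_mask.nii.gz`` and
    ``<prefix>_motion.tsv``."""
    prefix = Path(prefix)
    nib.save(
        nib.Nifti1Image(run.data.astype(np.float32), run.affine),
        str(prefix) + ".nii.gz",
    )
    nib.save(
        nib.Nifti1Image(run.mask.astype(np.uint8), run.affine),
        str(prefix) + "_mask.nii.gz",
    )
    if run.motion is not None:
        pd.DataFrame(
            run.motion, columns=[f"motion{j + 1}" for j in range(run.motion.shape[1])]
        ).to_csv(str(prefix) + "_motion.tsv", sep="\t", index=False)


def load_run(
    data_path: str | Path,
    mask_path: str | Path,
    tr: float,
    motion_path: str | Path | None = None,
    **labels,
) -> BoldRun:
    img = nib.load(str(data_path))
    mask = nib.load(str(mask_path))
    motion = (
        pd.read_csv(motion_path, sep="\t").to_numpy()
        if motion_path is not None
        else None
    )
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=float),
        tr=tr,
        mask=np.asarray(mask.dataobj) > 0,
        motion=motion,
        affine=img.affine,
        **labels,
    )


def save_pattern(pattern: SpatialPattern, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(pattern.data.astype(np.float32), pattern.affine), str(path)
    )


def load_pattern(path: str | Path, pattern_id: str | None = None) -> SpatialPattern:
    img = nib.load(str(path))
    return SpatialPattern(
        np.asarray(img.dataobj, dtype=float),
        pattern_id=pattern_id or Path(path).stem.split(".")[0],
        affine=img.affine,
    )


def save_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    hyp.to_frame().to_csv(path, sep="\t", index=False)


def load_hypnogram(path: str | Path) -> Hypnogram:
    t = pd.read_csv(path, sep="\t")
    return Hypnogram(t.sort_values("volume_index")["stage"].to_numpy())


def save_keypresses(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)


def load_keypresses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
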