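"""Within-network connectivity index (CI).

The CI quantifies how strongly a fixed spatial pattern X(v) co-activates in a
run Y(v, t).  For each volume t the in-mask voxel intensities are regressed
across voxels on the pattern (spatial GLM)::

    Y(v, t) = X(v) beta(t) + epsilon(v, t)
    sigma(t) = SD_v(epsilon(v, t))
    eta(t) = beta(t) / sigma(t)

and the CI is the variance of eta(t) over volumes.  Normalizing beta by the
cross-voxel residual SD makes the index specific to co-activation of the
pattern rather than to any global activation, and dividing the run by a single
pooled SD beforehand makes between-run comparisons insensitive to the total
BOLD variation of each run.

Scale behavior (asserted exactly in the test suite): CI(c*Y, X) = CI(Y, X) for
any c > 0, and CI(Y, c*X) = CI(Y, X) / c^2, so cross-run CI ratios are
invariant to a common rescaling of the pattern.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .containers import BoldRun, CoefSeries, ConnectivityIndexValue, SpatialPattern

__all__ = [
    "normalize_run",
    "spatial_regression",
    "connectivity_index",
    "ci_from_run",
    "ci_table",
]

MIN_PATTERN_VOXELS = 10


def normalize_run(run: BoldRun) -> BoldRun:
    """Divide every voxel series by the run's pooled in-mask SD.

    The scalar is the sample SD of all in-mask voxel-time samples after
    removing each voxel's temporal mean; one number per run, so the operation
    is a pure global rescaling.  The applied scalar accumulates in
    ``norm_scale`` (re-normalizing an already-normalized run finds a scalar of
    1 and leaves the data unchanged).
    """
    if run.n_volumes < 2:
        raise ValueError("need at least two volumes to normalize")
    y = run.in_mask()
    if y.size == 0:
        raise ValueError("empty brain mask")
    demeaned = y - y.mean(axis=1, keepdims=True)
    scale = float(np.std(demeaned.ravel(), ddof=1))
    if scale == 0:
        raise ValueError("constant run: pooled SD is zero, cannot normalize")
    data = run.data / scale
    return run.with_data(data, norm_scale=run.norm_scale * scale)


def spatial_regression(
    run: BoldRun,
    pattern: SpatialPattern,
    include_intercept: bool = True,
) -> CoefSeries:
    """Per-volume least squares of in-mask intensities on [X(v), 1].

    The intercept absorbs per-volume mean offsets so they do not leak into
    beta; ``include_intercept=False`` gives the literal no-offset regression.
    Volumes whose residuals vanish (data exactly proportional to the pattern)
    are flagged degenerate and get ``eta = nan``.
    """
    if pattern.data.shape != run.grid_shape:
        raise ValueError("pattern grid does not match run grid")
    x = pattern.data[run.mask]
    n_nonzero = int(np.count_nonzero(x))
    if n_nonzero < MIN_PATTERN_VOXELS:
        raise ValueError(
            f"pattern has {n_nonzero} in-mask voxels; need >= {MIN_PATTERN_VOXELS}"
        )
    if include_intercept and np.std(x) == 0:
        raise ValueError("constant pattern is collinear with the intercept")
    y = run.in_mask()
    n_vox = y.shape[0]
    if include_intercept:
        design = np.column_stack([x, np.ones(n_vox)])
    else:
        design = x[:, None]
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    beta = coefs[0]
    resid = y - design @ coefs
    sd = resid.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(y).max()))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate volume(s) with zero residual SD",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(degenerate, np.nan, beta / sd)
    return CoefSeries(
        beta=beta,
        resid_sd=sd,
        eta=eta,
        degenerate=degenerate,
        pattern_id=pattern.pattern_id,
        n_voxels=n_vox,
    )


def connectivity_index(
    coef: CoefSeries, min_volumes: int = 10, run_key: tuple | None = None
) -> ConnectivityIndexValue:
    """CI = sample variance of eta(t) over the retained (non-degenerate) volumes."""
    eta = coef.valid_eta()
    eta = eta[np.isfinite(eta)]
    if eta.size < min_volumes:
        raise ValueError(
            f"only {eta.size} defined eta values; need >= {min_volumes}"
        )
    return ConnectivityIndexValue(
        ci=float(np.var(eta, ddof=1)),
        pattern_id=coef.pattern_id,
        n_volumes_used=int(eta.size),
        run_key=run_key,
    )


def ci_from_run(
    run: BoldRun,
    pattern: SpatialPattern,
    normalize: bool = True,
    include_intercept: bool = True,
) -> ConnectivityIndexValue:
    """Convenience: normalize, spatially regress, and take the eta variance."""
    if normalize:
        run = normalize_run(run)
    coef = spatial_regression(run, pattern, include_intercept=include_intercept)
    return connectivity_index(coef, run_key=run.key)


def ci_table(
    runs: dict,
    patterns: dict[str, SpatialPattern] | list[SpatialPattern],
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Tidy CI table over a dict of runs keyed (subject, condition, session).

    The expected design is the full cross product of the observed subjects,
    conditions and sessions; missing cells are listed explicitly (error by
    default, warning with ``allow_missing``) rather than silently dropped.
    """
    if isinstance(patterns, dict):
        patterns = list(patterns.values())
    subjects = sorted({k[0] for k in runs})
    conditions = sorted({k[1] for k in runs})
    sessions = sorted({k[2] for k in runs})
    missing = [
        cell
        for cell in itertools.product(subjects, conditions, sessions)
        if cell not in runs
    ]
    if missing:
        msg = f"missing run cells: {missing}"
        if allow_missing:
            warnings.warn(msg, RuntimeWarning)
        else:
            raise ValueError(msg)
    rows = []
    for key in sorted(runs):
        norm = normalize_run(runs[key])
        for pat in patterns:
            value = connectivity_index(
                spatial_regression(norm, pat), run_key=key
            )
            rows.append(
                {
                    "subject": key[0],
                    "condition": key[1],
                    "session": key[2],
                    "pattern": pat.pattern_id,
                    "ci": value.ci,
                    "n_volumes": value.n_volumes_used,
                }
            )
    return pd.DataFrame(rows)
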