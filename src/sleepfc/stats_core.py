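"""Inferential machinery for within-subject factorial designs.

Implements the two-factor fully-within-subject repeated-measures ANOVA (each
effect tested against its own subject-by-effect interaction error term, no
sphericity correction, matching designs reported with uncorrected degrees of
freedom such as F(13, 156)), the paired two-tailed t test, the Pearson
correlation with its t-transform p value, and analytic power for the paired
design via the noncentral t distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rm_anova2",
    "paired_t",
    "pearson_r",
    "power_paired",
    "PairedTResult",
]


def _to_cube(
    data, subject: str, factor_a: str, factor_b: str, value: str
) -> tuple[np.ndarray, list, list]:
    """Coerce input to an ``(n_subjects, a, b)`` cube, checking completeness."""
    if isinstance(data, pd.DataFrame):
        pivot = data.pivot_table(
            index=subject, columns=[factor_a, factor_b], values=value, aggfunc="mean"
        )
        a_levels = sorted(data[factor_a].unique())
        b_levels = sorted(data[factor_b].unique())
        full = pd.MultiIndex.from_product([a_levels, b_levels])
        missing = [c for c in full if c not in pivot.columns]
        missing += list(map(tuple, np.argwhere(pivot.isna().to_numpy())))
        if missing:
            raise ValueError(f"incomplete crossed design; missing cells: {missing}")
        cube = pivot.reindex(columns=full).to_numpy()
        cube = cube.reshape(len(pivot), len(a_levels), len(b_levels))
        return cube, a_levels, b_levels
    cube = np.asarray(data, dtype=float)
    if cube.ndim != 3:
        raise ValueError("array input must be (n_subjects, a_levels, b_levels)")
    if np.isnan(cube).any():
        raise ValueError(
            f"incomplete crossed design; missing cells: "
            f"{list(map(tuple, np.argwhere(np.isnan(cube))))}"
        )
    a, b = cube.shape[1], cube.shape[2]
    return cube, list(range(a)), list(range(b))


def rm_anova2(
    data,
    subject: str = "subject",
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> pd.DataFrame:
    """Two-factor fully repeated-measures ANOVA.

    Parameters
    ----------
    data:
        Either a long-format DataFrame with one row per subject x A x B cell,
        or an ``(n_subjects, a, b)`` array.

    Returns
    -------
    DataFrame with one row per effect (A, B, A x B): sum of squares, numerator
    and denominator df, F, and p.  df identities: ``df_num = (a-1)``, ``(b-1)``,
    ``(a-1)(b-1)`` and ``df_den = df_num * (n-1)``.
    """
    cube, a_levels, b_levels = _to_cube(data, subject, factor_a, factor_b, value)
    n, a, b = cube.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = cube.mean()
    subj_m = cube.mean(axis=(1, 2))
    a_m = cube.mean(axis=(0, 2))
    b_m = cube.mean(axis=(0, 1))
    ab_m = cube.mean(axis=0)
    sa_m = cube.mean(axis=2)  # subject x A
    sb_m = cube.mean(axis=1)  # subject x B

    ss_total = float(((cube - grand) ** 2).sum())
    ss_subj = a * b * float(((subj_m - grand) ** 2).sum())
    ss_a = n * b * float(((a_m - grand) ** 2).sum())
    ss_b = n * a * float(((b_m - grand) ** 2).sum())
    ss_ab = n * float(
        ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    )
    ss_as = b * float(
        ((sa_m - subj_m[:, None] - a_m[None, :] + grand) ** 2).sum()
    )
    ss_bs = a * float(
        ((sb_m - subj_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    )
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    rows = []
    for name, ss_eff, ss_err, df_num in (
        (factor_a, ss_a, ss_as, a - 1),
        (factor_b, ss_b, ss_bs, b - 1),
        (f"{factor_a} x {factor_b}", ss_ab, ss_abs, (a - 1) * (b - 1)),
    ):
        df_den = df_num * (n - 1)
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        rows.append(
            {
                "effect": name,
                "ss": ss_eff,
                "ss_error": ss_err,
                "df_num": df_num,
                "df_den": df_den,
                "F": f,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def paired_t(x, y) -> PairedTResult:
    """Two-tailed paired t test on the differences ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences; t is infinite", RuntimeWarning)
        t = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
        return PairedTResult(float(t), n - 1, 0.0 if t != 0 else 1.0)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least four observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def power_paired(
    effect_mean: float, effect_sd: float, n: int, alpha: float = 0.05
) -> float:
    """Analytic power of the two-sided paired t test.

    The noncentrality parameter is ``(effect_mean / effect_sd) * sqrt(n)``
    with ``n - 1`` degrees of freedom; power is the noncentral-t mass beyond
    the two-sided critical values.
    """
    if effect_sd <= 0:
        raise ValueError("effect_sd must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = (effect_mean / effect_sd) * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
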