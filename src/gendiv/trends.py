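"""Inbreeding-rate trend statistics.

Annual rate from the log-regression of mean inbreeding on birth year, its
per-generation scaling, the segmented pre/post-genomic-selection model with
the slope-shift coefficient delta and relative change RC, and the two-cohort
mean comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendFit",
    "delta_f_per_year",
    "delta_f_per_generation",
    "segmented_gs_model",
    "cohort_comparison",
]


@dataclass
class TrendFit:
    """Container for rate and segmented-model results (unused fields None)."""

    slope_b: Optional[float] = None
    delta_f_year: Optional[float] = None
    delta_f_gen: Optional[float] = None
    alpha1: Optional[float] = None
    beta_pts: Optional[float] = None
    beta_gs: Optional[float] = None
    delta: Optional[float] = None
    se_delta: Optional[float] = None
    p_delta: Optional[float] = None
    rc: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def delta_f_per_year(
    annual_means: Mapping[int, float],
    rate_convention: str = "exp",
) -> TrendFit:
    """Annual inbreeding rate from OLS of ln(1 - mean F) on birth year.

    ``rate_convention="exp"`` (default) reports dF_year = 1 - exp(slope),
    exact on geometric series; ``"neg-slope"`` reports the first-order
    approximation -slope.
    """
    years = np.array(sorted(annual_means), dtype=float)
    x = np.array([annual_means[int(y)] for y in years], dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 annual means")
    if np.any(x >= 1.0) or np.any(x < 0.0):
        raise ValueError("annual means must lie in [0, 1)")
    slope, _ = np.polyfit(years, np.log1p(-x), 1)
    if rate_convention == "exp":
        dfy = 1.0 - np.exp(slope)
    elif rate_convention == "neg-slope":
        dfy = -slope
    else:
        raise ValueError(f"unknown rate convention {rate_convention!r}")
    return TrendFit(slope_b=float(slope), delta_f_year=float(dfy))


def delta_f_per_generation(delta_f_year: float, gi_years: float) -> float:
    """Per-generation rate: annual rate times the generation interval."""
    if gi_years <= 0:
        raise ValueError("gi_years must be positive")
    return delta_f_year * gi_years


def segmented_gs_model(
    records: pd.DataFrame,
    pts_range: tuple[int, int] = (2006, 2010),
    gs_range: tuple[int, int] = (2015, 2019),
    value_col: str = "value",
    year_col: str = "birth_year",
    shared_intercept: bool = True,
    rc_denominator: str = "pts",
) -> TrendFit:
    """Two-slope linear model of per-animal inbreeding on birth year.

    Fits value = alpha1 + beta_PTS * x + delta * x * I(x in GS cohort) over
    animals born in the two 5-year cohorts (gap years excluded).  Reports
    beta_PTS, beta_GS = beta_PTS + delta, delta with its ANOVA p-value
    (identical to the coefficient t-test), and RC = delta / beta_PTS
    (``rc_denominator="gs"`` switches to the beta_GS reading).
    """
    x_all = records[year_col].to_numpy(dtype=float)
    y_all = records[value_col].to_numpy(dtype=float)
    in_pts = (x_all >= pts_range[0]) & (x_all <= pts_range[1])
    in_gs = (x_all >= gs_range[0]) & (x_all <= gs_range[1])
    use = in_pts | in_gs
    x, y, gs = x_all[use], y_all[use], in_gs[use]
    for name, m in (("PTS", in_pts), ("GS", in_gs)):
        if m.sum() < 2 or len(np.unique(x_all[m])) < 2:
            raise ValueError(
                f"{name} cohort needs >=2 animals over >=2 distinct years"
            )

    if shared_intercept:
        X = np.column_stack([np.ones_like(x), x, x * gs])
        i_beta, i_delta = 1, 2
    else:
        X = np.column_stack([np.ones_like(x), gs.astype(float), x, x * gs])
        i_beta, i_delta = 2, 3
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular design (need >=2 distinct years per cohort)")

    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    if dof > 0:
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se_delta = float(np.sqrt(sigma2 * xtx_inv[i_delta, i_delta]))
        if se_delta > 0:
            tval = coef[i_delta] / se_delta
            p_delta = float(2.0 * stats.t.sf(abs(tval), dof))
        else:
            p_delta = 0.0 if coef[i_delta] != 0 else 1.0
    else:
        se_delta, p_delta = np.nan, np.nan

    beta_pts = float(coef[i_beta])
    delta = float(coef[i_delta])
    denom = beta_pts if rc_denominator == "pts" else beta_pts + delta
    if rc_denominator not in ("pts", "gs"):
        raise ValueError(f"unknown rc_denominator {rc_denominator!r}")
    rc = 0.0 if delta == 0 else (delta / denom if denom != 0 else np.nan)
    return TrendFit(
        alpha1=float(coef[0]),
        beta_pts=beta_pts,
        beta_gs=beta_pts + delta,
        delta=delta,
        se_delta=se_delta,
        p_delta=p_delta,
        rc=rc,
    )


def cohort_comparison(
    values_pts: Sequence[float], values_gs: Sequence[float]
) -> dict:
    """Welch two-sample t-test of cohort means."""
    a = np.asarray(values_pts, dtype=float)
    b = np.asarray(values_gs, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both cohorts")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_pts": float(a.mean()),
        "mean_gs": float(b.mean()),
        "t": float(t),
        "p": float(p),
    }
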