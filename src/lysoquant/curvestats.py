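"""Polynomial curve fitting and nested-model comparison of profile data.

Cumulative distribution profiles are compared between conditions the way
GraphPad Prism compares nonlinear fits: a centred 6th-order polynomial
``y = sum_j c_j (x - x0)^j`` is fitted by ordinary least squares either to
the pooled points of both groups (shared model) or separately per group,
and the improvement of the separate model is assessed with the extra
sum-of-squares F-test,

    F = ((SSR_shared - SSR_separate) / (df_shared - df_separate))
        / (SSR_separate / df_separate),

with p from the F(df_shared - df_separate, df_separate) distribution.
Points entering the fits are all per-cell (x, y) pairs, pooled across
cells — not the population mean curve — so per-cell degrees of freedom are
preserved.  Population curves for plotting are aggregated as mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .images import ValidationError
from .radial import CumulativeProfile

POLY_DEGREE = 6
N_COEF = POLY_DEGREE + 1
#: Default centering constant: midpoint of the 0-100 area-percent axis.
DEFAULT_X0 = 50.0


@dataclass
class PolyFit:
    """Centred polynomial least-squares fit."""

    coefficients: np.ndarray  # c_0 ... c_6 of sum c_j (x - x0)^j
    x0: float
    ssr: float
    n_points: int

    @property
    def df(self) -> int:
        return self.n_points - N_COEF

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _design(np.asarray(x, dtype=float), self.x0) @ self.coefficients


@dataclass
class CurveComparison:
    """Shared-vs-separate fit comparison by the extra sum-of-squares F-test."""

    ssr_shared: float
    ssr_separate: float
    df_shared: int
    df_separate: int
    f_stat: float
    p_value: float
    n_a: int = 0
    n_b: int = 0


@dataclass
class PopulationCurve:
    """Pointwise mean ± SEM across cells."""

    x: np.ndarray
    mean_y: np.ndarray
    sem_y: np.ndarray
    n_cells: int


def _design(x: np.ndarray, x0: float) -> np.ndarray:
    return np.vander(x - x0, N_COEF, increasing=True)


def fit_polynomial(
    points: Sequence[tuple[float, float]] | np.ndarray, x0: float = DEFAULT_X0
) -> PolyFit:
    """Ordinary least-squares fit of the 7-coefficient centred polynomial."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of (x, y)")
    if pts.shape[0] < N_COEF + 1:
        raise ValidationError(
            f"insufficient degrees of freedom: need >= {N_COEF + 1} points, "
            f"got {pts.shape[0]}"
        )
    x, y = pts[:, 0], pts[:, 1]
    X = _design(x, x0)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return PolyFit(
        coefficients=coef, x0=x0, ssr=float(resid @ resid), n_points=pts.shape[0]
    )


def extra_ss_ftest(
    ssr_shared: float, df_shared: int, ssr_separate: float, df_separate: int
) -> tuple[float, float]:
    """Extra sum-of-squares F statistic and p-value for nested fits."""
    if df_separate <= 0 or df_shared <= df_separate:
        raise ValidationError(
            f"degenerate degrees of freedom: shared {df_shared}, "
            f"separate {df_separate}"
        )
    extra = ssr_shared - ssr_separate
    # Guard against floating-point residue when the models coincide.
    if extra <= 1e-12 * max(ssr_shared, 1.0):
        extra = 0.0
    if ssr_separate <= 0:
        f = 0.0 if extra == 0.0 else np.inf
    else:
        f = (extra / (df_shared - df_separate)) / (ssr_separate / df_separate)
    p = float(stats.f.sf(f, df_shared - df_separate, df_separate))
    return float(f), p


def _pooled_points(profiles: Sequence[CumulativeProfile]) -> np.ndarray:
    xs = np.concatenate([p.x for p in profiles])
    ys = np.concatenate([p.y for p in profiles])
    return np.column_stack([xs, ys])


def compare_curves(
    group_a: Sequence[CumulativeProfile],
    group_b: Sequence[CumulativeProfile],
    x0: float = DEFAULT_X0,
) -> CurveComparison:
    """Compare two groups of profiles: one shared vs. two separate fits."""
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValidationError("each group needs at least one profile")
    pts_a = _pooled_points(group_a)
    pts_b = _pooled_points(group_b)
    if pts_a.shape[0] + pts_b.shape[0] < 15:
        raise ValidationError("need at least 15 pooled points for comparison")
    fit_a = fit_polynomial(pts_a, x0)
    fit_b = fit_polynomial(pts_b, x0)
    shared = fit_polynomial(np.vstack([pts_a, pts_b]), x0)
    ssr_sep = fit_a.ssr + fit_b.ssr
    df_sep = fit_a.df + fit_b.df
    f, p = extra_ss_ftest(shared.ssr, shared.df, ssr_sep, df_sep)
    return CurveComparison(
        ssr_shared=shared.ssr,
        ssr_separate=ssr_sep,
        df_shared=shared.df,
        df_separate=df_sep,
        f_stat=f,
        p_value=p,
        n_a=len(group_a),
        n_b=len(group_b),
    )


def aggregate_profiles(profiles: Sequence[CumulativeProfile]) -> PopulationCurve:
    """Pointwise mean and SEM (sd / sqrt(n)) across cells sharing an x grid."""
    if len(profiles) < 2:
        raise ValidationError("SEM undefined: need at least 2 profiles")
    x = profiles[0].x
    for p in profiles[1:]:
        if not np.array_equal(p.x, x):
            raise ValidationError("profiles do not share the same x grid")
    ys = np.stack([p.y for p in profiles])
    return PopulationCurve(
        x=x.copy(),
        mean_y=ys.mean(axis=0),
        sem_y=ys.std(axis=0, ddof=1) / np.sqrt(len(profiles)),
        n_cells=len(profiles),
    )


def two_tailed_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-sample t statistic and two-tailed p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return t, p
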