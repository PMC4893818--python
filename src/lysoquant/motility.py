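"""Organelle motility from time-lapse movies via Pearson-correlation decay.

The motility readout compares the first frame of a movie with every later
frame using the Pearson correlation coefficient (PCC) of the two intensity
vectors over an above-background pixel set.  Immobile organelles keep the
image similar to frame 0 (PCC stays high); motile organelles decorrelate
it, so the PCC decays toward a plateau set by the static structures and
the confinement geometry.  Decay curves are summarized with a one-phase
exponential fit,

    pcc(t) = plateau + (1 - plateau) * exp(-rate * t),

and groups of curves are compared with the same extra sum-of-squares
F-test used for distribution profiles, applied to the decay model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .curvestats import CurveComparison, extra_ss_ftest
from .images import CellMask, ImageFrame, ImageStack, ValidationError

THRESHOLD_MODES = ("union", "intersection", "mask")


@dataclass
class PCCDecayCurve:
    """Pearson correlation of frame 0 vs frame t over a movie."""

    times_s: np.ndarray
    pcc: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.pcc = np.asarray(self.pcc, dtype=float)
        if self.times_s.shape != self.pcc.shape:
            raise ValidationError("times_s and pcc must have equal length")
        if np.any(np.abs(self.pcc) > 1 + 1e-9):
            raise ValidationError("pcc values must lie in [-1, 1]")


@dataclass
class DecayFit:
    """One-phase exponential decay fit of a PCC curve."""

    plateau: float
    rate_per_s: float
    ssr: float
    n_points: int


def _decay_model(t: np.ndarray, plateau: float, rate: float) -> np.ndarray:
    return plateau + (1.0 - plateau) * np.exp(-rate * t)


def pcc(
    frame0: ImageFrame,
    frame_t: ImageFrame,
    mask: CellMask,
    threshold_mode: str = "union",
) -> float:
    """Pearson correlation of two frames on an above-background pixel set.

    Each frame is Otsu-thresholded inside the mask; the evaluation set is
    the pixels above threshold in either frame (``union``, default), in
    both (``intersection``), or the whole mask (``mask``).
    """
    if frame0.shape != frame_t.shape:
        raise ValidationError("frames must share dimensions")
    if threshold_mode not in THRESHOLD_MODES:
        raise ValidationError(f"threshold_mode must be one of {THRESHOLD_MODES}")
    a = frame0.pixels.astype(np.float64)
    b = frame_t.pixels.astype(np.float64)
    m = mask.mask
    if threshold_mode == "mask":
        sel = m
    else:
        above_a = _above_otsu(a, m)
        above_b = _above_otsu(b, m)
        sel = (above_a | above_b) if threshold_mode == "union" else (above_a & above_b)
    if sel.sum() < 10:
        raise ValidationError("fewer than 10 pixels in the evaluation set")
    va = a[sel]
    vb = b[sel]
    if va.std() == 0 or vb.std() == 0:
        raise ValidationError("constant intensity vector: correlation undefined")
    va = va - va.mean()
    vb = vb - vb.mean()
    return float((va @ vb) / np.sqrt((va @ va) * (vb @ vb)))


def _above_otsu(px: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = px[mask]
    if vals.max() == vals.min():
        # no background/foreground split possible; keep everything in-mask
        return mask.copy()
    return (px > threshold_otsu(vals)) & mask


def pcc_decay_curve(
    movie: ImageStack,
    mask: CellMask,
    channel: int | str = 0,
    threshold_mode: str = "union",
    cell_id: str = "",
) -> PCCDecayCurve:
    """PCC of frame 0 against every frame of the movie (frame 0 included)."""
    if movie.n_frames < 2:
        raise ValidationError("movie needs at least 2 frames")
    if movie.frame_interval_s is None:
        raise ValidationError("movie has no frame interval")
    f0 = movie.frame(channel, 0)
    times = np.arange(movie.n_frames) * movie.frame_interval_s
    vals = [1.0]  # pcc(f0, f0) = 1 by construction
    for t in range(1, movie.n_frames):
        vals.append(pcc(f0, movie.frame(channel, t), mask, threshold_mode))
    return PCCDecayCurve(times_s=times, pcc=np.array(vals), cell_id=cell_id)


def fit_decay(curve: PCCDecayCurve) -> DecayFit:
    """Bounded least-squares fit of the one-phase decay model."""
    t = curve.times_s
    y = curve.pcc
    if t.size < 4:
        raise ValidationError("need at least 4 points to fit a decay")
    if np.allclose(y, y[0]):
        # constant curve: rate 0, plateau at the constant level
        return DecayFit(
            plateau=float(y[0]), rate_per_s=0.0, ssr=0.0, n_points=t.size
        )
    span = t.max() - t.min()
    p0 = (float(np.clip(y.min(), -1, 1)), 1.0 / max(span, 1e-9) * 3)
    try:
        popt, _ = curve_fit(
            _decay_model,
            t,
            y,
            p0=p0,
            bounds=([-1.0, 0.0], [1.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        resid0 = y - _decay_model(t, *p0)
        raise RuntimeError(
            f"decay fit did not converge (initial SSR {resid0 @ resid0:.4g})"
        ) from exc
    resid = y - _decay_model(t, *popt)
    return DecayFit(
        plateau=float(popt[0]),
        rate_per_s=float(popt[1]),
        ssr=float(resid @ resid),
        n_points=t.size,
    )


def _pooled_decay_fit(curves: Sequence[PCCDecayCurve]) -> tuple[float, int]:
    t = np.concatenate([c.times_s for c in curves])
    y = np.concatenate([c.pcc for c in curves])
    fit = fit_decay(PCCDecayCurve(times_s=t, pcc=y))
    return fit.ssr, t.size - 2


def compare_decay(
    group_a: Sequence[PCCDecayCurve], group_b: Sequence[PCCDecayCurve]
) -> CurveComparison:
    """Extra sum-of-squares F-test of shared vs separate one-phase decays."""
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValidationError("each group needs at least one curve")
    ssr_a, df_a = _pooled_decay_fit(group_a)
    ssr_b, df_b = _pooled_decay_fit(group_b)
    ssr_shared, df_shared = _pooled_decay_fit(list(group_a) + list(group_b))
    ssr_sep = ssr_a + ssr_b
    df_sep = df_a + df_b
    f, p = extra_ss_ftest(ssr_shared, df_shared, ssr_sep, df_sep)
    return CurveComparison(
        ssr_shared=ssr_shared,
        ssr_separate=ssr_sep,
        df_shared=df_shared,
        df_separate=df_sep,
        f_stat=f,
        p_value=p,
        n_a=len(group_a),
        n_b=len(group_b),
    )
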