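"""Eccentricity-dependent degradation of shape stimuli.

Peripheral vision resolves progressively lower spatial frequencies.  We model
this with the classic exponential contrast-threshold law

    CT(f, e) = CT0 * exp(alpha * f * (e + e2) / e2)

where ``f`` is spatial frequency in cycles/deg, ``e`` retinal eccentricity in
degrees, and ``alpha = 0.106``, ``CT0 = 1/75``, ``e2 = 2.3`` deg are the
standard empirical constants.  Inverting the law at a maximum displayable
contrast gives a cut-off frequency per eccentricity, and blending a Gaussian
pyramid of the binary shape mask according to the local cut-off yields a
"foveated" soft-membership image: crisp at the current fixation, increasingly
blurred at the periphery.  Gaze-policy solvers consume these soft values as
target-location prior weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CSFParams",
    "FoveatedGrid",
    "contrast_threshold",
    "contrast_sensitivity",
    "cutoff_frequency",
    "foveate_grid",
    "SIGMA_CUTOFF_CONSTANT",
]

#: Gaussian half-amplitude relation: a Gaussian blur of width ``sigma`` (deg)
#: attenuates frequency ``f`` by exp(-2 pi^2 sigma^2 f^2); solving for the
#: half-amplitude point gives sigma = sqrt(ln 2 / 2) / (pi * f) = 0.18740 / f.
SIGMA_CUTOFF_CONSTANT = math.sqrt(math.log(2.0) / 2.0) / math.pi


@dataclass(frozen=True)
class CSFParams:
    """Constants of the contrast-threshold law.

    ``ct_max`` is the contrast ceiling at which the cut-off frequency is
    solved (1.0 = 100% contrast: beyond the cut-off even a full-contrast
    grating is invisible).
    """

    alpha: float = 0.106
    ct0: float = 1.0 / 75.0
    e2: float = 2.3
    ct_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.ct0:
            raise ValueError("ct0 must be positive")
        if not self.e2 > 0:
            raise ValueError("e2 must be positive")


@dataclass
class FoveatedGrid:
    """Soft shape membership in [0, 1] after simulated acuity loss.

    Shares the grid convention of :class:`gazeplan.shapes.ShapeGrid`:
    ``values[i, j]`` lives at ``(x0 + j*cell, y0 + i*cell)`` in degrees of
    visual angle, y up, origin at screen center.
    """

    values: np.ndarray
    cell_size_deg: float
    x0: float
    y0: float
    fixation: tuple[float, float]
    shape_id: str = ""


def _check_nonneg(f, e) -> None:
    if np.any(np.asarray(f) < 0):
        raise ValueError("spatial frequency must be >= 0")
    if np.any(np.asarray(e) < 0):
        raise ValueError("eccentricity must be >= 0")


def contrast_threshold(f, e, params: CSFParams = CSFParams()):
    """CT(f, e) = CT0 * exp(alpha * f * (e + e2) / e2).

    Strictly increasing in both ``f`` and (for f > 0) ``e``: peripheral,
    high-frequency content needs more contrast to be seen.
    """
    _check_nonneg(f, e)
    f = np.asarray(f, dtype=float)
    e = np.asarray(e, dtype=float)
    out = params.ct0 * np.exp(params.alpha * f * (e + params.e2) / params.e2)
    return out if out.ndim else float(out)


def contrast_sensitivity(f, e, params: CSFParams = CSFParams()):
    """CS = 1 / CT."""
    ct = contrast_threshold(f, e, params)
    return 1.0 / ct


def cutoff_frequency(e, params: CSFParams = CSFParams()):
    """Highest visible frequency at eccentricity ``e``.

    Solves CT(f, e) = ct_max in closed form:
    f_c = e2 * ln(ct_max / CT0) / (alpha * (e + e2)), strictly decreasing
    in eccentricity, halved at e = e2.
    """
    _check_nonneg(0.0, e)
    if params.ct_max <= params.ct0:
        raise ValueError("ct_max must exceed ct0 for a positive cutoff")
    e = np.asarray(e, dtype=float)
    out = params.e2 * math.log(params.ct_max / params.ct0) / (params.alpha * (e + params.e2))
    return out if out.ndim else float(out)


def foveate_grid(
    shape,
    fixation,
    params: CSFParams = CSFParams(),
    pyramid_levels: int = 6,
) -> FoveatedGrid:
    """Foveate a shape mask around a fixation point.

    A Gaussian pyramid of the mask is built whose level ``k`` has
    half-amplitude frequency ``f_max / 2**k`` with ``f_max`` the foveal
    cut-off; each cell is linearly interpolated between the two pyramid
    levels bracketing its local cut-off frequency.  Cells at the fixation
    itself reproduce the binary mask exactly, and a constant image is left
    unchanged (low-pass filters preserve DC).

    Parameters
    ----------
    shape:
        A ``ShapeGrid`` (or any object with ``mask``/``values``,
        ``cell_size_deg``, ``x0``, ``y0``).
    fixation:
        (x_deg, y_deg) center of gaze.
    pyramid_levels:
        Number of blur levels (>= 2); frequency ladder is geometric with
        ratio 2.
    """
    fx, fy = float(fixation[0]), float(fixation[1])
    if not (math.isfinite(fx) and math.isfinite(fy)):
        raise ValueError("fixation must be finite")
    if pyramid_levels < 2:
        raise ValueError("pyramid_levels must be >= 2")

    base = getattr(shape, "mask", None)
    if base is None:
        base = shape.values
    base = np.asarray(base, dtype=float)
    cs = float(shape.cell_size_deg)

    f_max = cutoff_frequency(0.0, params)
    levels = [base]
    for k in range(1, pyramid_levels):
        f_k = f_max / 2.0**k
        sigma_px = (SIGMA_CUTOFF_CONSTANT / f_k) / cs
        levels.append(ndimage.gaussian_filter(base, sigma=sigma_px, mode="nearest"))
    stack = np.stack(levels)  # (L, H, W)

    h, w = base.shape
    xs = shape.x0 + cs * np.arange(w)
    ys = shape.y0 + cs * np.arange(h)
    ecc = np.hypot(xs[None, :] - fx, ys[:, None] - fy)
    f_c = cutoff_frequency(ecc, params)
    # fractional pyramid position; 0 at the fovea, clipped at the coarsest level
    t = np.clip(np.log2(f_max / f_c), 0.0, pyramid_levels - 1.0)
    lo = np.floor(t).astype(int)
    hi = np.minimum(lo + 1, pyramid_levels - 1)
    frac = t - lo

    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    vals = (1.0 - frac) * stack[lo, ii, jj] + frac * stack[hi, ii, jj]
    vals = np.clip(vals, 0.0, 1.0)

    return FoveatedGrid(
        values=vals,
        cell_size_deg=cs,
        x0=float(shape.x0),
        y0=float(shape.y0),
        fixation=(fx, fy),
        shape_id=getattr(shape, "shape_id", ""),
    )
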