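"""Irregular search-shape stimuli.

Shapes are made the way the gaze-contingent search experiment makes them:
a handful of points drawn uniformly in a bounded square (23.24 x 23.24 deg of
visual angle), a closed B-spline through the points, the enclosed region
rasterized onto a regular grid in degrees of visual angle, filled (in the
display) with a white-noise texture, upscaled by 1.5 and centered on the
screen.  A model-driven selection step then picks shapes on which the greedy
and planning gaze policies maximally diverge or coincide in their first
fixation.

Grid convention: ``mask[i, j]`` is the cell centered at
``(x0 + j*cell, y0 + i*cell)``; x rightward, y upward, origin at screen
center; mirroring is x-negation.  The white-noise texture is cosmetic
metadata (a stored seed): only the mask drives the models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage

from .observers import ModelSpec, solve_myopic, solve_planned

__all__ = [
    "DEFAULT_BOUND_DEG",
    "DEFAULT_CELL_DEG",
    "DEFAULT_UPSCALE",
    "ControlPoints",
    "SplineShape",
    "ShapeGrid",
    "DivergenceReport",
    "DegenerateGeometryError",
    "StimulusShortageError",
    "draw_control_points",
    "fit_closed_bspline",
    "rasterize",
    "scale_shape",
    "mirror_shape",
    "policy_divergence",
    "generate_stimulus_set",
    "shape_to_json",
    "shape_from_json",
    "save_shape",
    "load_shape",
]

DEFAULT_BOUND_DEG = 23.24
DEFAULT_CELL_DEG = 0.25
DEFAULT_UPSCALE = 1.5

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class DegenerateGeometryError(ValueError):
    """Raised when a curve encloses no area or the points are collinear."""


class StimulusShortageError(RuntimeError):
    """Raised when a requested shape category cannot be filled; carries the
    full candidate log so the shortage is explicit, not silently truncated."""

    def __init__(self, message: str, log: list[dict]):
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class ControlPoints:
    points: np.ndarray  # (n, 2) degrees
    bound_deg: float
    seed: int


def draw_control_points(
    seed: int, n_points: int = 5, bound_deg: float = DEFAULT_BOUND_DEG
) -> ControlPoints:
    """n i.i.d. uniform points in the centered square of side ``bound_deg``."""
    if n_points < 4:
        raise ValueError("need at least 4 control points for a closed spline fit")
    if not bound_deg > 0:
        raise ValueError("bound_deg must be positive")
    rng = np.random.default_rng(seed)
    half = bound_deg / 2.0
    pts = rng.uniform(-half, half, size=(int(n_points), 2))
    return ControlPoints(points=pts, bound_deg=float(bound_deg), seed=int(seed))


@dataclass(frozen=True)
class SplineShape:
    """Closed (periodic) parametric B-spline, evaluable on [0, 1]."""

    degree: int
    knots: np.ndarray
    coefficients: tuple[np.ndarray, np.ndarray]
    closed: bool = True

    @property
    def tck(self):
        return (self.knots, [self.coefficients[0], self.coefficients[1]], self.degree)

    def evaluate(self, t):
        x, y = interpolate.splev(np.asarray(t, dtype=float), self.tck)
        return np.asarray(x), np.asarray(y)

    def polygon(self, n_samples: int = 1024) -> np.ndarray:
        t = np.linspace(0.0, 1.0, n_samples, endpoint=False)
        x, y = self.evaluate(t)
        return np.column_stack([x, y])


def fit_closed_bspline(cp: ControlPoints, degree: int = 3) -> SplineShape:
    """Interpolating periodic B-spline through the control points
    (chord-length parameterization, closure enforced by periodicity)."""
    if degree < 2:
        raise ValueError("degree must be >= 2")
    pts = np.asarray(cp.points, dtype=float)
    if len(pts) < degree + 1:
        raise ValueError("need at least degree+1 control points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1e-12):
        raise DegenerateGeometryError("control points are (near-)collinear")
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], per=1, k=degree, s=0.0)
    knots, coeffs, k = tck
    return SplineShape(
        degree=int(k),
        knots=np.asarray(knots),
        coefficients=(np.asarray(coeffs[0]), np.asarray(coeffs[1])),
    )


@dataclass
class ShapeGrid:
    """Rasterized binary stimulus mask on a regular grid (degrees)."""

    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    cell_size_deg: float
    x0: float
    y0: float
    shape_id: str = ""
    texture_seed: int = 0
    scale_factor: float = 1.0
    control_points: ControlPoints | None = None
    spline: SplineShape | None = None

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + self.cell_size_deg * np.arange(self.mask.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + self.cell_size_deg * np.arange(self.mask.shape[0])

    @property
    def area_deg2(self) -> float:
        return float(self.mask.sum()) * self.cell_size_deg**2

    @property
    def n_components(self) -> int:
        return int(ndimage.label(self.mask > 0, structure=_FOUR_CONN)[1])

    def support_centers(self) -> np.ndarray:
        ii, jj = np.nonzero(self.mask)
        return np.column_stack(
            [self.x0 + self.cell_size_deg * jj, self.y0 + self.cell_size_deg * ii]
        )

    def bbox_deg(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the occupied cell centers."""
        pts = self.support_centers()
        return (
            float(pts[:, 0].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].min()),
            float(pts[:, 1].max()),
        )

    def fits_bound(self, bound_deg: float = DEFAULT_BOUND_DEG) -> bool:
        xmin, xmax, ymin, ymax = self.bbox_deg()
        half = bound_deg / 2.0 + self.cell_size_deg / 2.0
        return max(abs(xmin), abs(xmax), abs(ymin), abs(ymax)) <= half


def _points_in_polygon(q: np.ndarray, poly: np.ndarray, rule: str = "evenodd") -> np.ndarray:
    """Vectorized point-in-polygon with a selectable fill rule.

    even-odd: crossing-number parity (self-intersecting outlines yield
    multiple lobes); nonzero: winding number.  Edges are processed in chunks
    to bound the broadcast memory.
    """
    if rule not in ("evenodd", "nonzero"):
        raise ValueError(f"unknown fill rule {rule!r}")
    qx = q[:, 0][:, None]
    qy = q[:, 1][:, None]
    px, py = poly[:, 0], poly[:, 1]
    px2, py2 = np.roll(px, -1), np.roll(py, -1)
    acc = np.zeros(len(q), dtype=np.int64)
    chunk = 128
    for s in range(0, len(poly), chunk):
        x1, y1 = px[s : s + chunk][None, :], py[s : s + chunk][None, :]
        x2, y2 = px2[s : s + chunk][None, :], py2[s : s + chunk][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (qy - y1) * (x2 - x1) / (y2 - y1)
        if rule == "evenodd":
            crosses = ((y1 > qy) != (y2 > qy)) & (qx < xint)
            acc += crosses.sum(axis=1)
        else:
            up = (y1 <= qy) & (y2 > qy) & (qx < xint)
            down = (y2 <= qy) & (y1 > qy) & (qx < xint)
            acc += up.sum(axis=1) - down.sum(axis=1)
    return (acc % 2 == 1) if rule == "evenodd" else (acc != 0)


def rasterize(
    curve,
    cell_size_deg: float = DEFAULT_CELL_DEG,
    fill_rule: str = "evenodd",
    margin_deg: float = 6.5,
    n_samples: int = 1024,
    shape_id: str = "",
    texture_seed: int = 0,
) -> ShapeGrid:
    """Rasterize a closed curve: a cell is inside iff its center is interior
    under ``fill_rule``.  The grid covers the curve's bounding box plus
    ``margin_deg`` (at least one search radius) and is symmetric about both
    axes so that mirroring is an exact column flip."""
    if not cell_size_deg > 0:
        raise ValueError("cell_size_deg must be positive")
    if isinstance(curve, SplineShape):
        poly = curve.polygon(n_samples)
        spline = curve
    else:
        poly = np.asarray(curve, dtype=float)
        spline = None
    cs = float(cell_size_deg)
    kx = math.ceil((np.abs(poly[:, 0]).max() + margin_deg) / cs)
    ky = math.ceil((np.abs(poly[:, 1]).max() + margin_deg) / cs)
    xs = np.arange(-kx, kx + 1) * cs
    ys = np.arange(-ky, ky + 1) * cs
    # only cells inside the outline's bounding box can be interior
    jx = np.flatnonzero((xs >= poly[:, 0].min() - cs) & (xs <= poly[:, 0].max() + cs))
    jy = np.flatnonzero((ys >= poly[:, 1].min() - cs) & (ys <= poly[:, 1].max() + cs))
    gx, gy = np.meshgrid(xs[jx], ys[jy])
    q = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.zeros((len(ys), len(xs)), dtype=bool)
    inside[np.ix_(jy, jx)] = _points_in_polygon(q, poly, fill_rule).reshape(
        len(jy), len(jx)
    )
    if not inside.any():
        raise DegenerateGeometryError("curve encloses no grid cell")
    return ShapeGrid(
        mask=inside.astype(np.uint8),
        cell_size_deg=cs,
        x0=float(xs[0]),
        y0=float(ys[0]),
        shape_id=shape_id,
        texture_seed=texture_seed,
        spline=spline,
    )


def scale_shape(shape: ShapeGrid, factor: float) -> ShapeGrid:
    """Scale the shape by ``factor`` about its bounding-box center and center
    the result on the screen origin (area scales by factor**2 within
    rasterization tolerance)."""
    if not factor > 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return replace(shape, mask=shape.mask.copy())
    if shape.spline is not None:
        poly = shape.spline.polygon()
        center = (poly.min(axis=0) + poly.max(axis=0)) / 2.0
        new_poly = (poly - center) * factor
        cx, cy = shape.spline.coefficients
        new_spline = SplineShape(
            degree=shape.spline.degree,
            knots=shape.spline.knots.copy(),
            coefficients=((cx - center[0]) * factor, (cy - center[1]) * factor),
        )
        out = rasterize(new_poly, shape.cell_size_deg, shape_id=shape.shape_id,
                        texture_seed=shape.texture_seed)
        return replace(out, spline=new_spline, control_points=shape.control_points,
                       scale_factor=shape.scale_factor * factor)
    # mask-only fallback: sample the original mask at output cell centers
    # mapped through the inverse scaling about the mask center (linear
    # interpolation, 0.5 level set) so the area scales without a half-cell
    # dilation bias, then recenter the bbox on the origin
    h, w = shape.mask.shape
    ho, wo = math.ceil(h * factor), math.ceil(w * factor)
    ci_in, cj_in = (h - 1) / 2.0, (w - 1) / 2.0
    ci_out, cj_out = (ho - 1) / 2.0, (wo - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
    coords = np.stack([(ii - ci_out) / factor + ci_in,
                       (jj - cj_out) / factor + cj_in])
    sampled = ndimage.map_coordinates(shape.mask.astype(float), coords,
                                      order=1, mode="constant", cval=0.0)
    zoomed = sampled > 0.5
    if not zoomed.any():
        raise DegenerateGeometryError("scaled mask is empty")
    nz_i, nz_j = np.nonzero(zoomed)
    cs = shape.cell_size_deg
    ci = (nz_i.min() + nz_i.max()) / 2.0
    cj = (nz_j.min() + nz_j.max()) / 2.0
    return replace(
        shape,
        mask=zoomed.astype(np.uint8),
        x0=-cj * cs,
        y0=-ci * cs,
        scale_factor=shape.scale_factor * factor,
        spline=None,
    )


def mirror_shape(shape: ShapeGrid) -> ShapeGrid:
    """Reflect about the vertical screen axis (x -> -x); an involution."""
    w = shape.mask.shape[1]
    x_last = shape.x0 + (w - 1) * shape.cell_size_deg
    spline = shape.spline
    if spline is not None:
        spline = SplineShape(
            degree=spline.degree,
            knots=spline.knots.copy(),
            coefficients=(-spline.coefficients[0], spline.coefficients[1].copy()),
        )
    cp = shape.control_points
    if cp is not None:
        cp = ControlPoints(cp.points * np.array([-1.0, 1.0]), cp.bound_deg, cp.seed)
    return replace(shape, mask=shape.mask[:, ::-1].copy(), x0=-x_last,
                   spline=spline, control_points=cp)


@dataclass
class DivergenceReport:
    """How far apart the greedy and planning scanpaths are on a shape.

    ``d_first_*`` compare first fixations; ``d_scanpath_myopic_vs_planned``
    is the worst per-step distance between the two policies' long-condition
    fixation sequences (a shape only counts as truly coincident when the
    *whole* scanpaths agree, the way the experiment's similar-policy stimuli
    were chosen)."""

    shape_id: str
    d_first_short_long_planned: float
    d_first_myopic_vs_planned: float
    d_scanpath_myopic_vs_planned: float
    category: str  # "divergent" | "coincident"


def policy_divergence(
    shape: ShapeGrid,
    spec: ModelSpec,
    threshold_deg: float = 2.0,
    *,
    solver_cell_deg: float = 1.0,
    refine: bool = False,
) -> DivergenceReport:
    """Distance between the planning policy's first fixation in the short vs.
    long condition, and between the greedy and planning policies in the long
    condition; a shape is "divergent" iff the first-fixation distance between
    the policies exceeds ``threshold_deg``."""
    opts = dict(solver_cell_deg=solver_cell_deg, refine=refine)
    f_short = solve_planned(shape, replace(spec, policy="planned", horizon=1), **opts)
    f_long = solve_planned(shape, replace(spec, policy="planned", horizon=2), **opts)
    f_myo = solve_myopic(shape, replace(spec, policy="myopic", horizon=2), **opts)
    p_s = f_short.planned_targets[0]
    d_sl = float(np.linalg.norm(p_s - f_long.planned_targets[0]))
    step_d = np.linalg.norm(f_myo.planned_targets - f_long.planned_targets, axis=1)
    return DivergenceReport(
        shape_id=shape.shape_id,
        d_first_short_long_planned=d_sl,
        d_first_myopic_vs_planned=float(step_d[0]),
        d_scanpath_myopic_vs_planned=float(step_d.max()),
        category="divergent" if step_d[0] > threshold_deg else "coincident",
    )


def generate_stimulus_set(
    n_candidates: int,
    seed: int,
    spec: ModelSpec,
    n_divergent: int,
    n_coincident: int,
    *,
    bound_deg: float = DEFAULT_BOUND_DEG,
    n_points: int = 5,
    degree: int = 3,
    cell_size_deg: float = DEFAULT_CELL_DEG,
    upscale: float = DEFAULT_UPSCALE,
    threshold_deg: float = 2.0,
    area_band: float = 0.35,
    solver_cell_deg: float = 1.0,
    verify_cell_deg: float = 0.5,
    verify_refine: bool = True,
) -> tuple[list[ShapeGrid], list[DivergenceReport], list[dict]]:
    """Generate candidate shapes and select the most divergent / most
    coincident ones.

    Two stages: a cheap screening pass at ``solver_cell_deg`` categorizes
    every candidate (divergent ranked by descending greedy-vs-planned
    first-fixation distance, coincident by ascending whole-scanpath
    distance), then the ranked finalists are re-solved at the finer
    ``verify_cell_deg`` (with local refinement) and only accepted when the
    category survives: divergent shapes must still split the first
    fixations, coincident shapes must agree along the whole scanpath.

    Candidates whose unscaled outline leaves the bounded sampling square,
    with more than two 4-connected lobes, or whose covered area falls
    outside ``1 +/- area_band`` of their category median, are logged and
    skipped.  Raises :class:`StimulusShortageError` when a category cannot
    be filled.
    """
    if n_divergent + n_coincident > n_candidates:
        raise ValueError("cannot request more shapes than candidates")
    rng = np.random.default_rng(seed)
    cand_seeds = rng.integers(0, 2**31 - 1, size=n_candidates)
    texture_seeds = rng.integers(0, 2**31 - 1, size=n_candidates)

    log: list[dict] = []
    pool: list[tuple[ShapeGrid, DivergenceReport, dict]] = []
    for i in range(n_candidates):
        entry: dict = {"candidate": i, "seed": int(cand_seeds[i])}
        log.append(entry)
        try:
            cp = draw_control_points(int(cand_seeds[i]), n_points, bound_deg)
            spline = fit_closed_bspline(cp, degree)
            poly = spline.polygon()
            if np.abs(poly).max() > bound_deg / 2.0:
                entry["status"] = "outline exceeds sampling square"
                continue
            # scale about the bbox center and center on the screen, then
            # rasterize once (same outcome as rasterize -> scale_shape)
            center = (poly.min(axis=0) + poly.max(axis=0)) / 2.0
            scaled_spline = SplineShape(
                degree=spline.degree,
                knots=spline.knots.copy(),
                coefficients=(
                    (spline.coefficients[0] - center[0]) * upscale,
                    (spline.coefficients[1] - center[1]) * upscale,
                ),
            )
            shape = rasterize(
                scaled_spline, cell_size_deg,
                shape_id=f"cand{i:03d}", texture_seed=int(texture_seeds[i]),
            )
            shape = replace(shape, control_points=cp, scale_factor=upscale)
            ncomp = shape.n_components
            if ncomp not in (1, 2):
                entry["status"] = f"{ncomp} components"
                continue
        except (DegenerateGeometryError, ValueError) as exc:
            entry["status"] = f"degenerate: {exc}"
            continue
        report = policy_divergence(shape, spec, threshold_deg,
                                   solver_cell_deg=solver_cell_deg)
        entry.update(
            status="ok",
            area_deg2=shape.area_deg2,
            n_components=ncomp,
            d_first_short_long_planned=report.d_first_short_long_planned,
            d_first_myopic_vs_planned=report.d_first_myopic_vs_planned,
            category=report.category,
        )
        pool.append((shape, report, entry))

    # area-similarity filter within each screening category (coincident
    # shapes are systematically smaller: agreement is easiest when one or
    # two fixations cover everything)
    for cat in ("divergent", "coincident"):
        members = [(s, r, e) for s, r, e in pool if r.category == cat]
        if not members:
            continue
        med = float(np.median([s.area_deg2 for s, _, _ in members]))
        for s, _, e in members:
            if abs(s.area_deg2 - med) > area_band * med:
                e["status"] = "area outside similarity band"
    pool = [(s, r, e) for s, r, e in pool if e["status"] == "ok"]

    div = sorted(
        (sre for sre in pool if sre[1].category == "divergent"),
        key=lambda sre: -sre[1].d_first_myopic_vs_planned,
    )
    coin = sorted(
        (sre for sre in pool if sre[1].category == "coincident"),
        key=lambda sre: sre[1].d_scanpath_myopic_vs_planned,
    )

    def _verify(ranked, quota, want_divergent):
        accepted = []
        for shape, _, entry in ranked:
            if len(accepted) == quota:
                break
            vrep = policy_divergence(
                shape, spec, threshold_deg,
                solver_cell_deg=verify_cell_deg, refine=verify_refine,
            )
            ok = (
                vrep.category == "divergent"
                if want_divergent
                else vrep.d_scanpath_myopic_vs_planned <= threshold_deg
            )
            entry["verified"] = ok
            entry["d_scanpath_verified"] = vrep.d_scanpath_myopic_vs_planned
            if ok:
                accepted.append((shape, vrep))
            else:
                entry["status"] = "failed fine-grid verification"
        return accepted

    div_ok = _verify(div, n_divergent, want_divergent=True)
    coin_ok = _verify(coin, n_coincident, want_divergent=False)
    if len(div_ok) < n_divergent or len(coin_ok) < n_coincident:
        raise StimulusShortageError(
            f"requested {n_divergent} divergent / {n_coincident} coincident shapes "
            f"but only {len(div_ok)} / {len(coin_ok)} candidates verified",
            log,
        )
    shapes = []
    reports = []
    for rank, (shape, rep) in enumerate(div_ok + coin_ok, start=1):
        sid = f"S{rank}-{rep.category}"
        shapes.append(replace(shape, shape_id=sid))
        reports.append(replace_report(rep, sid))
    return shapes, reports, log


def select_stimuli(
    seed: int,
    spec: ModelSpec,
    n_divergent: int = 2,
    n_coincident: int = 2,
    *,
    initial_candidates: int = 120,
    max_candidates: int = 960,
    **kwargs,
) -> tuple[list[ShapeGrid], list[DivergenceReport], list[dict]]:
    """Like :func:`generate_stimulus_set`, but grows the candidate pool
    (doubling up to ``max_candidates``) until both categories are filled —
    coincident shapes, where the greedy and planning first fixations agree,
    are rare among unconstrained random outlines."""
    n = initial_candidates
    last_exc: StimulusShortageError | None = None
    while n <= max_candidates:
        try:
            return generate_stimulus_set(
                n, seed, spec, n_divergent, n_coincident, **kwargs
            )
        except StimulusShortageError as exc:
            last_exc = exc
            n *= 2
    raise last_exc


def replace_report(rep: DivergenceReport, shape_id: str) -> DivergenceReport:
    return DivergenceReport(
        shape_id=shape_id,
        d_first_short_long_planned=rep.d_first_short_long_planned,
        d_first_myopic_vs_planned=rep.d_first_myopic_vs_planned,
        d_scanpath_myopic_vs_planned=rep.d_scanpath_myopic_vs_planned,
        category=rep.category,
    )


# ---------------------------------------------------------------------------
# JSON round trip (row-major run-length encoded mask; bit-exact floats)


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = mask.ravel().astype(np.int64)
    # alternating run lengths, starting with a (possibly zero) run of 0s
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], h: int, w: int) -> np.ndarray:
    vals = np.zeros(sum(runs), dtype=np.uint8)
    pos = 0
    val = 0
    for r in runs:
        vals[pos : pos + r] = val
        pos += r
        val ^= 1
    return vals.reshape(h, w)


def shape_to_json(shape: ShapeGrid) -> dict:
    h, w = shape.mask.shape
    doc = {
        "shape_id": shape.shape_id,
        "cell_size_deg": shape.cell_size_deg,
        "origin": "screen-center",
        "x0": shape.x0,
        "y0": shape.y0,
        "width_cells": w,
        "height_cells": h,
        "mask_rle": _rle_encode(shape.mask),
        "scale_factor": shape.scale_factor,
        "texture_seed": shape.texture_seed,
    }
    if shape.control_points is not None:
        cp = shape.control_points
        doc["control_points"] = {
            "points": cp.points.tolist(),
            "bound_deg": cp.bound_deg,
            "seed": cp.seed,
        }
    if shape.spline is not None:
        sp = shape.spline
        doc["spline"] = {
            "degree": sp.degree,
            "knots": sp.knots.tolist(),
            "coefficients": [sp.coefficients[0].tolist(), sp.coefficients[1].tolist()],
        }
    return doc


def shape_from_json(doc: dict) -> ShapeGrid:
    mask = _rle_decode(doc["mask_rle"], doc["height_cells"], doc["width_cells"])
    cp = None
    if "control_points" in doc:
        c = doc["control_points"]
        cp = ControlPoints(np.asarray(c["points"]), c["bound_deg"], c["seed"])
    sp = None
    if "spline" in doc:
        s = doc["spline"]
        sp = SplineShape(
            degree=s["degree"],
            knots=np.asarray(s["knots"]),
            coefficients=(np.asarray(s["coefficients"][0]), np.asarray(s["coefficients"][1])),
        )
    return ShapeGrid(
        mask=mask,
        cell_size_deg=doc["cell_size_deg"],
        x0=doc["x0"],
        y0=doc["y0"],
        shape_id=doc["shape_id"],
        texture_seed=doc["texture_seed"],
        scale_factor=doc["scale_factor"],
        control_points=cp,
        spline=sp,
    )


def save_shape(shape: ShapeGrid, path) -> None:
    with open(path, "w") as fh:
        json.dump(shape_to_json(shape), fh)


def load_shape(path) -> ShapeGrid:
    with open(path) as fh:
        return shape_from_json(json.load(fh))
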