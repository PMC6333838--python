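"""Gaze policies for coverage-reward visual search.

The search task is a belief MDP: the target is hidden uniformly inside an
irregular shape, a fixation reveals everything within a circular search area
(radius 6.5 deg), and the probability of answering "target present/absent"
correctly is proportional to the belief mass covered by the union of the
search areas visited.  Three policies over a discretized fixation-candidate
grid are implemented:

* MAP searcher   -- fixates the single most probable target cell.
* myopic/greedy  -- sequentially maximizes the immediate expected reward
                    (the ideal-observer strategy applied step by step).
* planning       -- jointly maximizes the expected total reward of the whole
                    two-fixation sequence (horizon 2, discount gamma = 1).

Bounded-actor extensions: a linear saccade-amplitude cost (``alpha``, in %
detection performance per degree) subtracted from the coverage reward, a
proportional saccadic undershoot applied to executed landings, and optional
foveation of the shape prior (see :mod:`gazeplan.foveation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import foveation as _fov

__all__ = [
    "BeliefState",
    "ModelSpec",
    "RewardBreakdown",
    "Scanpath",
    "PolicyProblem",
    "target_prior",
    "covered",
    "detection_probability",
    "p_correct",
    "step_reward",
    "apply_undershoot",
    "solve_map",
    "solve_myopic",
    "solve_planned",
    "predict_scanpath",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Which policy to run and with which bounded-actor extensions.

    ``cost_alpha`` is in % detection performance per degree of amplitude
    (the printed unit "DP/Deg"); ``undershoot_u`` is the fraction of saccade
    amplitude lost (landing = launch + (1-u)*(target-launch)).  ``gamma`` is
    kept for completeness but fixed at 1 for the finite two-step horizon.
    """

    policy: str = "planned"  # "map" | "myopic" | "planned"
    horizon: int = 2
    search_radius_deg: float = 6.5
    cost_alpha: float = 0.0
    undershoot_u: float = 0.0
    foveation: bool = False
    gamma: float = 1.0
    start_location: tuple[float, float] = (-14.0, 0.0)
    compensate_undershoot: bool = False

    def __post_init__(self) -> None:
        if self.policy not in ("map", "myopic", "planned"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.horizon not in (1, 2):
            raise ValueError("horizon must be 1 or 2")
        if not self.search_radius_deg > 0:
            raise ValueError("search_radius_deg must be positive")
        if self.cost_alpha < 0:
            raise ValueError("cost_alpha must be >= 0")
        if not (0.0 <= self.undershoot_u < 0.5):
            raise ValueError("undershoot_u must lie in [0, 0.5)")


@dataclass
class BeliefState:
    """Probability of the target occupying each supported grid cell."""

    xy: np.ndarray  # (N, 2) cell centers, degrees
    p: np.ndarray  # (N,) probabilities, sum to 1
    cell_size_deg: float

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("belief probabilities must be non-negative")
        total = self.p.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"belief must sum to 1 (got {total})")


@dataclass
class RewardBreakdown:
    detection_prob: float
    amplitude_deg: float
    cost: float
    reward: float


@dataclass
class Scanpath:
    planned_targets: np.ndarray  # (h, 2)
    executed_landings: np.ndarray  # (h, 2)
    rewards: list[RewardBreakdown]
    total_reward: float
    detection_prob: float


def target_prior(grid) -> BeliefState:
    """Uniform 1/N prior over a binary mask, or normalized soft weights for a
    foveated grid (soft membership read as target-location prior weight)."""
    if isinstance(grid, BeliefState):
        return grid
    vals = getattr(grid, "mask", None)
    if vals is None:
        vals = grid.values
    vals = np.asarray(vals, dtype=float)
    ii, jj = np.nonzero(vals > 0)
    if ii.size == 0:
        raise ValueError("empty support: no cell with positive weight")
    cs = float(grid.cell_size_deg)
    xy = np.column_stack([grid.x0 + cs * jj, grid.y0 + cs * ii])
    w = vals[ii, jj]
    return BeliefState(xy=xy, p=w / w.sum(), cell_size_deg=cs)


def covered(cell, fix, radius_deg: float):
    """1 iff the Euclidean distance from cell to fixation is strictly below
    the search radius (the inequality is strict)."""
    cell = np.asarray(cell, dtype=float)
    fix = np.asarray(fix, dtype=float)
    d = np.linalg.norm(cell - fix, axis=-1)
    out = (d < radius_deg).astype(int)
    return out if out.ndim else int(out)


def detection_probability(belief: BeliefState, fixations, radius_deg: float) -> float:
    """Belief mass of the union of search areas; monotone in appended fixations."""
    fixs = np.atleast_2d(np.asarray(fixations, dtype=float))
    if fixs.size == 0:
        raise ValueError("at least one fixation is required")
    d = cdist(belief.xy, fixs)
    cov = (d < radius_deg).any(axis=1)
    return float(belief.p[cov].sum())


def p_correct(detection_prob: float, target_prevalence: float = 0.5) -> float:
    """Probability of a correct present/absent response under the rule
    "respond present iff detected": prevalence*DP + (1-prevalence)."""
    if not (0.0 <= detection_prob <= 1.0 and 0.0 <= target_prevalence <= 1.0):
        raise ValueError("arguments must lie in [0, 1]")
    return target_prevalence * detection_prob + (1.0 - target_prevalence)


def step_reward(belief: BeliefState, fixations, spec: ModelSpec, from_point) -> RewardBreakdown:
    """r = 100 * DP - alpha * ||fix - from||  (DP in %, amplitude in deg)."""
    dp = detection_probability(belief, fixations, spec.search_radius_deg)
    fixs = np.atleast_2d(np.asarray(fixations, dtype=float))
    amp = float(np.linalg.norm(fixs[-1] - np.asarray(from_point, dtype=float)))
    cost = spec.cost_alpha * amp
    return RewardBreakdown(dp, amp, cost, 100.0 * dp - cost)


def apply_undershoot(from_point, target, u: float):
    """Landing point after a proportional undershoot: amplitude shrinks by (1-u)."""
    if not (0.0 <= u < 1.0):
        raise ValueError("undershoot fraction must lie in [0, 1)")
    f = np.asarray(from_point, dtype=float)
    t = np.asarray(target, dtype=float)
    return f + (1.0 - u) * (t - f)


# ---------------------------------------------------------------------------
# solver core


def _tiebreak(score: np.ndarray, amplitude: np.ndarray, prefer=None) -> int:
    """Among near-maximal scores, pick minimal amplitude, then (for pairs)
    maximal early coverage ``prefer`` — detection after the first fixation
    already ends the search, so of two equally rewarding, equally long
    scanpaths the one that covers more mass first is behaviorally prior —
    then the lowest index (candidates are stored in row-major (y, x) order
    in the task frame)."""
    near = np.flatnonzero(score >= score.max() - _TIE_TOL)
    amp = amplitude[near]
    near = near[amp <= amp.min() + _TIE_TOL]
    if prefer is not None and len(near) > 1:
        pref = prefer(near) if callable(prefer) else prefer[near]
        near = near[pref >= pref.max() - _TIE_TOL]
    return int(near[0])


def _aggregate_belief(belief: BeliefState, cell: float):
    """Sum belief mass onto a coarser lattice of spacing ``cell`` (multiples
    of cell).  Identity when the belief already lives on that lattice."""
    key = np.round(belief.xy / cell).astype(np.int64)
    if np.allclose(key * cell, belief.xy, atol=1e-9):
        # already aligned; collapse exact duplicates only
        pass
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    p = np.zeros(len(uniq))
    np.add.at(p, inv, belief.p)
    return uniq * cell, p


class PolicyProblem:
    """Precomputed coverage geometry for one belief + spec.

    Candidates are lattice points (spacing ``solver_cell_deg``) within one
    search radius of the belief support, plus the exact start location.  Any
    cell outside that set covers zero mass and is dominated by staying at the
    start, so restricting to it leaves the argmax unchanged.  All pairwise
    structures are cached so that re-solving at a new cost weight ``alpha``
    is a cheap vectorized argmax (used heavily during model fitting).
    """

    def __init__(
        self,
        belief: BeliefState,
        spec: ModelSpec,
        solver_cell_deg: float | None = None,
        candidate_mode: str = "dilate",
    ):
        self.belief = belief
        self.spec = spec
        self.radius = float(spec.search_radius_deg)
        self.cell = float(solver_cell_deg or belief.cell_size_deg)
        self.start = np.asarray(spec.start_location, dtype=float)

        self.support_xy, self.support_p = _aggregate_belief(belief, self.cell)

        lo = self.support_xy.min(axis=0) - self.radius
        hi = self.support_xy.max(axis=0) + self.radius
        jx = np.arange(math.floor(lo[0] / self.cell), math.ceil(hi[0] / self.cell) + 1)
        jy = np.arange(math.floor(lo[1] / self.cell), math.ceil(hi[1] / self.cell) + 1)
        gx, gy = np.meshgrid(jx * self.cell, jy * self.cell)
        cand = np.column_stack([gx.ravel(), gy.ravel()])
        if candidate_mode == "dilate":
            dmin, _ = cKDTree(self.support_xy).query(cand)
            cand = cand[dmin < self.radius]
        elif candidate_mode != "full":
            raise ValueError(f"unknown candidate_mode {candidate_mode!r}")
        if not np.any(np.all(np.abs(cand - self.start) < 1e-12, axis=1)):
            cand = np.vstack([cand, self.start])
        # row-major (y, x) order in the task frame: x runs away from the
        # start side, so tie-breaking commutes with mirroring the display
        self._sgn = -1.0 if self.start[0] > 0 else 1.0
        order = np.lexsort((self._sgn * cand[:, 0], cand[:, 1]))
        self.cand = cand[order]

        self.C = cdist(self.cand, self.support_xy) < self.radius
        self.m = self.C @ self.support_p  # single-fixation coverage mass
        self.d0 = np.linalg.norm(self.cand - self.start, axis=1)
        self._G = None
        self._D = None
        self._pair_parts = None
        #: cross-call memo for solved targets (policies are deterministic, so
        #: repeated fits against the same geometry can share solutions)
        self.solve_memo: dict = {}

    # pairwise structures, built lazily (only joint planning needs them)
    @property
    def G(self) -> np.ndarray:
        if self._G is None:
            Cw = self.C * self.support_p
            self._G = Cw @ self.C.T  # overlap mass of two search areas
        return self._G

    @property
    def D(self) -> np.ndarray:
        if self._D is None:
            self._D = cdist(self.cand, self.cand)
        return self._D

    # --- coarse argmax ---
    def best_single(self, alpha: float) -> np.ndarray:
        score = 100.0 * self.m - alpha * self.d0
        return self.cand[_tiebreak(score, self.d0)]

    def _pair_score_parts(self) -> tuple[np.ndarray, np.ndarray]:
        # 100*union and total amplitude are alpha-independent; cache them and
        # release the raw overlap/distance matrices (only needed here)
        if self._pair_parts is None:
            b100 = 100.0 * (self.m[:, None] + self.m[None, :] - self.G)
            amp = self.d0[:, None] + self.D
            self._pair_parts = (b100.ravel(), amp.ravel())
            self._G = None
            self._D = None
        return self._pair_parts

    def best_pair(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        b100, amp = self._pair_score_parts()
        k = _tiebreak(b100 - alpha * amp, amp,
                      prefer=lambda idx: self.m[idx // len(self.cand)])
        i, j = divmod(k, len(self.cand))
        return self.cand[i], self.cand[j]

    def best_second_from_point(self, f1, alpha: float) -> np.ndarray:
        """Greedy continuation: maximize incremental covered mass given a
        (possibly off-lattice) first fixation, minus the saccade cost."""
        f1 = np.asarray(f1, dtype=float)
        cov1 = np.linalg.norm(self.support_xy - f1, axis=1) < self.radius
        overlap = self.C @ (self.support_p * cov1)
        d1 = np.linalg.norm(self.cand - f1, axis=1)
        score = 100.0 * (self.m - overlap) - alpha * d1
        return self.cand[_tiebreak(score, d1)]

    # --- local refinement on the native (fine) belief ---
    def _local_lattice(self, xy, fine_cell: float, window_deg: float) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        k = int(round(window_deg / fine_cell))
        offs = np.arange(-k, k + 1) * fine_cell
        base = np.round(xy / fine_cell) * fine_cell
        gx, gy = np.meshgrid(base[0] + offs, base[1] + offs)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[np.lexsort((self._sgn * pts[:, 0], pts[:, 1]))]
        return np.vstack([pts, xy])

    def refine_single(self, xy, alpha: float, fine_cell: float = 0.25, window_deg: float = 1.0):
        cand = self._local_lattice(xy, fine_cell, window_deg)
        mass = (cdist(cand, self.belief.xy) < self.radius) @ self.belief.p
        d0 = np.linalg.norm(cand - self.start, axis=1)
        return cand[_tiebreak(100.0 * mass - alpha * d0, d0)]

    def refine_pair(self, xy1, xy2, alpha: float, fine_cell: float = 0.25, window_deg: float = 1.0):
        c1 = self._local_lattice(xy1, fine_cell, window_deg)
        c2 = self._local_lattice(xy2, fine_cell, window_deg)
        p = self.belief.p
        C1 = cdist(c1, self.belief.xy) < self.radius
        C2 = cdist(c2, self.belief.xy) < self.radius
        m1 = C1 @ p
        m2 = C2 @ p
        overlap = (C1 * p) @ C2.T
        union = m1[:, None] + m2[None, :] - overlap
        amp = np.linalg.norm(c1 - self.start, axis=1)[:, None] + cdist(c1, c2)
        pref = np.broadcast_to(m1[:, None], union.shape).ravel()
        k = _tiebreak((100.0 * union - alpha * amp).ravel(), amp.ravel(), prefer=pref)
        i, j = divmod(k, len(c2))
        return c1[i], c2[j]

    def refine_second(self, f1, xy2, alpha: float, fine_cell: float = 0.25, window_deg: float = 1.0):
        f1 = np.asarray(f1, dtype=float)
        cand = self._local_lattice(xy2, fine_cell, window_deg)
        cov1 = np.linalg.norm(self.belief.xy - f1, axis=1) < self.radius
        resid = np.where(cov1, 0.0, self.belief.p)
        inc = (cdist(cand, self.belief.xy) < self.radius) @ resid
        d1 = np.linalg.norm(cand - f1, axis=1)
        return cand[_tiebreak(100.0 * inc - alpha * d1, d1)]

    # --- MAP searcher ---
    def map_sequence(self, horizon: int) -> list[np.ndarray]:
        """Fixate the cell of maximal posterior mass; ties resolved by
        distance to the current gaze, then lexicographic; posterior restricted
        to uncovered cells before the second step."""
        gaze = self.start
        active = self.support_p.copy()
        order = np.lexsort((self._sgn * self.support_xy[:, 0], self.support_xy[:, 1]))
        targets = []
        for _ in range(horizon):
            p_ord = active[order]
            d_ord = np.linalg.norm(self.support_xy[order] - gaze, axis=1)
            k = _tiebreak(p_ord, d_ord)
            tgt = self.support_xy[order[k]]
            targets.append(tgt)
            covered_now = np.linalg.norm(self.support_xy - tgt, axis=1) < self.radius
            active = np.where(covered_now, 0.0, active)
            gaze = tgt
        return targets


# ---------------------------------------------------------------------------
# public solvers


def _assemble(belief: BeliefState, targets, spec: ModelSpec) -> Scanpath:
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    u = spec.undershoot_u
    landings = []
    launch = np.asarray(spec.start_location, dtype=float)
    for t in targets:
        aim = t if not spec.compensate_undershoot else launch + (t - launch) / (1.0 - u)
        land = apply_undershoot(launch, aim, u)
        landings.append(land)
        launch = land
    landings = np.asarray(landings)

    rewards = []
    total = 0.0
    prev_dp = 0.0
    launch = np.asarray(spec.start_location, dtype=float)
    for n in range(len(landings)):
        dp_n = detection_probability(belief, landings[: n + 1], spec.search_radius_deg)
        amp = float(np.linalg.norm(landings[n] - launch))
        cost = spec.cost_alpha * amp
        r = 100.0 * (dp_n - prev_dp) - cost
        rewards.append(RewardBreakdown(dp_n, amp, cost, r))
        total += r
        prev_dp = dp_n
        launch = landings[n]
    return Scanpath(targets, landings, rewards, total, prev_dp)


def _prepare(shape_or_belief, spec, solver_cell_deg, problem):
    if problem is not None:
        return problem
    return PolicyProblem(target_prior(shape_or_belief), spec, solver_cell_deg)


def solve_map(
    shape,
    spec: ModelSpec,
    *,
    solver_cell_deg: float | None = None,
    problem: PolicyProblem | None = None,
) -> Scanpath:
    pb = _prepare(shape, spec, solver_cell_deg, problem)
    targets = pb.map_sequence(spec.horizon)
    return _assemble(pb.belief, targets, spec)


def solve_myopic(
    shape,
    spec: ModelSpec,
    *,
    solver_cell_deg: float | None = None,
    refine: bool = False,
    refine_cell_deg: float = 0.25,
    refine_window_deg: float = 1.0,
    problem: PolicyProblem | None = None,
) -> Scanpath:
    """Greedy policy: each fixation maximizes its own incremental reward."""
    pb = _prepare(shape, spec, solver_cell_deg, problem)
    a = spec.cost_alpha
    f1 = pb.best_single(a)
    if refine:
        f1 = pb.refine_single(f1, a, refine_cell_deg, refine_window_deg)
    targets = [f1]
    if spec.horizon == 2:
        f2 = pb.best_second_from_point(f1, a)
        if refine:
            f2 = pb.refine_second(f1, f2, a, refine_cell_deg, refine_window_deg)
        targets.append(f2)
    return _assemble(pb.belief, targets, spec)


def solve_planned(
    shape,
    spec: ModelSpec,
    *,
    solver_cell_deg: float | None = None,
    refine: bool = False,
    refine_cell_deg: float = 0.25,
    refine_window_deg: float = 1.0,
    problem: PolicyProblem | None = None,
) -> Scanpath:
    """Planning policy: joint argmax of the total expected reward over
    ordered fixation pairs (reduces to the single argmax at horizon 1)."""
    pb = _prepare(shape, spec, solver_cell_deg, problem)
    a = spec.cost_alpha
    if spec.horizon == 1:
        f1 = pb.best_single(a)
        if refine:
            f1 = pb.refine_single(f1, a, refine_cell_deg, refine_window_deg)
        return _assemble(pb.belief, [f1], spec)
    f1, f2 = pb.best_pair(a)
    if refine:
        f1, f2 = pb.refine_pair(f1, f2, a, refine_cell_deg, refine_window_deg)
    return _assemble(pb.belief, [f1, f2], spec)


_SOLVERS = {"map": solve_map, "myopic": solve_myopic, "planned": solve_planned}


def predict_scanpath(
    shape,
    condition: str,
    spec: ModelSpec,
    *,
    solver_cell_deg: float = 1.0,
    refine: bool = True,
    refine_cell_deg: float = 0.25,
    refine_window_deg: float = 1.0,
    second_stage_fixation=None,
    csf_params: _fov.CSFParams | None = None,
) -> Scanpath:
    """Full pipeline: (optionally) foveate, solve the policy, undershoot.

    ``condition`` "short" forces horizon 1, "long" horizon 2.  With foveation
    on, the first decision uses the shape foveated at the start location; the
    second decision re-foveates at the executed first landing (simulation
    mode) or at ``second_stage_fixation`` when given (data mode: the
    empirical mean first landing).  Executed landings are the model's
    predicted mean fixation locations.
    """
    if condition not in ("short", "long"):
        raise ValueError("condition must be 'short' or 'long'")
    horizon = 1 if condition == "short" else 2
    spec = replace(spec, horizon=horizon)
    solve = _SOLVERS[spec.policy]
    opts = dict(solver_cell_deg=solver_cell_deg)
    if spec.policy != "map":
        opts.update(refine=refine, refine_cell_deg=refine_cell_deg,
                    refine_window_deg=refine_window_deg)

    true_belief = target_prior(shape)
    if not spec.foveation:
        return solve(shape, spec, **opts)

    csf = csf_params or _fov.CSFParams()
    fov_a = _fov.foveate_grid(shape, spec.start_location, csf)
    path = solve(fov_a, spec, **opts)
    targets = list(path.planned_targets)
    if horizon == 2 and spec.policy != "map":
        l1 = apply_undershoot(spec.start_location, targets[0], spec.undershoot_u)
        center2 = second_stage_fixation if second_stage_fixation is not None else l1
        fov_b = _fov.foveate_grid(shape, center2, csf)
        pb_b = PolicyProblem(target_prior(fov_b), spec, solver_cell_deg)
        f2 = pb_b.best_second_from_point(targets[0], spec.cost_alpha)
        if refine:
            f2 = pb_b.refine_second(targets[0], f2, spec.cost_alpha,
                                    refine_cell_deg, refine_window_deg)
        targets[1] = f2
    return _assemble(true_belief, targets, spec)
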