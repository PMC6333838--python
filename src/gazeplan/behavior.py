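"""Behavioral preprocessing of fixation-sequence tables.

Mirrors the experiment's analysis pipeline: load per-fixation CSV rows into
trials, apply the sequential trial filters (gaze never entered the shape;
wrong number of fixations for the condition; target present), optionally
discard minority search strategies identified with a Gaussian mixture model
on two-lobed shapes, aggregate mean landing positions within subjects, and
contrast bivariate first-fixation means between conditions with a two-sample
Hotelling T^2 test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "FIXATION_COLUMNS",
    "SchemaError",
    "DegenerateDataError",
    "TrialRecord",
    "FilterReport",
    "StrategyClusters",
    "SubjectSummary",
    "HotellingResult",
    "load_fixation_table",
    "write_fixation_table",
    "filter_trials",
    "cluster_strategies",
    "apply_strategy_filter",
    "summarize_subjects",
    "hotelling_t2",
]

#: exact CSV header, one row per fixation, fix_index 1-based
FIXATION_COLUMNS = [
    "subject_id", "block", "trial", "shape_id", "condition", "mirrored",
    "target_present", "target_found", "entered_shape", "fix_index",
    "x_deg", "y_deg", "onset_ms", "duration_ms",
]

_CONDITIONS = ("short", "long")


class SchemaError(ValueError):
    """The fixation table violates the CSV contract."""


class DegenerateDataError(ValueError):
    """Sample too small or covariance singular for the requested statistic."""


@dataclass
class TrialRecord:
    subject_id: str
    block: int
    trial: int
    shape_id: str
    condition: str  # "short" | "long"
    mirrored: int
    target_present: int
    target_found: int
    entered_shape: int
    fixations: np.ndarray  # (k, 4): x_deg, y_deg, onset_ms, duration_ms

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)

    def first_fixation(self) -> np.ndarray:
        return self.fixations[0, :2]


def load_fixation_table(path) -> list[TrialRecord]:
    """Parse a fixation CSV into TrialRecords.

    Structural problems (missing columns) and malformed rows (unknown
    condition token, flag contradictions) raise :class:`SchemaError` naming
    every offending row; nothing is silently dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    bad: list[str] = []
    for idx, row in df.iterrows():
        if row["condition"] not in _CONDITIONS:
            bad.append(f"row {idx}: unknown condition {row['condition']!r}")
        elif int(row["target_found"]) == 1 and int(row["target_present"]) == 0:
            bad.append(f"row {idx}: target_found without target_present")
    if bad:
        raise SchemaError("malformed rows: " + "; ".join(bad))

    records = []
    for (subj, block, trial), grp in df.groupby(
        ["subject_id", "block", "trial"], sort=True
    ):
        grp = grp.sort_values("fix_index")
        records.append(
            TrialRecord(
                subject_id=str(subj),
                block=int(block),
                trial=int(trial),
                shape_id=str(grp["shape_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
                mirrored=int(grp["mirrored"].iloc[0]),
                target_present=int(grp["target_present"].iloc[0]),
                target_found=int(grp["target_found"].iloc[0]),
                entered_shape=int(grp["entered_shape"].iloc[0]),
                fixations=grp[["x_deg", "y_deg", "onset_ms", "duration_ms"]].to_numpy(
                    dtype=float
                ),
            )
        )
    return records


def write_fixation_table(trials: list[TrialRecord], path) -> None:
    rows = []
    for t in trials:
        for k, (x, y, onset, dur) in enumerate(t.fixations, start=1):
            rows.append(
                dict(
                    subject_id=t.subject_id, block=t.block, trial=t.trial,
                    shape_id=t.shape_id, condition=t.condition, mirrored=t.mirrored,
                    target_present=t.target_present, target_found=t.target_found,
                    entered_shape=t.entered_shape, fix_index=k,
                    x_deg=x, y_deg=y, onset_ms=onset, duration_ms=dur,
                )
            )
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


@dataclass
class FilterReport:
    """Telescoping ledger of the sequential trial filters.

    Stage percentages follow the experiment's reporting convention: the
    no-shape-gaze share is taken of the raw input, the wrong-fixation-count
    share of what remains, the target-present share of what remains after
    that, and the strategy share of the post-target-filter pool.
    """

    n_input: int = 0
    n_no_shape_gaze: int = 0
    n_wrong_fixation_count: int = 0
    n_target_present: int = 0
    n_strategy_discarded: int = 0
    n_final: int = 0

    def _pct(self, num: int, denom: int) -> float:
        return 100.0 * num / denom if denom else 0.0

    @property
    def pct_no_shape_gaze(self) -> float:
        return self._pct(self.n_no_shape_gaze, self.n_input)

    @property
    def pct_wrong_fixation_count(self) -> float:
        return self._pct(self.n_wrong_fixation_count, self.n_input - self.n_no_shape_gaze)

    @property
    def pct_target_present(self) -> float:
        return self._pct(
            self.n_target_present,
            self.n_input - self.n_no_shape_gaze - self.n_wrong_fixation_count,
        )

    @property
    def pct_strategy_discarded(self) -> float:
        return self._pct(
            self.n_strategy_discarded,
            self.n_input - self.n_no_shape_gaze - self.n_wrong_fixation_count
            - self.n_target_present,
        )

    def telescopes(self) -> bool:
        removed = (
            self.n_no_shape_gaze + self.n_wrong_fixation_count
            + self.n_target_present + self.n_strategy_discarded
        )
        return self.n_input - removed == self.n_final


_DEFAULT_RULES = {"short": (1,), "long": (2,)}


def filter_trials(
    trials: list[TrialRecord], condition_rules: dict | None = None
) -> tuple[list[TrialRecord], FilterReport]:
    """Apply the sequential filters in the fixed order: (1) gaze never
    entered the shape, (2) wrong fixation count for the condition (1 short /
    2 long), (3) target present (regardless of whether it was found)."""
    rules = condition_rules or _DEFAULT_RULES
    report = FilterReport(n_input=len(trials))
    stage1 = []
    for t in trials:
        if t.entered_shape == 0:
            report.n_no_shape_gaze += 1
        else:
            stage1.append(t)
    stage2 = []
    for t in stage1:
        if t.n_fixations not in rules[t.condition]:
            report.n_wrong_fixation_count += 1
        else:
            stage2.append(t)
    kept = []
    for t in stage2:
        if t.target_present == 1:
            report.n_target_present += 1
        else:
            kept.append(t)
    report.n_final = len(kept)
    return kept, report


@dataclass
class StrategyClusters:
    assignments: np.ndarray  # (n,) component label per trial
    n_components: int
    kept_label: int
    kept_fraction: float
    keep_mask: np.ndarray  # (n,) bool
    component_means: np.ndarray = field(default=None, repr=False)


def cluster_strategies(
    first_fixations, max_components: int = 3, seed: int = 0
) -> StrategyClusters:
    """Identify qualitatively different search strategies from first-fixation
    scatter: full-covariance Gaussian mixtures for k = 1..max_components,
    k selected by BIC, and only the most frequent component kept."""
    pts = np.asarray(first_fixations, dtype=float)
    if len(pts) < 2 * max_components:
        raise ValueError("need at least 2*max_components points")
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            n_init=3, reg_covar=1e-6,
        ).fit(pts)
        b = gm.bic(pts)
        if b < best_bic:
            best_bic = b
            best = gm
    labels = best.predict(pts)
    counts = np.bincount(labels, minlength=best.n_components)
    kept_label = int(np.argmax(counts))
    keep = labels == kept_label
    return StrategyClusters(
        assignments=labels,
        n_components=int(best.n_components),
        kept_label=kept_label,
        kept_fraction=float(keep.mean()),
        keep_mask=keep,
        component_means=best.means_,
    )


def apply_strategy_filter(
    trials: list[TrialRecord],
    report: FilterReport,
    multimodal_shape_ids,
    max_components: int = 3,
    seed: int = 0,
) -> tuple[list[TrialRecord], FilterReport]:
    """Discard minority-strategy trials on the flagged (two-lobed) shapes.

    First fixations are clustered per shape *and condition* in canonical
    orientation: strategy modes are alternative scanpaths under the same
    task demand, so pooling conditions would mistake a genuine
    short-vs-long difference for a strategy split."""
    multimodal = set(multimodal_shape_ids)
    keep_flags = {}
    groups = {}
    for i, t in enumerate(trials):
        if t.shape_id in multimodal:
            groups.setdefault((t.shape_id, t.condition), []).append(i)
    for idx in groups.values():
        if len(idx) < 2 * max_components:
            continue
        pts = np.array([_canonical_xy(trials[i])[0] for i in idx])
        clusters = cluster_strategies(pts, max_components, seed)
        for i, keep in zip(idx, clusters.keep_mask):
            keep_flags[i] = bool(keep)
    kept = []
    for i, t in enumerate(trials):
        if keep_flags.get(i, True):
            kept.append(t)
        else:
            report.n_strategy_discarded += 1
    report.n_final = len(kept)
    return kept, report


def _canonical_xy(trial: TrialRecord) -> np.ndarray:
    """Fixation coordinates reflected to the canonical (unmirrored) layout."""
    xy = trial.fixations[:, :2].copy()
    if trial.mirrored:
        xy[:, 0] = -xy[:, 0]
    return xy


@dataclass
class SubjectSummary:
    """Per-subject mean landing positions and per-slot covariances.

    A slot is a (shape_id, condition, fix_index) triple; ``subject_means``
    is indexed by (subject_id, shape_id, condition, fix_index).  Slots a
    subject never contributed to are simply absent (missing, not zero).
    """

    subject_means: pd.DataFrame
    slot_covariances: dict
    raw_covariances: dict
    observations_by_slot: dict | None = None

    @property
    def slots(self) -> list[tuple]:
        return sorted(self.slot_covariances.keys())

    def observations(self, slot) -> np.ndarray:
        if self.observations_by_slot is not None:
            return self.observations_by_slot[slot]
        shape_id, condition, fix_index = slot
        sel = self.subject_means.xs(
            (shape_id, condition, fix_index),
            level=("shape_id", "condition", "fix_index"),
        )
        return sel[["x", "y"]].to_numpy()

    def grand_means(self) -> dict:
        return {slot: self.observations(slot).mean(axis=0) for slot in self.slots}

    @property
    def n_obs(self) -> int:
        return sum(len(self.observations(s)) for s in self.slots)


def summarize_subjects(trials: list[TrialRecord]) -> SubjectSummary:
    """Mean landing positions aggregated within subjects (mirrored trials
    reflected to the canonical orientation first), plus per-slot covariance
    of the subject means and of the raw fixations."""
    rows = []
    for t in trials:
        for k, (x, y) in enumerate(_canonical_xy(t), start=1):
            rows.append(
                dict(subject_id=t.subject_id, shape_id=t.shape_id,
                     condition=t.condition, fix_index=k, x=x, y=y)
            )
    if not rows:
        raise ValueError("no trials to summarize")
    df = pd.DataFrame(rows)
    means = df.groupby(["subject_id", "shape_id", "condition", "fix_index"])[
        ["x", "y"]
    ].mean()

    slot_cov = {}
    raw_cov = {}
    obs = {}
    for slot, grp in means.groupby(level=["shape_id", "condition", "fix_index"]):
        pts = grp[["x", "y"]].to_numpy()
        key = (slot[0], slot[1], int(slot[2]))
        obs[key] = pts
        slot_cov[key] = np.cov(pts.T, ddof=1) if len(pts) > 1 else None
    for slot, grp in df.groupby(["shape_id", "condition", "fix_index"]):
        pts = grp[["x", "y"]].to_numpy()
        raw_cov[(slot[0], slot[1], int(slot[2]))] = (
            np.cov(pts.T, ddof=1) if len(pts) > 1 else None
        )
    return SubjectSummary(subject_means=means, slot_covariances=slot_cov,
                          raw_covariances=raw_cov, observations_by_slot=obs)


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    mean_a: np.ndarray
    mean_b: np.ndarray
    pooled_cov: np.ndarray


def hotelling_t2(sample_a, sample_b) -> HotellingResult:
    """Two-sample Hotelling T^2 for bivariate means with pooled covariance.

    T^2 = (n1 n2)/(n1+n2) d' S_p^{-1} d with S_p the pooled covariance;
    F = T^2 (n1+n2-p-1) / (p (n1+n2-2)) with (p, n1+n2-p-1) df, p = 2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) arrays")
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise DegenerateDataError("each sample needs at least 3 points")
    p = 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a.T, ddof=1) + (n2 - 1) * np.cov(b.T, ddof=1)) / (
        n1 + n2 - 2
    )
    if np.linalg.cond(s_pooled) > 1e12:
        raise DegenerateDataError("pooled covariance is (near-)singular")
    d = ma - mb
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s_pooled, d))
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, p, df2))
    return HotellingResult(
        t2=t2, f_stat=float(f_stat), df=(p, df2), p_value=p_value,
        mean_a=ma, mean_b=mb, pooled_cov=s_pooled,
    )
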