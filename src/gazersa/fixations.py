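"""Fixation-report parsing, exclusion rules, descriptives and density maps.

The preprocessing stage mirrors standard infant free-viewing practice: trials
are dropped when the participant did not start at screen center, looked only
off-image, made fewer than three fixations, or accumulated less than 1 s of
fixation time; participants contributing fewer than 18 usable trials are
dropped; and each kept trial's gaze is rendered as a Gaussian-smoothed,
min-max-rescaled fixation density map (the ``mat2gray`` convention: 0 at the
least-fixated pixel, 1 at the most-fixated one).

Coordinate convention: 0-based, ``x_px`` is the column, ``y_px`` the row,
origin at the top-left; real-valued positions are rounded half-away-from-zero
to pixel indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

logger = logging.getLogger("gazersa")

REPORT_COLUMNS = [
    "participant_id", "age_group", "trial_index", "scene_id",
    "index_in_trial", "x_px", "y_px", "duration_ms", "started_at_center",
]

#: Exclusion rules in attribution order (a trial carries the first violated rule).
EXCLUSION_RULES = (
    "center_start_fail",    # rule 1: trial did not begin with central fixation
    "outside_image_only",   # rule 2: every fixation fell off the image
    "lt3_fixations",        # rule 3: fewer than three total fixations
    "sum_dur_lt_1000ms",    # rule 4: fixation durations sum to < 1000 ms
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixationRecord:
    index_in_trial: int
    x_px: float
    y_px: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be non-negative")


@dataclass(frozen=True)
class Trial:
    """One 5-s free-viewing of a scene, with its ordered fixation events."""

    participant_id: str
    scene_id: str
    trial_index: int
    fixations: tuple[FixationRecord, ...]
    started_at_center: bool = True

    def __post_init__(self) -> None:
        idx = [f.index_in_trial for f in self.fixations]
        if idx != sorted(idx):
            raise ValueError("fixations must be ordered by index_in_trial")

    @property
    def total_duration_ms(self) -> float:
        return sum(f.duration_ms for f in self.fixations)


@dataclass(frozen=True)
class SubjectSession:
    participant_id: str
    age_group: str
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class DensityMapParams:
    """Density-map construction parameters.

    ``sigma_px`` is the operative Gaussian smoothing sd; ``cutoff_db`` is
    recorded metadata only (the filter's stated low-pass cutoff), since the
    cutoff-to-sigma convention is not applied here.
    """

    image_h: int = 1000
    image_w: int = 1000
    sigma_px: float = 7.21
    cutoff_db: float = -6.0
    drop_first_fixation: bool = True

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.image_h < 1 or self.image_w < 1:
            raise ValueError("image extent must be positive")


@dataclass(frozen=True)
class FixationDensityMap:
    participant_id: str
    scene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("density map contains non-finite values")


@dataclass
class ExclusionReport:
    """Outcome of the trial/subject exclusion cascade.

    ``trial_outcomes`` maps (participant_id, trial_index) to either "kept" or
    the first violated rule; rule percentages for rules 3-4 are computed over
    the trials remaining after the earlier rules, matching how sequential
    exclusion cascades are conventionally reported.
    """

    trial_outcomes: dict[tuple[str, int], str] = field(default_factory=dict)
    excluded_subjects: dict[str, str] = field(default_factory=dict)
    rule_counts: dict[str, int] = field(default_factory=dict)
    rule_percentages: dict[str, float] = field(default_factory=dict)
    n_trials_total: int = 0
    n_trials_kept: int = 0

    def merge(self, other: "ExclusionReport") -> "ExclusionReport":
        out = ExclusionReport(
            trial_outcomes={**self.trial_outcomes, **other.trial_outcomes},
            excluded_subjects={**self.excluded_subjects, **other.excluded_subjects},
            rule_counts={
                k: self.rule_counts.get(k, 0) + other.rule_counts.get(k, 0)
                for k in set(self.rule_counts) | set(other.rule_counts)
            },
            n_trials_total=self.n_trials_total + other.n_trials_total,
            n_trials_kept=self.n_trials_kept + other.n_trials_kept,
        )
        out._recompute_percentages()
        return out

    def _recompute_percentages(self) -> None:
        # rules 1-2 are shares of all trials; rules 3-4 of the trials that
        # survived the earlier rules
        remaining = self.n_trials_total
        pct = {}
        for i, rule in enumerate(EXCLUSION_RULES):
            n = self.rule_counts.get(rule, 0)
            base = self.n_trials_total if i < 2 else remaining
            pct[rule] = 100.0 * n / base if base else 0.0
            remaining -= n
        self.rule_percentages = pct


@dataclass(frozen=True)
class LookingStats:
    """Per-age-group looking descriptives (mean, sd across participants)."""

    table: pd.DataFrame  # index: age_group; columns: n, usable_trials_mean/sd, ...


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_fixation_report(path: str | Path) -> list[SubjectSession]:
    """Parse a tab-separated fixation event report into per-participant sessions.

    The file must carry the documented header columns; malformed rows are
    reported with their line numbers, and duplicate (participant, trial_index)
    pairs are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty fixation report: {path}")
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation report {path} lacks columns: {missing}")
    if df.empty:
        raise ValueError(f"fixation report {path} has a header but no rows")

    bad = df[["x_px", "y_px", "duration_ms"]].apply(
        pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line and 1-basing
        raise ValueError(f"malformed numeric fields in {path} at lines {lines}")

    sessions = []
    for pid, sub in df.groupby("participant_id", sort=True):
        groups = sorted(sub["age_group"].unique())
        if len(groups) > 1:
            raise ValueError(f"participant {pid} appears in multiple age groups: {groups}")
        trials = []
        for (tidx, scene), tri in sub.groupby(["trial_index", "scene_id"], sort=True):
            tri = tri.sort_values("index_in_trial")
            fixations = tuple(
                FixationRecord(int(r.index_in_trial), float(r.x_px), float(r.y_px),
                               float(r.duration_ms))
                for r in tri.itertuples()
            )
            center = bool(tri["started_at_center"].iloc[0] in (True, "true", "True", 1))
            trials.append(Trial(str(pid), str(scene), int(tidx), fixations, center))
        seen = [t.trial_index for t in trials]
        dups = {i for i in seen if seen.count(i) > 1}
        if dups:
            raise ValueError(f"duplicate trial for participant {pid}: indices {sorted(dups)}")
        sessions.append(SubjectSession(str(pid), str(groups[0]), tuple(trials)))
    return sessions


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def _in_image(f: FixationRecord, params: DensityMapParams) -> bool:
    xi, yi = _round_half_away(f.x_px), _round_half_away(f.y_px)
    return 0 <= xi < params.image_w and 0 <= yi < params.image_h


def _first_violated_rule(trial: Trial, params: DensityMapParams) -> str | None:
    if not trial.started_at_center:
        return "center_start_fail"
    if trial.fixations and not any(_in_image(f, params) for f in trial.fixations):
        return "outside_image_only"
    if len(trial.fixations) < 3:
        return "lt3_fixations"
    if trial.total_duration_ms < 1000.0:
        return "sum_dur_lt_1000ms"
    return None


def apply_trial_exclusions(
    session: SubjectSession, params: DensityMapParams
) -> tuple[SubjectSession, ExclusionReport]:
    """Drop trials violating the four sequential exclusion rules.

    Each excluded trial is attributed to the first rule it violates, in rule
    order (center start, off-image only, <3 fixations, <1000 ms total).
    """
    report = ExclusionReport(n_trials_total=len(session.trials),
                             rule_counts={r: 0 for r in EXCLUSION_RULES})
    kept = []
    for trial in session.trials:
        rule = _first_violated_rule(trial, params)
        key = (session.participant_id, trial.trial_index)
        if rule is None:
            report.trial_outcomes[key] = "kept"
            kept.append(trial)
        else:
            report.trial_outcomes[key] = rule
            report.rule_counts[rule] += 1
    report.n_trials_kept = len(kept)
    report._recompute_percentages()
    return replace(session, trials=tuple(kept)), report


def apply_subject_exclusion(
    sessions: list[SubjectSession], min_trials: int = 18
) -> tuple[list[SubjectSession], ExclusionReport]:
    """Drop participants contributing fewer than ``min_trials`` usable trials."""
    report = ExclusionReport()
    kept = []
    for s in sessions:
        if len(s.trials) < min_trials:
            report.excluded_subjects[s.participant_id] = "lt18_usable_trials"
        else:
            kept.append(s)
    if sessions and not kept:
        logger.warning("all %d participants excluded (<%d usable trials)",
                       len(sessions), min_trials)
    return kept, report


def compute_looking_stats(sessions: list[SubjectSession]) -> LookingStats:
    """Per-group looking descriptives over usable trials.

    For each participant: usable-trial count, mean fixations per trial, mean
    fixation duration, mean total looking per trial; then mean and sd across
    participants within each age group (ddof=1).
    """
    rows = []
    for s in sessions:
        if not s.trials:
            continue
        nfix = [len(t.fixations) for t in s.trials]
        durs = [f.duration_ms for t in s.trials for f in t.fixations]
        rows.append({
            "age_group": s.age_group,
            "usable_trials": len(s.trials),
            "fixations_per_trial": float(np.mean(nfix)),
            "fixation_duration_ms": float(np.mean(durs)) if durs else np.nan,
            "total_look_ms": float(np.mean([t.total_duration_ms for t in s.trials])),
        })
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        return LookingStats(table=pd.DataFrame())
    agg = per_subject.groupby("age_group").agg(
        n=("usable_trials", "size"),
        usable_trials_mean=("usable_trials", "mean"),
        usable_trials_sd=("usable_trials", "std"),
        fixations_per_trial_mean=("fixations_per_trial", "mean"),
        fixations_per_trial_sd=("fixations_per_trial", "std"),
        fixation_duration_mean=("fixation_duration_ms", "mean"),
        fixation_duration_sd=("fixation_duration_ms", "std"),
        total_look_mean=("total_look_ms", "mean"),
        total_look_sd=("total_look_ms", "std"),
    )
    return LookingStats(table=agg)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def _round_half_away(v: float) -> int:
    return int(np.sign(v) * np.floor(abs(v) + 0.5))


def gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Unnormalized-then-normalized 1-D Gaussian taps over [-radius, radius]."""
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_counts(counts: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with zero-padded borders.

    Separable convolution with a kernel truncated at 8.5 sigma (tail mass
    below 1e-15), numerically equivalent to a dense 2-D convolution.
    """
    radius = min(int(np.ceil(8.5 * sigma)), max(counts.shape))
    k = gaussian_kernel(sigma, radius)
    out = convolve1d(counts, k, axis=0, mode="constant", cval=0.0)
    return convolve1d(out, k, axis=1, mode="constant", cval=0.0)


def mat2gray(m: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant input maps to all zeros."""
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def density_map(trial: Trial, params: DensityMapParams) -> FixationDensityMap:
    """Render one trial's fixations as a smoothed, rescaled density map.

    The first fixation is dropped (it is the forced center start); each
    remaining in-image fixation adds 1 at its rounded pixel; the count image
    is smoothed with an isotropic Gaussian of sd ``sigma_px`` and min-max
    rescaled to [0, 1].  Individual off-image fixations are silently dropped.
    """
    fixations = trial.fixations[1:] if params.drop_first_fixation else trial.fixations
    counts = np.zeros((params.image_h, params.image_w))
    n_counted = 0
    for f in fixations:
        xi, yi = _round_half_away(f.x_px), _round_half_away(f.y_px)
        if 0 <= xi < params.image_w and 0 <= yi < params.image_h:
            counts[yi, xi] += 1.0
            n_counted += 1
    if n_counted == 0:
        raise ValueError(
            f"no countable fixations for {trial.participant_id}/{trial.scene_id}")
    smoothed = smooth_counts(counts, params.sigma_px)
    return FixationDensityMap(trial.participant_id, trial.scene_id, mat2gray(smoothed))


def density_map_for_scene(
    trials: list[Trial], params: DensityMapParams
) -> FixationDensityMap:
    """Density map pooling all of one participant's trials on one scene.

    Counts are accumulated across trials before smoothing, so a scene viewed
    once reduces to :func:`density_map`.
    """
    if not trials:
        raise ValueError("no trials supplied")
    scene_ids = {t.scene_id for t in trials}
    if len(scene_ids) > 1:
        raise ValueError(f"trials span multiple scenes: {sorted(scene_ids)}")
    counts = np.zeros((params.image_h, params.image_w))
    n_counted = 0
    for trial in trials:
        fixations = trial.fixations[1:] if params.drop_first_fixation else trial.fixations
        for f in fixations:
            xi, yi = _round_half_away(f.x_px), _round_half_away(f.y_px)
            if 0 <= xi < params.image_w and 0 <= yi < params.image_h:
                counts[yi, xi] += 1.0
                n_counted += 1
    if n_counted == 0:
        raise ValueError(
            f"no countable fixations for {trials[0].participant_id}/{trials[0].scene_id}")
    smoothed = smooth_counts(counts, params.sigma_px)
    return FixationDensityMap(trials[0].participant_id, trials[0].scene_id,
                              mat2gray(smoothed))
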