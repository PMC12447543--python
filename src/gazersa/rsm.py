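"""Representational similarity matrices, (partial) Spearman RSA, noise ceilings.

An RSM is the item×item Pearson-correlation matrix of response vectors
(fixation density maps flattened to vectors, or voxel patterns).
Representational similarity between two data sources is the Spearman rank
correlation of their RSMs' strictly lower triangles; the per-participant
estimate is that correlation computed against each fMRI subject's RSM
(restricted to the scenes the participant saw) and then averaged over fMRI
subjects — RSMs themselves are never averaged across fMRI subjects, since a
mean RSM can misrepresent the shared representational geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .synthetic import VoxelPatternSet

__all__ = [
    "RSM", "ROISpec", "SimilarityEstimate", "NoiseCeiling",
    "build_rsm", "rsm_from_patterns", "concatenate_roi", "restrict_rsm",
    "lower_triangle", "representational_similarity",
    "average_over_fmri_subjects", "partial_representational_similarity",
    "noise_ceiling", "combined_noise_ceiling",
]


@dataclass(frozen=True)
class RSM:
    """Symmetric item×item Pearson-correlation matrix with unit diagonal."""

    item_ids: tuple[str, ...]
    values: np.ndarray
    source: str = "gaze"  # {"gaze", "fmri"}
    owner_id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValueError("RSM shape does not match item_ids")
        if n < 3:
            raise ValueError("an RSM needs at least 3 items")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("RSM is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("RSM diagonal is not 1")
        if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("RSM entries outside [-1, 1]")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass(frozen=True)
class ROISpec:
    """Named ROI assembled by concatenating constituent pattern sets.

    e.g. V1 = V1v + V1d: the ventral and dorsal voxel vectors are appended
    (in the recorded component order) before any RSM is built.
    """

    roi_id: str
    display_name: str
    component_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.component_ids:
            raise ValueError("ROISpec needs at least one component")


@dataclass(frozen=True)
class SimilarityEstimate:
    participant_id: str
    roi_id: str
    rho: float
    n_items: int
    n_fmri_subjects_averaged: int
    partialed_on: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho):
            raise ValueError("rho must be finite")


@dataclass(frozen=True)
class NoiseCeiling:
    """Combined gaze×fMRI noise ceiling for one ROI and age group."""

    roi_id: str
    group: str
    gaze_lower: float
    gaze_upper: float
    fmri_lower: float
    fmri_upper: float

    @property
    def lower(self) -> float:
        return self.gaze_lower * self.fmri_lower

    @property
    def upper(self) -> float:
        return self.gaze_upper * self.fmri_upper


# ---------------------------------------------------------------------------
# RSM construction
# ---------------------------------------------------------------------------

def build_rsm(
    vectors: dict[str, np.ndarray],
    item_ids: list[str] | tuple[str, ...],
    source: str = "gaze",
    owner_id: str = "",
) -> RSM:
    """Pairwise Pearson correlation of per-item response vectors.

    A zero-variance vector is a hard error naming the offending item, never a
    silent NaN.
    """
    item_ids = tuple(item_ids)
    if len(item_ids) < 3:
        raise ValueError("need at least 3 items")
    mat = np.array([np.asarray(vectors[i], dtype=float).ravel() for i in item_ids])
    if mat.shape[1] < 2:
        raise ValueError("vectors must have length >= 2")
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = [item_ids[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"degenerate pattern (zero variance) for items: {bad}")
    r = np.corrcoef(mat)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return RSM(item_ids=item_ids, values=r, source=source, owner_id=owner_id)


def rsm_from_patterns(patterns: VoxelPatternSet) -> RSM:
    """RSM of one fMRI subject×ROI voxel-pattern matrix."""
    vectors = {sid: patterns.patterns[i] for i, sid in enumerate(patterns.scene_ids)}
    return build_rsm(vectors, patterns.scene_ids, source="fmri",
                     owner_id=f"{patterns.fmri_subject_id}/{patterns.roi_id}")


def concatenate_roi(
    pattern_sets: list[VoxelPatternSet], spec: ROISpec
) -> VoxelPatternSet:
    """Append constituent voxel vectors (e.g. ventral+dorsal) in spec order."""
    by_id = {p.roi_id: p for p in pattern_sets}
    missing = [c for c in spec.component_ids if c not in by_id]
    if missing:
        raise ValueError(f"missing components for {spec.roi_id}: {missing}")
    parts = [by_id[c] for c in spec.component_ids]
    ref = parts[0]
    for p in parts[1:]:
        if p.scene_ids != ref.scene_ids:
            raise ValueError(
                f"scene alignment mismatch between {ref.roi_id} and {p.roi_id}")
        if p.fmri_subject_id != ref.fmri_subject_id:
            raise ValueError("components come from different fMRI subjects")
    return VoxelPatternSet(
        fmri_subject_id=ref.fmri_subject_id,
        roi_id=spec.roi_id,
        scene_ids=ref.scene_ids,
        patterns=np.concatenate([p.patterns for p in parts], axis=1),
    )


def restrict_rsm(rsm: RSM, scene_subset: list[str] | tuple[str, ...]) -> RSM:
    """Row/column submatrix over a scene subset, in subset order."""
    subset = tuple(scene_subset)
    unknown = [s for s in subset if s not in rsm.item_ids]
    if unknown:
        raise ValueError(f"unknown items: {unknown}")
    if len(subset) < 3:
        raise ValueError("too few shared scenes (need >= 3)")
    pos = [rsm.item_ids.index(s) for s in subset]
    return replace(rsm, item_ids=subset, values=rsm.values[np.ix_(pos, pos)])


# ---------------------------------------------------------------------------
# representational similarity
# ---------------------------------------------------------------------------

def lower_triangle(rsm: RSM) -> np.ndarray:
    """Strictly-lower-triangle entries (diagonal excluded), row-major order."""
    n = rsm.n_items
    return rsm.values[np.tril_indices(n, k=-1)]


def _check_aligned(*rsms: RSM) -> None:
    ref = rsms[0].item_ids
    for r in rsms[1:]:
        if r.item_ids != ref:
            raise ValueError("RSMs must share item_ids in identical order")


def representational_similarity(gaze_rsm: RSM, fmri_rsm: RSM) -> float:
    """Spearman rho between two RSMs' strictly lower triangles.

    Ties receive average ranks; a constant lower triangle is an error rather
    than a NaN.
    """
    _check_aligned(gaze_rsm, fmri_rsm)
    a, b = lower_triangle(gaze_rsm), lower_triangle(fmri_rsm)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate RSM: constant lower triangle")
    return float(stats.spearmanr(a, b).statistic)


def average_over_fmri_subjects(
    per_subject_rhos: list[float],
    participant_id: str = "",
    roi_id: str = "",
    n_items: int = 0,
    partialed_on: str | None = None,
) -> SimilarityEstimate:
    """Arithmetic mean of per-fMRI-subject rhos (no Fisher-z transform)."""
    if not per_subject_rhos:
        raise ValueError("no per-subject rho values to average")
    return SimilarityEstimate(
        participant_id=participant_id,
        roi_id=roi_id,
        rho=float(np.mean(per_subject_rhos)),
        n_items=n_items,
        n_fmri_subjects_averaged=len(per_subject_rhos),
        partialed_on=partialed_on,
    )


def partial_representational_similarity(
    gaze_rsm: RSM, fmri_rsm: RSM, nuisance_rsm: RSM
) -> float:
    """Partial Spearman rho controlling for a nuisance RSM (e.g. salience).

    All three lower triangles are rank-transformed (average ranks); gaze and
    fMRI ranks are residualized on the nuisance ranks by least squares with
    intercept, and the Pearson correlation of the residuals is returned.
    """
    _check_aligned(gaze_rsm, fmri_rsm, nuisance_rsm)
    g = stats.rankdata(lower_triangle(gaze_rsm))
    f = stats.rankdata(lower_triangle(fmri_rsm))
    z = stats.rankdata(lower_triangle(nuisance_rsm))
    if np.ptp(z) == 0:
        raise ValueError("degenerate nuisance RSM: constant lower triangle")
    if np.ptp(g) == 0 or np.ptp(f) == 0:
        raise ValueError("degenerate RSM: constant lower triangle")
    X = np.column_stack([np.ones_like(z), z])
    rg = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
    rf = f - X @ np.linalg.lstsq(X, f, rcond=None)[0]
    # a triangle fully explained by the nuisance has no residual signal; the
    # relative threshold absorbs least-squares round-off
    if rg.std() <= 1e-10 * g.std() or rf.std() <= 1e-10 * f.std():
        return 0.0
    return float(np.corrcoef(rg, rf)[0, 1])


# ---------------------------------------------------------------------------
# noise ceilings
# ---------------------------------------------------------------------------

def noise_ceiling(rsms_by_subject: list[RSM]) -> tuple[float, float]:
    """Leave-one-out noise-ceiling bounds for one data source.

    Upper bound: mean over subjects of Spearman rho between each subject's RSM
    and the mean RSM including that subject.  Lower bound: same against the
    mean RSM excluding that subject.
    """
    if len(rsms_by_subject) < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    _check_aligned(*rsms_by_subject)
    tris = np.array([lower_triangle(r) for r in rsms_by_subject])
    n = tris.shape[0]
    total = tris.sum(axis=0)
    upper, lower = [], []
    for i in range(n):
        mean_incl = total / n
        mean_excl = (total - tris[i]) / (n - 1)
        upper.append(stats.spearmanr(tris[i], mean_incl).statistic)
        lower.append(stats.spearmanr(tris[i], mean_excl).statistic)
    return float(np.mean(lower)), float(np.mean(upper))


def combined_noise_ceiling(
    gaze: tuple[float, float],
    fmri: tuple[float, float],
    roi_id: str = "",
    group: str = "",
) -> NoiseCeiling:
    """Combined ceiling: the product of the gaze and fMRI bounds."""
    for b in (*gaze, *fmri):
        if not -1 - 1e-12 <= b <= 1 + 1e-12:
            raise ValueError("ceiling bounds must lie in [-1, 1]")
    return NoiseCeiling(roi_id=roi_id, group=group,
                        gaze_lower=gaze[0], gaze_upper=gaze[1],
                        fmri_lower=fmri[0], fmri_upper=fmri[1])
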