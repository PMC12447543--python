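"""Synthetic scene-viewing studies with planted representational structure.

The generator emulates a developmental free-viewing experiment: a set of
natural scenes is characterized at several feature-abstraction levels
(operationalized as spatial smoothness scales), each age group places its
fixations according to a weighted mixture of those levels, and a set of
fMRI "subjects" carries regions of interest whose voxel patterns read out
one or more levels with additive Gaussian noise.  Because the mixture
weights and ROI loadings are known, every downstream stage (density maps,
RSMs, representational similarity, group inference) can be tested for
recovery of the planted geometry without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

from .fixations import FixationRecord, Trial

__all__ = [
    "SceneFeatureSet",
    "AgeGroupProfile",
    "SyntheticROIProfile",
    "SyntheticStudy",
    "VoxelPatternSet",
    "make_scene_features",
    "simulate_fixations",
    "simulate_voxel_patterns",
    "generate_study",
    "demo_study_config",
]

#: Side length of the coarse grid used for level embeddings (D = EMBED_GRID**2).
EMBED_GRID = 12

DURATION_LOG_SD = 0.4  # log-scale sd of the log-normal fixation-duration model


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneFeatureSet:
    """Multi-level feature description of one scene.

    ``level_maps`` holds one non-negative H×W probability map per abstraction
    level (each sums to 1); ``level_embeddings`` holds one length-D vector per
    level, a deterministic coarse down-sampling of the corresponding map used
    for voxel readout.
    """

    scene_id: str
    level_maps: tuple[np.ndarray, ...]
    level_embeddings: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        for m in self.level_maps:
            if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"level map of {self.scene_id} is not a distribution")

    @property
    def shape(self) -> tuple[int, int]:
        return self.level_maps[0].shape

    @property
    def n_levels(self) -> int:
        return len(self.level_maps)


@dataclass(frozen=True)
class AgeGroupProfile:
    """How one age group distributes gaze over the abstraction levels."""

    name: str
    mixture_weights: tuple[float, ...]
    n_participants: int
    trials_per_participant: int
    fixations_per_trial_mean: float
    total_look_ms_mean: float

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights of {self.name!r} must be >=0 and sum to 1")
        if self.fixations_per_trial_mean <= 0 or self.total_look_ms_mean <= 0:
            raise ValueError("looking-behavior means must be positive")

    @property
    def fixation_duration_mean_ms(self) -> float:
        return self.total_look_ms_mean / self.fixations_per_trial_mean


@dataclass(frozen=True)
class SyntheticROIProfile:
    """Voxel population reading out a weighted set of abstraction levels."""

    roi_id: str
    level_loadings: tuple[float, ...]
    n_voxels: int = 200
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("an ROI needs at least 2 voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticStudy:
    """Complete configuration of one synthetic study; doubles as ground truth."""

    scenes: tuple[SceneFeatureSet, ...]
    profiles: tuple[AgeGroupProfile, ...]
    rois: tuple[SyntheticROIProfile, ...]
    n_fmri_subjects: int = 8
    seed: int = 0
    feature_scales: tuple[float, ...] | None = None  # smoothness per level, px

    def __post_init__(self) -> None:
        if len(self.scenes) < 2:
            raise ValueError("need at least 2 scenes")
        if not self.profiles:
            raise ValueError("need at least one age-group profile")
        if any(p.n_participants < 1 for p in self.profiles):
            raise ValueError("each age group needs at least one participant")
        if self.n_fmri_subjects < 1:
            raise ValueError("need at least one fMRI subject")

    def ground_truth(self) -> dict:
        """JSON-serializable echo of the planted configuration."""
        return {
            "seed": self.seed,
            "n_fmri_subjects": self.n_fmri_subjects,
            "feature_scales": list(self.feature_scales) if self.feature_scales else None,
            "suggested_density_sigma_px": (
                self.feature_scales[0] / 2.0 if self.feature_scales else None),
            "scene_ids": [s.scene_id for s in self.scenes],
            "map_shape": list(self.scenes[0].shape),
            "n_levels": self.scenes[0].n_levels,
            "profiles": [asdict(p) for p in self.profiles],
            "rois": [asdict(r) for r in self.rois],
        }


@dataclass(frozen=True)
class VoxelPatternSet:
    """Scenes×voxels activation matrix for one fMRI subject and one ROI."""

    fmri_subject_id: str
    roi_id: str
    scene_ids: tuple[str, ...]
    patterns: np.ndarray  # (n_scenes, n_voxels)

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.scene_ids):
            raise ValueError("pattern rows must align with scene_ids")
        if self.patterns.shape[1] < 2:
            raise ValueError("an ROI needs at least 2 voxels")


# ---------------------------------------------------------------------------
# scene features
# ---------------------------------------------------------------------------

def _embed(map_: np.ndarray, grid: int = EMBED_GRID) -> np.ndarray:
    """Coarse block-average of a map on a grid×grid lattice, flattened."""
    h, w = map_.shape
    rows = (np.arange(grid) * h) // grid
    cols = (np.arange(grid) * w) // grid
    pooled = np.add.reduceat(np.add.reduceat(map_, rows, axis=0), cols, axis=1)
    counts = np.outer(np.diff(np.append(rows, h)), np.diff(np.append(cols, w)))
    return (pooled / counts).ravel()


def make_scene_features(
    n_scenes: int,
    H: int,
    W: int,
    L: int,
    smoothness_per_level: list[float] | tuple[float, ...],
    seed: int,
) -> list[SceneFeatureSet]:
    """Generate scenes whose feature maps dissociate across abstraction levels.

    Each level map is an independently seeded Gaussian-smoothed exponentiated
    white-noise field: smoothness (the Gaussian length scale, in pixels) is
    the operational definition of abstraction level, so scales must be
    strictly increasing with level.
    """
    scales = [float(s) for s in smoothness_per_level]
    if len(scales) != L:
        raise ValueError("need one smoothness scale per level")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("levels must increase in abstraction scale")
    if n_scenes < 2:
        raise ValueError("need at least 2 scenes")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    scenes = []
    for i in range(n_scenes):
        maps, embs = [], []
        for scale in scales:
            z = gaussian_filter(rng.standard_normal((H, W)), scale, mode="reflect")
            z = (z - z.mean()) / max(z.std(), 1e-12)  # equalize contrast across scales
            m = np.exp(z)
            m /= m.sum()
            maps.append(m)
            embs.append(_embed(m))
        scenes.append(
            SceneFeatureSet(
                scene_id=f"scene{i:03d}",
                level_maps=tuple(maps),
                level_embeddings=tuple(embs),
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# fixation simulation
# ---------------------------------------------------------------------------

def _lognormal_durations(rng: np.random.Generator, n: int, mean_ms: float) -> np.ndarray:
    mu = np.log(mean_ms) - DURATION_LOG_SD**2 / 2.0
    return rng.lognormal(mu, DURATION_LOG_SD, size=n)


def simulate_fixations(
    scene: SceneFeatureSet,
    profile: AgeGroupProfile,
    n_fix: int,
    seed: int,
    participant_id: str = "sim",
    trial_index: int = 0,
) -> Trial:
    """Sample one trial of fixations on a scene for one age-group profile.

    Locations are i.i.d. draws from the pixel distribution proportional to the
    mixture sum of the scene's level maps under the profile's weights.  A
    synthetic center-start fixation is prepended (the one the preprocessing
    stage later drops); durations are log-normal around the profile's mean.
    """
    if n_fix < 0:
        raise ValueError("n_fix must be non-negative")
    w = np.asarray(profile.mixture_weights, dtype=float)
    if len(w) != scene.n_levels:
        raise ValueError("profile weight length must match scene levels")
    mix = sum(wl * m for wl, m in zip(w, scene.level_maps))
    total = float(mix.sum())
    if total <= 0:
        raise ValueError("mixture collapses to an all-zero map")

    h, wd = scene.shape
    scene_tag = int(hashlib.md5(scene.scene_id.encode()).hexdigest()[:8], 16)
    rng = np.random.default_rng(np.random.SeedSequence([seed, scene_tag]))
    flat_idx = rng.choice(h * wd, size=n_fix, p=(mix / total).ravel())
    ys, xs = np.divmod(flat_idx, wd)
    durations = _lognormal_durations(rng, n_fix + 1, profile.fixation_duration_mean_ms)

    fixations = [
        FixationRecord(index_in_trial=0, x_px=(wd - 1) / 2.0, y_px=(h - 1) / 2.0,
                       duration_ms=float(durations[0]))
    ]
    for k in range(n_fix):
        fixations.append(
            FixationRecord(index_in_trial=k + 1, x_px=float(xs[k]), y_px=float(ys[k]),
                           duration_ms=float(durations[k + 1]))
        )
    return Trial(
        participant_id=participant_id,
        scene_id=scene.scene_id,
        trial_index=trial_index,
        fixations=tuple(fixations),
        started_at_center=True,
    )


# ---------------------------------------------------------------------------
# voxel-pattern simulation
# ---------------------------------------------------------------------------

def _readout_basis(rng: np.random.Generator, n_voxels: int, dim: int) -> np.ndarray:
    """Random n_voxels×dim basis with orthonormal columns, each orthogonal to
    the constant vector.

    This construction makes the noise-free pattern RSM equal the embedding RSM
    exactly: inner products of embeddings are preserved and every pattern is
    already voxel-mean-centered.
    """
    if n_voxels < dim + 1:
        raise ValueError("need n_voxels >= embedding dim + 1")
    g = rng.standard_normal((n_voxels, dim))
    g -= g.mean(axis=0, keepdims=True)  # project out the constant direction
    q, r = np.linalg.qr(g)
    return q * np.sign(np.diag(r))  # fix QR sign ambiguity for determinism


def simulate_voxel_patterns(
    scenes: list[SceneFeatureSet] | tuple[SceneFeatureSet, ...],
    roi: SyntheticROIProfile,
    fmri_subject_seed: int,
) -> VoxelPatternSet:
    """Simulate one fMRI subject's scenes×voxels pattern matrix for one ROI.

    Each level's scene embeddings are standardized, mapped through a
    per-subject random orthogonal readout scaled by the ROI's level loadings,
    and corrupted with i.i.d. Gaussian noise of sd ``roi.noise_sd``.  Readout
    bases differ across subject seeds, so subjects share representational
    geometry but not voxel responses.
    """
    if len(scenes) < 2:
        raise ValueError("need at least 2 scenes")
    n_levels = scenes[0].n_levels
    if len(roi.level_loadings) != n_levels:
        raise ValueError("ROI loading length must match scene levels")
    dim = len(scenes[0].level_embeddings[0])
    rng = np.random.default_rng(
        np.random.SeedSequence([int(fmri_subject_seed),
                                int(hashlib.md5(roi.roi_id.encode()).hexdigest()[:8], 16)])
    )

    signal = np.zeros((len(scenes), roi.n_voxels))
    for lvl, loading in enumerate(roi.level_loadings):
        basis = _readout_basis(rng, roi.n_voxels, dim)
        emb = np.array([s.level_embeddings[lvl] for s in scenes])
        emb = emb - emb.mean(axis=1, keepdims=True)  # center within each scene
        norm = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = np.divide(emb, norm, out=np.zeros_like(emb), where=norm > 0)
        signal += loading * emb @ basis.T

    noise = roi.noise_sd * rng.standard_normal(signal.shape) / np.sqrt(roi.n_voxels)
    return VoxelPatternSet(
        fmri_subject_id=f"fmri{fmri_subject_seed:02d}",
        roi_id=roi.roi_id,
        scene_ids=tuple(s.scene_id for s in scenes),
        patterns=signal + noise,
    )


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def demo_study_config(
    n_scenes: int = 30,
    H: int = 64,
    W: int = 64,
    n_participants: int = 20,
    n_voxels: int = 200,
    seed: int = 0,
) -> SyntheticStudy:
    """The default demonstration study.

    Three abstraction levels; young infants driven purely by the lowest level,
    older infants by an even low/mid split, adults mostly low/mid with a small
    high-level component; three ROIs each loading one level.  Trials-per-
    participant equals the scene count (each scene viewed once) and looking
    parameters sit near observed infant/adult values (~9-16 fixations per
    5 s trial, ~3.0-4.3 s of the 5 s spent fixating; per-fixation durations
    follow as total look / fixation count).  Feature scales of
    8/10/13 px on a 64-px scene: level geometries dissociate because the
    fields are independent, while the near-equal scales give the levels
    comparable measurement reliability under sparse fixation sampling — a
    mixture with equal weights then yields approximately equal measured
    similarity, as an equal-weight gaze policy should.
    """
    scales = (8.0, 10.0, 13.0)
    scenes = make_scene_features(n_scenes, H, W, L=3,
                                 smoothness_per_level=scales, seed=seed)
    profiles = (
        AgeGroupProfile("young", (1.0, 0.0, 0.0), n_participants, n_scenes, 9.1, 3040.0),
        AgeGroupProfile("old", (0.5, 0.5, 0.0), n_participants, n_scenes, 9.5, 3560.0),
        AgeGroupProfile("adult", (0.45, 0.45, 0.1), n_participants, n_scenes, 16.0, 4270.0),
    )
    rois = (
        SyntheticROIProfile("roi_low", (1.0, 0.0, 0.0), n_voxels=n_voxels),
        SyntheticROIProfile("roi_mid", (0.0, 1.0, 0.0), n_voxels=n_voxels),
        SyntheticROIProfile("roi_high", (0.0, 0.0, 1.0), n_voxels=n_voxels),
    )
    return SyntheticStudy(scenes=tuple(scenes), profiles=profiles, rois=rois,
                          n_fmri_subjects=8, seed=seed, feature_scales=scales)


def simulate_sessions(config: SyntheticStudy) -> list["SubjectSession"]:
    """Simulate all participants' fixation sessions for a study config."""
    from .fixations import SubjectSession

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sessions = []
    pid = 0
    for profile in config.profiles:
        for _ in range(profile.n_participants):
            participant_id = f"{profile.name}{pid:03d}"
            pid += 1
            n_trials = min(profile.trials_per_participant, len(config.scenes))
            scene_idx = rng.choice(len(config.scenes), size=n_trials, replace=False)
            trials = []
            for t, si in enumerate(sorted(scene_idx)):
                n_fix = int(rng.poisson(profile.fixations_per_trial_mean))
                trial_seed = int(rng.integers(2**31))
                trial = simulate_fixations(
                    config.scenes[si], profile, n_fix, seed=trial_seed,
                    participant_id=participant_id, trial_index=t,
                )
                trials.append(trial)
            sessions.append(SubjectSession(participant_id=participant_id,
                                           age_group=profile.name, trials=tuple(trials)))
    return sessions


def simulate_all_voxel_patterns(config: SyntheticStudy) -> list[VoxelPatternSet]:
    """Voxel patterns for every fMRI subject × ROI in a study config."""
    out = []
    for s in range(config.n_fmri_subjects):
        subject_seed = config.seed * 1000 + s
        for roi in config.rois:
            out.append(simulate_voxel_patterns(config.scenes, roi, subject_seed))
    return out


def generate_study(config: SyntheticStudy, outdir: str | Path) -> Path:
    """Write a complete study bundle to ``outdir``.

    Layout: ``fixations.tsv`` (tab-separated fixation event report),
    ``voxels.h5`` (HDF5 groups /<fmri_subject>/<roi_id> with a ``scene_ids``
    attribute), ``salience/<scene_id>.txt`` (the level-1 map, reused as the
    salience nuisance), and ``ground_truth.json`` (planted configuration and
    content hashes).  Every file round-trips through the package readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sessions = simulate_sessions(config)
    rows = ["participant_id\tage_group\ttrial_index\tscene_id\tindex_in_trial"
            "\tx_px\ty_px\tduration_ms\tstarted_at_center"]
    for sess in sessions:
        for trial in sess.trials:
            for f in trial.fixations:
                rows.append(
                    f"{sess.participant_id}\t{sess.age_group}\t{trial.trial_index}"
                    f"\t{trial.scene_id}\t{f.index_in_trial}\t{f.x_px:.3f}\t{f.y_px:.3f}"
                    f"\t{f.duration_ms:.3f}\t{str(trial.started_at_center).lower()}"
                )
    (outdir / "fixations.tsv").write_text("\n".join(rows) + "\n")

    with h5py.File(outdir / "voxels.h5", "w") as h5:
        for vps in simulate_all_voxel_patterns(config):
            ds = h5.require_group(vps.fmri_subject_id).create_dataset(
                vps.roi_id, data=vps.patterns)
            ds.attrs["scene_ids"] = list(vps.scene_ids)

    saldir = outdir / "salience"
    saldir.mkdir(exist_ok=True)
    for scene in config.scenes:
        np.savetxt(saldir / f"{scene.scene_id}.txt", scene.level_maps[0], fmt="%.8e")

    manifest = config.ground_truth()
    manifest["file_sha256"] = {
        "fixations.tsv": hashlib.sha256((outdir / "fixations.tsv").read_bytes()).hexdigest(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
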