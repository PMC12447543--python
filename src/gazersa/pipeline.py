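"""End-to-end orchestration: bundle I/O, staged analysis, results, figures.

A *study bundle* is a directory holding ``fixations.tsv`` (tab-separated
fixation events), ``voxels.h5`` (HDF5 groups ``/<fmri_subject>/<roi_id>``
with a ``scene_ids`` attribute), an optional ``salience/`` directory of
per-scene text matrices, and a manifest.  The pipeline runs preprocessing
(exclusions, density maps), RSM construction, per-participant
representational similarity (optionally salience-partialed), noise ceilings,
and the group statistics, writing tidy CSVs plus a plain-text report and
figures, with a manifest recording the seed, configuration hash and input
hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .fixations import (
    DensityMapParams, SubjectSession, ExclusionReport,
    read_fixation_report, apply_trial_exclusions, apply_subject_exclusion,
    compute_looking_stats, density_map_for_scene,
)
from .rsm import (
    RSM, ROISpec, build_rsm, rsm_from_patterns, concatenate_roi, restrict_rsm,
    representational_similarity, partial_representational_similarity,
    average_over_fmri_subjects, noise_ceiling, combined_noise_ceiling,
)
from .synthetic import VoxelPatternSet, SyntheticStudy, generate_study

logger = logging.getLogger("gazersa")

__all__ = [
    "RunConfig", "demo_run_config", "load_voxel_patterns", "load_salience_maps",
    "preprocess", "similarity_table", "noise_ceilings", "run_statistics",
    "run_bundle", "analyze_study", "write_report",
]


@dataclass
class RunConfig:
    """Analysis configuration; every default actually used is logged."""

    density: DensityMapParams = field(default_factory=DensityMapParams)
    roi_specs: list[ROISpec] | None = None      # None: use ROIs as stored
    min_usable_trials: int = 18
    partial_on_salience: bool = False
    compute_noise_ceiling: bool = True
    infant_groups: tuple[str, str] = ("young", "old")
    adult_group: str = "adult"
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.roi_specs is not None:
            d["roi_specs"] = [asdict(s) for s in self.roi_specs]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def demo_run_config(study: SyntheticStudy, **overrides) -> RunConfig:
    """Analysis configuration matched to a synthetic study's geometry.

    The map extent follows the study's scenes and the smoothing sigma is half
    the finest feature scale (the analogue, at reduced scene resolution, of
    smoothing at the scale of eye-tracker error).
    """
    h, w = study.scenes[0].shape
    sigma = study.feature_scales[0] / 2.0 if study.feature_scales else 7.21
    density = DensityMapParams(image_h=h, image_w=w, sigma_px=sigma)
    return RunConfig(density=density, seed=study.seed, **overrides)


# ---------------------------------------------------------------------------
# bundle readers
# ---------------------------------------------------------------------------

def load_voxel_patterns(path: str | Path) -> list[VoxelPatternSet]:
    """Read all fMRI subject × ROI pattern matrices from a voxels HDF5 file."""
    out = []
    with h5py.File(path, "r") as h5:
        for subj in sorted(h5.keys()):
            for roi in sorted(h5[subj].keys()):
                ds = h5[subj][roi]
                scene_ids = tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in ds.attrs["scene_ids"]
                )
                out.append(VoxelPatternSet(
                    fmri_subject_id=subj, roi_id=roi,
                    scene_ids=scene_ids, patterns=ds[()],
                ))
    if not out:
        raise ValueError(f"no voxel patterns found in {path}")
    return out


def load_salience_maps(directory: str | Path) -> dict[str, np.ndarray]:
    """Read per-scene salience matrices (``<scene_id>.txt``) from a directory."""
    directory = Path(directory)
    maps = {p.stem: np.loadtxt(p) for p in sorted(directory.glob("*.txt"))}
    if not maps:
        raise ValueError(f"no salience maps found in {directory}")
    return maps


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def preprocess(
    sessions: list[SubjectSession], config: RunConfig
) -> tuple[list[SubjectSession], ExclusionReport, dict[str, dict[str, np.ndarray]]]:
    """Exclusions plus per-participant per-scene density maps.

    Returns the kept sessions, the merged exclusion report, and a nested map
    participant_id -> scene_id -> density-map array (trials on the same scene
    are pooled before smoothing).
    """
    report = ExclusionReport()
    kept_sessions = []
    for s in sessions:
        s2, r = apply_trial_exclusions(s, config.density)
        report = report.merge(r)
        kept_sessions.append(s2)
    kept_sessions, subj_report = apply_subject_exclusion(
        kept_sessions, config.min_usable_trials)
    report = report.merge(subj_report)

    maps: dict[str, dict[str, np.ndarray]] = {}
    for s in kept_sessions:
        by_scene: dict[str, list] = {}
        for t in s.trials:
            by_scene.setdefault(t.scene_id, []).append(t)
        maps[s.participant_id] = {}
        for scene_id, trials in by_scene.items():
            try:
                dm = density_map_for_scene(trials, config.density)
            except ValueError:
                logger.warning("skipping %s/%s: no countable fixations",
                               s.participant_id, scene_id)
                continue
            maps[s.participant_id][scene_id] = dm.values
    return kept_sessions, report, maps


def _fmri_rsms(
    patterns: list[VoxelPatternSet], config: RunConfig
) -> dict[str, dict[str, RSM]]:
    """Full-scene-set RSM per ROI per fMRI subject, after any concatenation."""
    by_subject: dict[str, list[VoxelPatternSet]] = {}
    for p in patterns:
        by_subject.setdefault(p.fmri_subject_id, []).append(p)
    rsms: dict[str, dict[str, RSM]] = {}
    for subj, plist in sorted(by_subject.items()):
        if config.roi_specs is None:
            rois = plist
        else:
            rois = []
            for spec in config.roi_specs:
                try:
                    rois.append(concatenate_roi(plist, spec))
                except ValueError as e:
                    raise ValueError(f"ROI {spec.roi_id!r}: {e}") from e
        rsms[subj] = {p.roi_id: rsm_from_patterns(p) for p in rois}
    return rsms


def similarity_table(
    sessions: list[SubjectSession],
    density_maps: dict[str, dict[str, np.ndarray]],
    patterns: list[VoxelPatternSet],
    config: RunConfig,
    salience_maps: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict[str, RSM]]:
    """Per-participant×ROI Spearman similarity, averaged over fMRI subjects.

    Each participant's gaze RSM is built from their own scene set; every fMRI
    RSM is restricted to exactly those scenes before the rank correlation, and
    the per-subject rhos are averaged arithmetically.  With
    ``config.partial_on_salience`` a salience RSM over the same scenes is
    partialed out of both sides (partial Spearman).
    """
    fmri = _fmri_rsms(patterns, config)
    sal_rsm_full = None
    first_subject_rsms = next(iter(fmri.values()))
    all_scenes = next(iter(first_subject_rsms.values())).item_ids
    if config.partial_on_salience:
        if salience_maps is None:
            raise ValueError("partial_on_salience requires salience maps")
        sal_rsm_full = build_rsm(
            {s: salience_maps[s] for s in all_scenes}, all_scenes,
            source="gaze", owner_id="salience")

    group_of = {s.participant_id: s.age_group for s in sessions}
    gaze_rsms: dict[str, RSM] = {}
    rows = []
    for pid, scene_maps in density_maps.items():
        scenes = tuple(s for s in all_scenes if s in scene_maps)
        if len(scenes) < 3:
            logger.warning("skipping %s: fewer than 3 usable scenes", pid)
            continue
        gaze = build_rsm({s: scene_maps[s] for s in scenes}, scenes,
                         source="gaze", owner_id=pid)
        gaze_rsms[pid] = gaze
        for roi_id in sorted(next(iter(fmri.values())).keys()):
            rhos, rhos_partial = [], []
            for subj in sorted(fmri):
                fr = restrict_rsm(fmri[subj][roi_id], scenes)
                rhos.append(representational_similarity(gaze, fr))
                if sal_rsm_full is not None:
                    sal = restrict_rsm(sal_rsm_full, scenes)
                    rhos_partial.append(
                        partial_representational_similarity(gaze, fr, sal))
            est = average_over_fmri_subjects(
                rhos, participant_id=pid, roi_id=roi_id, n_items=len(scenes))
            row = {"participant_id": pid, "age_group": group_of[pid],
                   "roi_id": roi_id, "rho": est.rho, "n_items": est.n_items,
                   "n_fmri_subjects": est.n_fmri_subjects_averaged}
            row["rho_partial"] = float(np.mean(rhos_partial)) if rhos_partial else np.nan
            rows.append(row)
    return pd.DataFrame(rows), gaze_rsms


def noise_ceilings(
    gaze_rsms: dict[str, RSM],
    sessions: list[SubjectSession],
    patterns: list[VoxelPatternSet],
    config: RunConfig,
) -> pd.DataFrame:
    """Combined gaze×fMRI noise ceilings per age group × ROI.

    The gaze ceiling is computed per age group over the scenes common to all
    of that group's participants; the fMRI ceiling per ROI over the fMRI
    subjects; the combined bounds are their products.
    """
    fmri = _fmri_rsms(patterns, config)
    roi_ids = sorted(next(iter(fmri.values())).keys())
    fmri_bounds = {}
    for roi_id in roi_ids:
        fmri_bounds[roi_id] = noise_ceiling(
            [fmri[s][roi_id] for s in sorted(fmri)])

    rows = []
    groups = sorted({s.age_group for s in sessions})
    for g in groups:
        pids = [s.participant_id for s in sessions
                if s.age_group == g and s.participant_id in gaze_rsms]
        if len(pids) < 2:
            logger.warning("noise ceiling skipped for group %s: <2 participants", g)
            continue
        common = set(gaze_rsms[pids[0]].item_ids)
        for p in pids[1:]:
            common &= set(gaze_rsms[p].item_ids)
        order = [s for s in gaze_rsms[pids[0]].item_ids if s in common]
        if len(order) < 3:
            logger.warning("noise ceiling skipped for group %s: <3 shared scenes", g)
            continue
        gaze_bounds = noise_ceiling([restrict_rsm(gaze_rsms[p], order) for p in pids])
        for roi_id in roi_ids:
            nc = combined_noise_ceiling(gaze_bounds, fmri_bounds[roi_id],
                                        roi_id=roi_id, group=g)
            rows.append({"age_group": g, "roi_id": roi_id,
                         "gaze_lower": nc.gaze_lower, "gaze_upper": nc.gaze_upper,
                         "fmri_lower": nc.fmri_lower, "fmri_upper": nc.fmri_upper,
                         "lower": nc.lower, "upper": nc.upper})
    return pd.DataFrame(rows)


def run_statistics(table: pd.DataFrame, config: RunConfig) -> dict:
    """Infant mixed model (age×ROI) plus a separate adult (ROI-only) model.

    Adults are never entered into the infant model; their ROI effect is
    tested in a one-group repeated-measures fit.
    """
    from .inference import (fit_mixed_model, estimated_marginal_means,
                            posthoc_roi_contrasts, between_age_contrasts)

    results: dict = {}
    # fix the factor order (young first) so the between-age contrast is
    # old - young regardless of participant-id sort order
    infant = pd.concat([table[table["age_group"] == g]
                        for g in config.infant_groups], ignore_index=True)
    if not infant.empty and infant["age_group"].nunique() == 2:
        model = fit_mixed_model(infant)
        results["infant_model"] = model
        results["infant_anova"] = model.anova
        results["infant_emmeans"] = estimated_marginal_means(model, config.alpha)
        results["infant_posthoc"] = posthoc_roi_contrasts(model, config.alpha)
        results["infant_age_contrasts"] = between_age_contrasts(model)
    adult = table[table["age_group"] == config.adult_group]
    if not adult.empty:
        model = fit_mixed_model(adult)
        results["adult_model"] = model
        results["adult_anova"] = model.anova
        results["adult_emmeans"] = estimated_marginal_means(model, config.alpha)
        results["adult_posthoc"] = posthoc_roi_contrasts(model, config.alpha)
    if not results:
        raise ValueError("similarity table contains no analyzable age groups")
    return results


# ---------------------------------------------------------------------------
# end-to-end drivers
# ---------------------------------------------------------------------------

def analyze_study(
    sessions: list[SubjectSession],
    patterns: list[VoxelPatternSet],
    config: RunConfig,
    salience_maps: dict[str, np.ndarray] | None = None,
) -> dict:
    """Run all analysis stages in memory and return a results dictionary."""
    kept, report, dmaps = preprocess(sessions, config)
    table, gaze_rsms = similarity_table(kept, dmaps, patterns, config, salience_maps)
    if table.empty:
        raise ValueError("no similarity estimates could be computed")
    results = {"exclusions": report, "sessions_kept": kept,
               "looking_stats": compute_looking_stats(kept),
               "similarity": table, "gaze_rsms": gaze_rsms}
    if config.compute_noise_ceiling:
        results["noise_ceilings"] = noise_ceilings(gaze_rsms, kept, patterns, config)
    results.update(run_statistics(table, config))
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_bundle(
    bundle_dir: str | Path,
    outdir: str | Path,
    config: RunConfig,
    resume: bool = False,
) -> dict:
    """Analyze an on-disk study bundle and write the results bundle.

    With ``resume=True`` an existing ``similarity.csv`` in ``outdir`` is
    reloaded instead of recomputing the gaze/RSM stages (noise ceilings are
    then skipped).  Outputs: exclusion summary, looking stats, similarity
    table, noise ceilings, ANOVA/EMM/post hoc CSVs, a plain-text report and a
    manifest with config/input hashes.
    """
    bundle_dir, outdir = Path(bundle_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fix_path = bundle_dir / "fixations.tsv"
    vox_path = bundle_dir / "voxels.h5"
    for p in (fix_path, vox_path):
        if not p.exists():
            raise FileNotFoundError(f"bundle is missing {p.name}")

    sim_path = outdir / "similarity.csv"
    resumed = resume and sim_path.exists()
    if resumed:
        logger.info("resuming from %s", sim_path)
        table = pd.read_csv(sim_path)
        results = {"similarity": table}
        results.update(run_statistics(table, config))
    else:
        sessions = read_fixation_report(fix_path)
        patterns = load_voxel_patterns(vox_path)
        salience = None
        if config.partial_on_salience:
            salience = load_salience_maps(bundle_dir / "salience")
        results = analyze_study(sessions, patterns, config, salience)

    _write_results(results, outdir, config, rewrite_similarity=not resumed)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "input_sha256": {p.name: _sha256(p) for p in (fix_path, vox_path)},
    }
    if "exclusions" in results:
        rep = results["exclusions"]
        manifest["trials"] = {
            "total": rep.n_trials_total, "kept": rep.n_trials_kept,
            "by_rule": rep.rule_counts, "pct_by_rule": rep.rule_percentages,
            "excluded_subjects": rep.excluded_subjects,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _write_results(results: dict, outdir: Path, config: RunConfig,
                   rewrite_similarity: bool = True) -> None:
    if rewrite_similarity:
        results["similarity"].to_csv(outdir / "similarity.csv", index=False)
    if "looking_stats" in results and not results["looking_stats"].table.empty:
        results["looking_stats"].table.to_csv(outdir / "looking_stats.csv")
    if "noise_ceilings" in results and not results["noise_ceilings"].empty:
        results["noise_ceilings"].to_csv(outdir / "noise_ceilings.csv", index=False)
    anova_frames = []
    for key in ("infant_anova", "adult_anova"):
        if key in results:
            f = results[key].reset_index()
            f.insert(0, "model", key.split("_")[0])
            anova_frames.append(f)
    if anova_frames:
        pd.concat(anova_frames).to_csv(outdir / "anova_table.csv", index=False)
    emm_frames = [results[k].assign(model=k.split("_")[0])
                  for k in ("infant_emmeans", "adult_emmeans") if k in results]
    if emm_frames:
        pd.concat(emm_frames).to_csv(outdir / "emmeans.csv", index=False)
    ph_frames = [results[k].assign(model=k.split("_")[0])
                 for k in ("infant_posthoc", "adult_posthoc") if k in results]
    if ph_frames:
        pd.concat(ph_frames).to_csv(outdir / "posthoc.csv", index=False)
    if "infant_age_contrasts" in results:
        results["infant_age_contrasts"].to_csv(outdir / "age_contrasts.csv", index=False)
    (outdir / "report.txt").write_text(format_report(results))


def format_report(results: dict) -> str:
    """Plain-text summary mirroring conventional F/t reporting style."""
    lines = ["Representational similarity analysis report", "=" * 44, ""]
    for label, key in (("Infants (age x ROI)", "infant_anova"),
                       ("Adults (ROI only)", "adult_anova")):
        if key not in results:
            continue
        lines.append(label)
        for eff, row in results[key].iterrows():
            lines.append(
                f"  {eff}: F({row.df_num:.0f}, {row.df_den:.0f}) = {row.F:.2f}, "
                f"p = {row.p:.4g}")
        lines.append("")
    for label, key in (("Infant post hoc contrasts", "infant_posthoc"),
                       ("Adult post hoc contrasts", "adult_posthoc")):
        if key not in results:
            continue
        lines.append(label)
        for _, r in results[key].iterrows():
            star = " *" if r.significant else ""
            lines.append(
                f"  [{r.age_group}] {r.contrast}: t({r.df:.0f}) = {r.t:.2f}, "
                f"p_holm = {r.p_holm:.4g}{star}")
        lines.append("")
    if "infant_age_contrasts" in results:
        ac = results["infant_age_contrasts"]
        lines.append(f"Between-age contrasts ({ac['contrast'].iloc[0]})")
        for _, r in ac.iterrows():
            lines.append(f"  {r.roi_id}: t({r.df:.0f}) = {r.t:.2f}, p = {r.p:.4g}")
        lines.append("")
    return "\n".join(lines)


def write_report_figures(results: dict, outdir: str | Path) -> list[Path]:
    """Bar-with-CI figure of EMMs per model, with noise-ceiling whiskers.

    The rendered values are taken from the same frames written to CSV, so
    figures and tables cannot disagree.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ceilings = results.get("noise_ceilings")
    paths = []
    for key in ("infant_emmeans", "adult_emmeans"):
        if key not in results:
            continue
        emm = results[key]
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = list(pd.unique(emm["age_group"]))
        rois = list(pd.unique(emm["roi_id"]))
        width = 0.8 / len(groups)
        for gi, g in enumerate(groups):
            sub = emm[emm["age_group"] == g].set_index("roi_id").loc[rois]
            x = np.arange(len(rois)) + gi * width
            ax.bar(x, sub["emmean"], width=width, label=g,
                   yerr=[sub["emmean"] - sub["ci_low"], sub["ci_high"] - sub["emmean"]],
                   capsize=3)
            if ceilings is not None and not ceilings.empty:
                for xi, roi in zip(x, rois):
                    c = ceilings[(ceilings.age_group == g) & (ceilings.roi_id == roi)]
                    if not c.empty:
                        ax.plot([xi, xi], [c["lower"].iloc[0], c["upper"].iloc[0]],
                                color="gray", lw=1.5)
                        ax.scatter([xi, xi],
                                   [c["lower"].iloc[0], c["upper"].iloc[0]],
                                   marker="_", color="gray")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks(np.arange(len(rois)) + 0.4 - width / 2)
        ax.set_xticklabels(rois)
        ax.set_ylabel("Spearman rho")
        ax.legend()
        fig.tight_layout()
        path = outdir / f"{key}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


write_report = write_report_figures
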