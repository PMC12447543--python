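"""Group-level inference on representational-similarity estimates.

The central model is ``rho ~ age * ROI + (1 | participant)``: a Gaussian
linear mixed model with a random participant intercept, one between-subject
factor (age group) and one within-subject factor (ROI), every participant
contributing one rho per ROI.  Because the within-subject design is complete,
the model admits the exact classical split-plot decomposition with two error
strata — subjects-within-groups for the age effect, the subject×ROI residual
for the ROI and interaction effects — which this module computes in closed
form (Type-III sums of squares, sum-to-zero contrasts).  On balanced data
this coincides with the REML random-intercept fit.

Post hoc t tests compare estimated marginal means; ROI contrasts within each
age group form a Holm-corrected family; between-age contrasts use a
Satterthwaite combination of the two error strata.  Monte-Carlo harnesses
estimate the family-wise error rate under the global null and the power of
the age×ROI interaction test at a given Cohen's f.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MixedModelResult", "PowerSimConfig",
    "fit_mixed_model", "estimated_marginal_means", "holm_adjust",
    "posthoc_roi_contrasts", "between_age_contrasts",
    "simulate_fwer", "simulate_power",
]


# ---------------------------------------------------------------------------
# model result container
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Fitted split-plot mixed model.

    ``anova`` holds one row per fixed effect (age, roi, age:roi — age rows
    absent for single-group fits) with F, numerator/denominator df and p.
    ``ms_subject``/``mse_within`` are the two error-stratum mean squares on
    the response scale, from which the variance components derive.
    """

    anova: pd.DataFrame
    age_groups: tuple[str, ...]
    roi_ids: tuple[str, ...]
    cell_means: pd.DataFrame          # age_group rows × roi_id columns
    group_ns: dict[str, int]
    ms_subject: float
    df_subject: int
    mse_within: float
    df_within: int
    sigma2_subject: float
    sigma2_resid: float


@dataclass(frozen=True)
class PowerSimConfig:
    """Configuration of the a-priori power / FWER simulation."""

    effect_size_f: float = 0.1
    n_per_group: int = 40
    n_groups: int = 2
    n_roi_levels: int = 3
    within_subject_correlation: float = 0.5
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ValueError("effect_size_f must be >= 0")
        if not 0 <= self.within_subject_correlation < 1:
            raise ValueError("within_subject_correlation must be in [0, 1)")
        if self.n_groups < 1 or self.n_roi_levels < 2 or self.n_per_group < 2:
            raise ValueError("design too small")


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding)
# ---------------------------------------------------------------------------

def _sum_code(levels: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor with k levels (k-1 columns)."""
    out = np.zeros((len(levels), k - 1))
    for j in range(k - 1):
        out[levels == j, j] = 1.0
        out[levels == k - 1, j] = -1.0
    return out


def _ssr(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _fit_arrays(Y: np.ndarray, group_idx: np.ndarray,
                age_groups: tuple[str, ...], roi_ids: tuple[str, ...]) -> MixedModelResult:
    """Split-plot fit on a complete (N subjects × b ROIs) response matrix."""
    N, b = Y.shape
    a = len(age_groups)
    if b < 2:
        raise ValueError("need at least 2 ROI levels")
    group_ns = {g: int((group_idx == gi).sum()) for gi, g in enumerate(age_groups)}
    if any(n < 2 for n in group_ns.values()):
        raise ValueError("need at least 2 participants per age group")

    # --- between-subject stratum: subject means -----------------------------
    u = Y.mean(axis=1)
    gmeans = np.array([u[group_idx == gi].mean() for gi in range(a)])
    sse_between = float(sum(((u[group_idx == gi] - gmeans[gi]) ** 2).sum()
                            for gi in range(a)))
    df_subject = N - a
    ms_subject = b * sse_between / df_subject  # on the y (not subject-mean) scale

    rows = []
    if a >= 2:
        # Type-III age test on subject means (sum-coded OLS drop test)
        Xa = np.column_stack([np.ones(N), _sum_code(group_idx, a)])
        ss_age = _ssr(Xa[:, :1], u) - _ssr(Xa, u)
        f_age = (b * ss_age / (a - 1)) / ms_subject
        rows.append(("age", f_age, a - 1, df_subject,
                     stats.f.sf(f_age, a - 1, df_subject)))

    # --- within-subject stratum: subject-centered responses -----------------
    Z = (Y - u[:, None]).ravel()
    roi_idx = np.tile(np.arange(b), N)
    subj_group = np.repeat(group_idx, b)
    R = _sum_code(roi_idx, b)
    if a >= 2:
        A = _sum_code(subj_group, a)
        AR = np.einsum("ij,ik->ijk", A, R).reshape(len(Z), (a - 1) * (b - 1))
        X_full = np.column_stack([R, AR])
        X_no_roi = AR
        X_no_int = R
    else:
        X_full = R
        X_no_roi = np.empty((len(Z), 0))
        X_no_int = None

    sse_full = _ssr(X_full, Z)
    df_within = (N - a) * (b - 1)
    mse_within = sse_full / df_within

    ss_roi = _ssr(X_no_roi, Z) - sse_full
    f_roi = (ss_roi / (b - 1)) / mse_within
    rows.append(("roi", f_roi, b - 1, df_within, stats.f.sf(f_roi, b - 1, df_within)))
    if a >= 2:
        ss_int = _ssr(X_no_int, Z) - sse_full
        df_int = (a - 1) * (b - 1)
        f_int = (ss_int / df_int) / mse_within
        rows.append(("age:roi", f_int, df_int, df_within,
                     stats.f.sf(f_int, df_int, df_within)))

    anova = pd.DataFrame(rows, columns=["effect", "F", "df_num", "df_den", "p"]
                         ).set_index("effect")
    cell_means = pd.DataFrame(
        [[Y[group_idx == gi][:, r].mean() for r in range(b)] for gi in range(a)],
        index=list(age_groups), columns=list(roi_ids),
    )
    sigma2_resid = mse_within
    sigma2_subject = max(0.0, (ms_subject - mse_within) / b)
    return MixedModelResult(
        anova=anova, age_groups=age_groups, roi_ids=roi_ids,
        cell_means=cell_means, group_ns=group_ns,
        ms_subject=ms_subject, df_subject=df_subject,
        mse_within=mse_within, df_within=df_within,
        sigma2_subject=sigma2_subject, sigma2_resid=sigma2_resid,
    )


# ---------------------------------------------------------------------------
# public model fit
# ---------------------------------------------------------------------------

def fit_mixed_model(table: pd.DataFrame) -> MixedModelResult:
    """Fit ``rho ~ age * ROI + (1 | participant)`` on a tidy similarity table.

    ``table`` needs columns participant_id, age_group, roi_id, rho, with one
    row per participant×ROI and every participant contributing all ROIs.
    With a single age group the age terms are omitted (the adult-only model).
    """
    required = {"participant_id", "age_group", "roi_id", "rho"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"similarity table lacks columns: {sorted(missing)}")
    if not np.isfinite(table["rho"]).all():
        raise ValueError("rho values must be finite")

    roi_ids = tuple(pd.unique(table["roi_id"]))
    if len(roi_ids) < 2:
        raise ValueError("need at least 2 ROI levels")
    age_groups = tuple(pd.unique(table["age_group"]))

    wide = table.pivot_table(index="participant_id", columns="roi_id",
                             values="rho", aggfunc="first")
    if wide.isna().any().any() or len(wide) * len(roi_ids) != len(table):
        raise ValueError("design incomplete: each participant needs one rho per ROI")
    wide = wide[list(roi_ids)]
    grp = table.drop_duplicates("participant_id").set_index("participant_id")["age_group"]
    group_idx = np.array([age_groups.index(grp[p]) for p in wide.index])
    return _fit_arrays(wide.to_numpy(), group_idx, age_groups, roi_ids)


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts
# ---------------------------------------------------------------------------

def _satterthwaite(c1: float, ms1: float, df1: int,
                   c2: float, ms2: float, df2: int) -> float:
    v = c1 * ms1 + c2 * ms2
    denom = (c1 * ms1) ** 2 / df1 + (c2 * ms2) ** 2 / df2
    return v**2 / denom if denom > 0 else df2


def estimated_marginal_means(model: MixedModelResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell estimated marginal means with 95% CIs against zero.

    For this design the EMMs are the unweighted cell means; their variance
    combines the two error strata, Var = (MS_subj + (b-1)·MSE_w) / (b·n_g),
    with Satterthwaite degrees of freedom.
    """
    b = len(model.roi_ids)
    rows = []
    for g in model.age_groups:
        n_g = model.group_ns[g]
        var = (model.ms_subject + (b - 1) * model.mse_within) / (b * n_g)
        df = _satterthwaite(1 / (b * n_g), model.ms_subject, model.df_subject,
                            (b - 1) / (b * n_g), model.mse_within, model.df_within)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        for r in model.roi_ids:
            m = model.cell_means.loc[g, r]
            se = np.sqrt(var)
            lo, hi = m - tcrit * se, m + tcrit * se
            rows.append({"age_group": g, "roi_id": r, "emmean": m, "se": se,
                         "df": df, "ci_low": lo, "ci_high": hi,
                         "excludes_zero": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment of a p-value family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def posthoc_roi_contrasts(model: MixedModelResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise ROI contrasts on EMMs, Holm-corrected within each age group.

    ROI differences within a subject cancel the random intercept, so the
    contrast variance is 2·MSE_w/n_g with the within-stratum df.
    """
    rows = []
    for g in model.age_groups:
        n_g = model.group_ns[g]
        se = np.sqrt(2 * model.mse_within / n_g)
        group_rows = []
        for r1, r2 in combinations(model.roi_ids, 2):
            diff = model.cell_means.loc[g, r1] - model.cell_means.loc[g, r2]
            t = diff / se
            p = 2 * stats.t.sf(abs(t), model.df_within)
            group_rows.append({"age_group": g, "contrast": f"{r1} - {r2}",
                               "estimate": diff, "t": t, "df": model.df_within,
                               "p_raw": p})
        adj = holm_adjust([r["p_raw"] for r in group_rows])
        for r, pa in zip(group_rows, adj):
            r["p_holm"] = pa
            r["significant"] = bool(pa < alpha)
        rows.extend(group_rows)
    return pd.DataFrame(rows)


def between_age_contrasts(model: MixedModelResult, roi_id: str | None = None) -> pd.DataFrame:
    """Old-minus-young group contrast within each (or one named) ROI.

    A between-group difference at a fixed ROI mixes both error strata:
    Var = (MS_subj + (b-1)·MSE_w)/b · (1/n1 + 1/n2), Satterthwaite df.
    """
    if len(model.age_groups) != 2:
        raise ValueError("between-age contrasts need exactly 2 age groups")
    g1, g2 = model.age_groups  # contrast is second minus first (old - young)
    b = len(model.roi_ids)
    n1, n2 = model.group_ns[g1], model.group_ns[g2]
    w = (1 / n1 + 1 / n2)
    var = (model.ms_subject + (b - 1) * model.mse_within) / b * w
    df = _satterthwaite(w / b, model.ms_subject, model.df_subject,
                        w * (b - 1) / b, model.mse_within, model.df_within)
    rois = model.roi_ids if roi_id is None else (roi_id,)
    rows = []
    for r in rois:
        if r not in model.roi_ids:
            raise ValueError(f"unknown ROI: {r}")
        diff = model.cell_means.loc[g2, r] - model.cell_means.loc[g1, r]
        t = diff / np.sqrt(var)
        rows.append({"roi_id": r, "contrast": f"{g2} - {g1}", "estimate": diff,
                     "t": t, "df": df, "p": 2 * stats.t.sf(abs(t), df)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo power and FWER harnesses
# ---------------------------------------------------------------------------

def _interaction_pattern(a: int, b: int) -> np.ndarray:
    """A doubly-centered a×b cell pattern carrying a pure interaction."""
    base = np.outer(np.linspace(-1, 1, a), np.linspace(-1, 1, b))
    base -= base.mean(axis=0, keepdims=True)
    base -= base.mean(axis=1, keepdims=True)
    return base / np.sqrt((base**2).mean())


def _simulate_dataset(rng: np.random.Generator, cfg: PowerSimConfig,
                      cell_effects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b, n = cfg.n_groups, cfg.n_roi_levels, cfg.n_per_group
    rho = cfg.within_subject_correlation
    N = a * n
    group_idx = np.repeat(np.arange(a), n)
    intercepts = rng.normal(0.0, np.sqrt(rho), N)
    eps = rng.normal(0.0, np.sqrt(1.0 - rho), (N, b))
    Y = intercepts[:, None] + eps + cell_effects[group_idx]
    return Y, group_idx


def _sim_labels(cfg: PowerSimConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return (tuple(f"g{i}" for i in range(cfg.n_groups)),
            tuple(f"roi{i}" for i in range(cfg.n_roi_levels)))


def simulate_fwer(config: PowerSimConfig) -> dict:
    """Family-wise error of the Holm-corrected within-group ROI contrasts
    under the global null.

    Each replicate draws a balanced null dataset (unit total variance split
    between the subject intercept and residual by
    ``within_subject_correlation``), fits the mixed model and runs the Holm
    post hoc families.  The Holm guarantee is per family — the contrasts
    across ROIs *within one age group* — so the reported ``fwer`` is the
    largest per-family rate of at least one false rejection; the pooled rate
    of any rejection anywhere in a replicate (which Holm does not bound by
    alpha, since the groups form separate families) is returned alongside as
    ``any_rejection_rate``.  A binomial standard error and 95% CI accompany
    the estimate.
    """
    if config.effect_size_f != 0:
        raise ValueError("simulate_fwer requires f = 0 (use simulate_power)")
    if config.n_reps < 1000:
        raise ValueError("insufficient replicates (need n_reps >= 1000)")
    rng = np.random.default_rng(config.seed)
    groups, rois = _sim_labels(config)
    zero = np.zeros((config.n_groups, config.n_roi_levels))
    fam_hits = np.zeros(config.n_groups)
    any_hits = 0
    for _ in range(config.n_reps):
        Y, gidx = _simulate_dataset(rng, config, zero)
        model = _fit_arrays(Y, gidx, groups, rois)
        ph = posthoc_roi_contrasts(model, alpha=config.alpha)
        per = (ph.groupby("age_group")["significant"].any()
               .reindex(list(groups)).to_numpy())
        fam_hits += per
        any_hits += int(per.any())
    rates = fam_hits / config.n_reps
    fwer = float(rates.max())
    se = np.sqrt(fwer * (1 - fwer) / config.n_reps)
    return {"fwer": fwer, "fwer_per_group": rates.tolist(),
            "any_rejection_rate": any_hits / config.n_reps, "se": float(se),
            "ci_low": max(0.0, fwer - 1.96 * se),
            "ci_high": min(1.0, fwer + 1.96 * se),
            "n_reps": config.n_reps, "alpha": config.alpha}


def simulate_power(config: PowerSimConfig) -> dict:
    """Power of the age×ROI interaction F test at the configured Cohen's f.

    Cohen's f is taken relative to the total within-cell standard deviation
    (subject intercept plus residual, fixed at 1): interaction cell offsets
    with root-mean-square f are planted on a doubly-centered pattern.
    """
    if config.effect_size_f <= 0:
        raise ValueError("simulate_power requires f > 0 (use simulate_fwer for the null)")
    rng = np.random.default_rng(config.seed)
    groups, rois = _sim_labels(config)
    effects = config.effect_size_f * _interaction_pattern(config.n_groups,
                                                          config.n_roi_levels)
    hits = 0
    for _ in range(config.n_reps):
        Y, gidx = _simulate_dataset(rng, config, effects)
        model = _fit_arrays(Y, gidx, groups, rois)
        hits += int(model.anova.loc["age:roi", "p"] < config.alpha)
    power = hits / config.n_reps
    se = np.sqrt(power * (1 - power) / max(config.n_reps, 1))
    return {"power": power, "se": se, "n_reps": config.n_reps,
            "alpha": config.alpha, "effect_size_f": config.effect_size_f,
            "n_per_group": config.n_per_group,
            "within_subject_correlation": config.within_subject_correlation}
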