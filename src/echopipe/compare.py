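"""Method comparison, group inference, and behavioral statistics.

The comparison framework regresses each subject's denoised Z-statistic
map (weighted-echoes or RETROICOR) voxel-wise on the uncorrected
single-echo Z map.  A slope of 1 means the post-processing approach
yields equivalent Z values; below 1 means the denoised Z values are
systematically lower — the signature of removing noise-driven Z
fluctuations that the raw reference retains.  The battery of tests on the
per-subject slopes and R^2 values (one-sample t against 1, Welch t
between methods, one-way ANOVA with Tukey-adjusted pairwise contrasts
across groups) mirrors how such comparisons are reported.

Group-level activation uses voxel-wise OLS on subject contrast estimates
with group indicators and demeaned covariates (e.g., mean correct-trial
reaction time), followed by permutation cluster-extent inference:
supra-threshold (Z > 2.32 by default) 26-connected clusters are tested
against the sign-flipping null distribution of maximum cluster size, and
clusters with p < 0.05 are flagged — a self-contained alternative to
parametric random-field cluster p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .firstlevel import z_from_t

__all__ = [
    "MethodComparison",
    "ClusterResult",
    "Cluster",
    "zmap_regression",
    "slope_test_battery",
    "group_contrast",
    "find_clusters",
    "cluster_inference",
    "behavior_stats",
    "bold_behavior_correlation",
]

logger = logging.getLogger(__name__)

VOXEL_Z_THRESHOLD = 2.32   # voxel-level threshold, P < 0.01 one-sided
CLUSTER_ALPHA = 0.05
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class MethodComparison:
    """One subject-method row of the voxel-wise Z-map regression."""

    subject: str
    method: str
    group: str
    slope: float
    intercept: float
    r2: float
    n_voxels: int


def zmap_regression(
    test_z: np.ndarray,
    reference_z: np.ndarray,
    mask: np.ndarray,
    intercept: bool = True,
) -> tuple[float, float, float, int]:
    """OLS of test-map Z on reference-map Z over in-mask voxels.

    Returns (slope, intercept, R^2, n_voxels).  With ``intercept=False``
    the line is forced through the origin and R^2 is the uncentered
    coefficient of determination.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(reference_z, dtype=float)[mask]
    y = np.asarray(test_z, dtype=float)[mask]
    if np.var(x) == 0:
        raise ValueError("reference map has zero variance within the mask")
    if intercept:
        res = stats.linregress(x, y)
        slope, icept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        icept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum(y**2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, icept, r2, int(mask.sum())


def _f_oneway(samples: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p with an exact-tie guard.

    When the between-group sum of squares is zero (identical group means)
    the F statistic is defined as 0 with p = 1, instead of the 0/0 NaN a
    naive computation produces on degenerate data.
    """
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_between <= 1e-300:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def _tukey(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    groups = sorted(set(labels))
    samples = [values[labels == g] for g in groups]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def slope_test_battery(
    comparisons: list[MethodComparison] | pd.DataFrame,
) -> dict:
    """Statistical battery over the per-subject slope and R^2 values.

    Per method: one-sample t of the slopes against 1.  Between the two
    methods: Welch two-sample t for slope and for R^2.  Across groups
    (when group labels vary): one-way ANOVA and Tukey-adjusted pairwise
    comparisons for both quantities per method.
    """
    if isinstance(comparisons, list):
        df = pd.DataFrame([c.__dict__ for c in comparisons])
    else:
        df = comparisons.copy()
    methods = sorted(df["method"].unique())
    out: dict = {"per_method": {}, "between_methods": {}, "group_anova": {}}

    for m in methods:
        sl = df.loc[df["method"] == m, "slope"].to_numpy(float)
        if len(sl) < 2:
            raise ValueError(f"method {m!r} has fewer than 2 subjects")
        if sl.std(ddof=1) == 0.0:
            # degenerate constant sample: t is 0 when the mean hits the
            # null value exactly, +/-inf otherwise
            t = 0.0 if sl.mean() == 1.0 else np.sign(sl.mean() - 1.0) * np.inf
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_1samp(sl, popmean=1.0)
        out["per_method"][m] = {
            "mean_slope": float(sl.mean()),
            "sd_slope": float(sl.std(ddof=1)),
            "t_vs_1": float(t),
            "df": len(sl) - 1,
            "p": float(p),
        }

    if len(methods) == 2:
        a = df[df["method"] == methods[0]]
        b = df[df["method"] == methods[1]]
        for quantity in ("slope", "r2"):
            res = stats.ttest_ind(
                a[quantity].to_numpy(float),
                b[quantity].to_numpy(float),
                equal_var=False,
            )
            out["between_methods"][quantity] = {
                "methods": methods,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }

    for m in methods:
        sub = df[df["method"] == m]
        labels = sub["group"].to_numpy()
        if len(set(labels)) < 2:
            continue
        entry = {}
        for quantity in ("slope", "r2"):
            vals = sub[quantity].to_numpy(float)
            samples = [vals[labels == g] for g in sorted(set(labels))]
            f, p = _f_oneway(samples)
            entry[quantity] = {
                "F": float(f),
                "df": (len(samples) - 1, len(vals) - len(samples)),
                "p": float(p),
                "tukey": _tukey(vals, labels),
            }
        out["group_anova"][m] = entry
    return out


# ---------------------------------------------------------------------------
# group-level activation model


@dataclass
class GroupStatMaps:
    """Voxel-wise group model output."""

    group_means: dict[str, np.ndarray]
    difference_z: dict[str, np.ndarray]
    omnibus_f: np.ndarray
    omnibus_p: np.ndarray
    dof: int
    condition_number: float


def group_contrast(
    subject_maps: np.ndarray,
    groups: list[str],
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> GroupStatMaps:
    """Voxel-wise OLS of subject contrast estimates on group membership.

    ``subject_maps`` is ``(n_subjects, x, y, z)``.  The design holds one
    indicator column per group (cell means) plus covariates demeaned
    across all subjects; pairwise group differences are returned as Z
    maps, plus the omnibus F over group means.  A covariate nearly
    collinear with the group structure is reported as a warning with the
    design condition number, not an error.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    labels = np.asarray(groups)
    if len(labels) != n:
        raise ValueError("one group label per subject required")
    names = sorted(set(labels))
    if len(names) < 2 or any((labels == g).sum() < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 subjects each")

    cols = [np.asarray(labels == g, dtype=float) for g in names]
    x = np.column_stack(cols)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cov = cov - cov.mean(axis=0, keepdims=True)
        keep = cov.std(axis=0) > 0
        cov = cov[:, keep]
        x = np.column_stack([x, cov])
    cond = float(np.linalg.cond(x))
    if cond > 1e6:
        logger.warning(
            "group design is near-confounded (condition number %.3g)", cond
        )

    rank = np.linalg.matrix_rank(x)
    dof = n - rank
    y = maps.reshape(n, -1)
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)

    grid = maps.shape[1:]
    group_means = {g: beta[i].reshape(grid) for i, g in enumerate(names)}

    diff_z: dict[str, np.ndarray] = {}
    for i in range(len(names)):
        for j in range(len(names)):
            if i == j:
                continue
            c = np.zeros(x.shape[1])
            c[i], c[j] = 1.0, -1.0
            var = sigma2 * float(c @ xtx_inv @ c)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(var > 0, (c @ beta) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
            diff_z[f"{names[i]}>{names[j]}"] = z_from_t(t, dof).reshape(grid)

    # omnibus F: equality of the group means
    k = len(names)
    contrast_rows = np.zeros((k - 1, x.shape[1]))
    for r in range(k - 1):
        contrast_rows[r, r], contrast_rows[r, r + 1] = 1.0, -1.0
    cb = contrast_rows @ beta
    mid = np.linalg.pinv(contrast_rows @ xtx_inv @ contrast_rows.T)
    quad = np.einsum("rv,rs,sv->v", cb, mid, cb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fmap = np.where(sigma2 > 0, quad / ((k - 1) * np.where(sigma2 > 0, sigma2, 1)), 0.0)
    pmap = stats.f.sf(fmap, k - 1, max(dof, 1))

    return GroupStatMaps(
        group_means=group_means,
        difference_z=diff_z,
        omnibus_f=fmap.reshape(grid),
        omnibus_p=pmap.reshape(grid),
        dof=dof,
        condition_number=cond,
    )


# ---------------------------------------------------------------------------
# cluster-extent inference


@dataclass
class Cluster:
    voxels: np.ndarray          # (n, 3) integer indices
    size: int
    peak_z: float
    p_value: float = np.nan
    significant: bool = False


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    voxel_threshold: float = VOXEL_Z_THRESHOLD
    null_max_sizes: np.ndarray | None = None

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def find_clusters(zmap: np.ndarray, voxel_z: float = VOXEL_Z_THRESHOLD) -> list[Cluster]:
    """26-connected supra-threshold clusters of a Z map (one-sided, Z > thr)."""
    above = np.asarray(zmap) > voxel_z
    labels, n = ndimage.label(above, structure=CONNECTIVITY_26)
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = zmap[labels == lab]
        clusters.append(
            Cluster(voxels=idx, size=len(idx), peak_z=float(vals.max()))
        )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def _one_sample_z(maps: np.ndarray) -> np.ndarray:
    """One-sample t -> Z map over the subject axis (axis 0)."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return z_from_t(t, n - 1)


def cluster_inference(
    subject_maps: np.ndarray,
    voxel_z: float = VOXEL_Z_THRESHOLD,
    cluster_alpha: float = CLUSTER_ALPHA,
    n_permutations: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Permutation cluster-extent inference on a stack of subject maps.

    The observed group Z map is the one-sample t (over subjects)
    converted to Z.  Under the null of symmetric subject effects, the
    signs of whole subject maps are exchangeable: ``n_permutations``
    random sign-flips build the null distribution of the maximum
    supra-threshold cluster size, and each observed cluster receives
    ``p = (1 + #(max_perm >= size)) / (1 + n_permutations)``.

    A map with no supra-threshold voxels yields an empty (non-error)
    result.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    maps = np.asarray(subject_maps, dtype=float)
    if mask is not None:
        maps = maps * np.asarray(mask, dtype=bool)[None]
    n_subj = maps.shape[0]

    zmap = _one_sample_z(maps)
    clusters = find_clusters(zmap, voxel_z)
    result = ClusterResult(clusters=clusters, voxel_threshold=voxel_z)
    if not clusters:
        result.null_max_sizes = np.zeros(n_permutations, dtype=int)
        return result

    # thresholding the permutation t maps at the t value equivalent to
    # voxel_z is identical to thresholding their Z maps (monotone map),
    # and avoids the per-voxel t -> Z conversion inside the loop
    t_thresh = float(stats.t.isf(stats.norm.sf(voxel_z), n_subj - 1))
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations, dtype=int)
    sqrt_n = np.sqrt(n_subj)
    for p in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        flipped = maps * signs[:, None, None, None]
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tmap = np.where(sd > 0, mean / (sd / sqrt_n), 0.0)
        labels, nlab = ndimage.label(tmap > t_thresh, structure=CONNECTIVITY_26)
        if nlab:
            null_max[p] = int(np.bincount(labels.ravel())[1:].max())

    for c in result.clusters:
        c.p_value = float((1 + np.sum(null_max >= c.size)) / (1 + n_permutations))
        c.significant = c.p_value < cluster_alpha
    result.null_max_sizes = null_max
    return result


# ---------------------------------------------------------------------------
# behavior


def summarize_behavior(events: pd.DataFrame) -> dict:
    """Per-subject behavioral summary from a trial table with rt/correct."""
    correct = events["correct"].astype(bool)
    out = {
        "accuracy": float(correct.mean()),
        "rt_correct": float(events.loc[correct, "rt"].mean()),
    }
    for cond in ("congruent", "incongruent"):
        sel = events["condition"] == cond
        if not (sel & correct).any():
            raise ValueError(f"no correct {cond} trials for this subject")
        out[f"rt_{cond}"] = float(events.loc[sel & correct, "rt"].mean())
        out[f"accuracy_{cond}"] = float(correct[sel].mean())
    out["rt_executive"] = out["rt_incongruent"] - out["rt_congruent"]
    return out


def behavior_stats(
    events_by_subject: dict[str, pd.DataFrame],
    groups: dict[str, str],
) -> dict:
    """Group behavioral statistics over per-subject trial tables.

    Computes per-subject summaries (mean correct-trial RT overall and per
    condition, accuracy, executive RT), then a one-way ANOVA with Tukey
    pairwise comparisons on each RT measure across groups.  Helper
    entries for two-group Wilcoxon rank-sum (exact null for n <= 25) and
    chi-square tests are exposed as callables on the summary table.
    """
    rows = []
    for sid, ev in events_by_subject.items():
        try:
            summ = summarize_behavior(ev)
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
        summ["subject"] = sid
        summ["group"] = groups[sid]
        rows.append(summ)
    df = pd.DataFrame(rows)
    labels = df["group"].to_numpy()
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")

    anova: dict = {}
    for measure in ("rt_correct", "rt_congruent", "rt_incongruent",
                    "rt_executive", "accuracy"):
        vals = df[measure].to_numpy(float)
        samples = [vals[labels == g] for g in names]
        f, p = _f_oneway(samples)
        anova[measure] = {
            "F": float(f),
            "df": (len(names) - 1, len(vals) - len(names)),
            "p": float(p),
            "tukey": _tukey(vals, labels),
        }
    return {"summary": df, "anova": anova}


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-group Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for samples of 25 or fewer, normal
    approximation otherwise.  Returns the Mann-Whitney U statistic for
    the first sample and the two-sided p.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"W": float(res.statistic), "p": float(res.pvalue), "method": method}


def chi_square_counts(table: np.ndarray) -> dict:
    """Chi-square test of independence on a contingency table of counts."""
    res = stats.chi2_contingency(np.asarray(table))
    return {"chi2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}


def bold_behavior_correlation(
    psc: np.ndarray, behavior: np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlation of per-subject percent signal change vs behavior.

    Returns (r, R^2, two-sided p from the t transform).
    """
    psc = np.asarray(psc, float)
    behavior = np.asarray(behavior, float)
    if len(psc) != len(behavior) or len(psc) < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(psc) == 0 or np.std(behavior) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(psc, behavior)
    return float(r), float(r**2), float(p)
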