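"""Per-subject preprocessing and GLM for the event-related flanker task.

The stage chain mirrors a standard FEAT-style first level: frame-wise
displacement QC from the rigid-body motion trace, 6-mm Gaussian spatial
smoothing, 50-s high-pass temporal filtering (implemented as projection
onto a discrete-cosine drift basis), a design matrix of double-gamma
HRF-convolved condition regressors built from the trial table, voxel-wise
OLS with contrast t-statistics mapped to Z, and percent-signal-change
extraction within clusters.

Task regressors are one column per condition x cue cell using correct
trials only; incorrect trials are absorbed into a nuisance column.  The
two installed contrasts are *all versus baseline* (mean over the correct
task columns; low-level fixation is the implicit baseline) and the
*executive* contrast (incongruent minus congruent, collapsed over cue).

Each task column is scaled so that one isolated trial produces a response
with unit peak: contrast estimates are then directly the peak response in
signal units, and percent signal change is ``100 * cope / baseline``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .relaxometry import CombinedSeries

__all__ = [
    "MotionSummary",
    "DesignMatrix",
    "StatMaps",
    "double_gamma_hrf",
    "framewise_displacement",
    "smooth_spatial",
    "highpass_temporal",
    "build_design",
    "highpass_design",
    "fit_glm",
    "percent_signal_change",
    "z_from_t",
]

FD_THRESHOLD_MM = 0.4   # inclusion rule: mean FD below this
HEAD_RADIUS_MM = 50.0   # rotation-to-arc-length conversion
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# hemodynamic response


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t`` (s).

    Difference of two gamma densities (response minus undershoot) with the
    de-facto standard parameters: response delay 6, undershoot delay 16,
    unit dispersions, undershoot amplitude 1/6.  The kernel is scaled to
    unit peak.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = stats.gamma.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - undershoot_ratio * under
    m = h.max()
    return h / m if m > 0 else h


# ---------------------------------------------------------------------------
# motion QC


@dataclass
class MotionSummary:
    """Frame-wise displacement series and the FD inclusion decision."""

    fd: np.ndarray
    mean_fd: float
    included: bool
    threshold_mm: float = FD_THRESHOLD_MM


def framewise_displacement(
    motion_trace: np.ndarray,
    head_radius_mm: float = HEAD_RADIUS_MM,
    threshold_mm: float = FD_THRESHOLD_MM,
) -> MotionSummary:
    """FD per volume from a 6-parameter rigid-body trace.

    ``FD_t = sum |d translations| + r * sum |d rotations|`` with translations
    in mm, rotations in radians converted to arc length on a sphere of
    radius ``head_radius_mm``.  FD of the first volume is defined as 0; the
    mean is taken over the remaining volumes.  A subject is included when
    mean FD is below ``threshold_mm``.
    """
    motion = np.asarray(motion_trace, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion trace must have shape (n_volumes, 6), got {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 volumes")
    diffs = np.abs(np.diff(motion, axis=0))
    fd_tail = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    mean_fd = float(fd_tail.mean())
    return MotionSummary(
        fd=fd, mean_fd=mean_fd, included=mean_fd < threshold_mm,
        threshold_mm=threshold_mm,
    )


# ---------------------------------------------------------------------------
# preprocessing


def _voxel_sizes(series: CombinedSeries) -> np.ndarray:
    return np.sqrt((series.affine[:3, :3] ** 2).sum(axis=0))


def smooth_spatial(series: CombinedSeries, fwhm_mm: float) -> CombinedSeries:
    """Per-volume Gaussian smoothing with kernel width ``fwhm_mm``.

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``; reflective
    boundaries preserve the global mean.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return series.copy_with(series.data.copy(), smoothed_fwhm_mm=0.0)
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / _voxel_sizes(series)
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        out[..., t] = ndimage.gaussian_filter(
            series.data[..., t], sigma=sigma_vox, mode="reflect"
        )
    return series.copy_with(out, smoothed_fwhm_mm=float(fwhm_mm))


def dct_drift_basis(n_volumes: int, tr_ms: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: columns with period longer than ``cutoff_s``.

    DCT-II functions ``cos(pi k (2t + 1) / (2N))`` for ``k = 1..K`` with
    ``K = floor(2 N TR / cutoff)``; the constant term is excluded.
    """
    tr_s = tr_ms / 1000.0
    n_basis = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def highpass_design(design: "DesignMatrix", tr_ms: float,
                    cutoff_s: float) -> "DesignMatrix":
    """Apply the data high-pass to the design columns (FEAT convention).

    Task and nuisance regressors are projected off the same discrete-cosine
    drift basis as the data so that design and data live in the same
    temporal band; the constant column is left untouched.
    """
    basis = dct_drift_basis(design.n_volumes, tr_ms, cutoff_s)
    mat = design.matrix.copy()
    if basis.shape[1] > 0:
        for col in mat.columns:
            if col == "constant":
                continue
            y = mat[col].to_numpy(dtype=float)
            mean = y.mean()
            centered = y - mean
            coef, *_ = np.linalg.lstsq(basis, centered, rcond=None)
            mat[col] = centered - basis @ coef + mean
    return DesignMatrix(
        matrix=mat,
        contrasts=dict(design.contrasts),
        task_columns=list(design.task_columns),
        frame_times=design.frame_times,
        event_peak_scale=design.event_peak_scale,
    )


def highpass_temporal(series: CombinedSeries, cutoff_s: float) -> CombinedSeries:
    """Remove slow drift by projecting out the discrete-cosine basis.

    Components with period longer than ``cutoff_s`` are removed; the voxel
    mean is retained.  Requires ``cutoff_s > 2 * TR`` (anything shorter
    would eat the task band).
    """
    tr_s = series.tr / 1000.0
    if cutoff_s <= 2.0 * tr_s:
        raise ValueError(
            f"high-pass cutoff {cutoff_s} s must exceed twice the TR ({2 * tr_s} s)"
        )
    basis = dct_drift_basis(series.n_volumes, series.tr, cutoff_s)
    data = series.data
    mean = data.mean(axis=3, keepdims=True)
    centered = data - mean
    if basis.shape[1] > 0:
        flat = centered.reshape(-1, series.n_volumes)
        coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
        flat = flat - (basis @ coef).T
        centered = flat.reshape(data.shape)
    return series.copy_with(centered + mean, highpass_cutoff_s=float(cutoff_s))


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Named regressors per volume plus contrast weight vectors.

    ``task_columns`` lists the correct-trial condition regressors that carry
    contrast weight; ``matrix`` additionally holds nuisance columns and the
    constant.  Task columns are scaled to unit isolated-event peak, so the
    effective peak-to-baseline range of every contrast regressor is 1.
    """

    matrix: pd.DataFrame
    contrasts: dict[str, np.ndarray]
    task_columns: list[str]
    frame_times: np.ndarray
    event_peak_scale: float = 1.0

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def contrast_vector(self, name: str) -> np.ndarray:
        return self.contrasts[name]


def _convolve_events(
    onsets_s: np.ndarray,
    duration_s: float,
    frame_times: np.ndarray,
    hrf_kwargs: dict | None = None,
    dt: float = 0.05,
    hrf_length_s: float = 32.0,
) -> tuple[np.ndarray, float]:
    """HRF-convolve a boxcar event train on a fine grid and sample at frames.

    Returns the sampled regressor (unscaled) and the peak amplitude of one
    isolated event on the fine grid, used for unit-peak normalization.
    """
    t_end = frame_times[-1] + hrf_length_s
    n_fine = int(np.ceil(t_end / dt)) + 1
    fine = np.zeros(n_fine)
    for onset in onsets_s:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + duration_s) / dt))
        fine[i0:max(i1, i0 + 1)] = 1.0
    kernel = double_gamma_hrf(np.arange(0, hrf_length_s, dt), **(hrf_kwargs or {}))
    conv = np.convolve(fine, kernel)[:n_fine] * dt

    single = np.zeros(int(np.ceil((duration_s + hrf_length_s) / dt)) + 1)
    single[: max(int(round(duration_s / dt)), 1)] = 1.0
    single_resp = np.convolve(single, kernel) * dt
    peak = float(single_resp.max())

    idx = np.clip(np.round(frame_times / dt).astype(int), 0, n_fine - 1)
    return conv[idx], peak


def build_design(
    events: pd.DataFrame,
    tr_ms: float,
    n_volumes: int,
    correct_only: bool = True,
    nuisance: pd.DataFrame | None = None,
    hrf_kwargs: dict | None = None,
    target_duration_s: float = 1.55,
) -> DesignMatrix:
    """Build the first-level design matrix from a trial table.

    ``events`` needs columns ``onset`` (s), ``condition``
    (congruent/incongruent), ``cue`` (cued/uncued) and, when
    ``correct_only``, ``correct``.  One regressor is built per
    condition x cue cell of the correct trials (boxcar of the target
    presentation convolved with the double-gamma HRF); incorrect trials go
    into a separate nuisance column.  Contrasts installed:

    - ``all_vs_baseline``: mean of the correct task columns (fixation is
      the implicit baseline of the GLM).
    - ``executive``: mean of incongruent columns minus mean of congruent
      columns, cue conditions merged within congruency.
    """
    frame_times = np.arange(n_volumes) * tr_ms / 1000.0
    events = events.reset_index(drop=True)
    if len(events) and events["onset"].iloc[-1] > frame_times[-1]:
        raise ValueError(
            f"event at {events['onset'].iloc[-1]:.1f} s lies beyond the run "
            f"({frame_times[-1]:.1f} s)"
        )

    if correct_only and "correct" in events.columns and len(events):
        correct_mask = events["correct"].astype(bool)
    else:
        correct_mask = pd.Series(True, index=events.index, dtype=bool)

    cols: dict[str, np.ndarray] = {}
    peak_scale = 1.0
    task_columns: list[str] = []
    conditions = ["congruent", "incongruent"]
    cues = ["cued", "uncued"]
    for cond in conditions:
        for cue in cues:
            sel = events[
                correct_mask
                & (events["condition"] == cond)
                & (events["cue"] == cue)
            ] if len(events) else events
            name = f"{cond}_{cue}"
            if len(sel) == 0:
                continue
            reg, peak = _convolve_events(
                sel["onset"].to_numpy(float) + 0.55,  # target onset within trial
                target_duration_s,
                frame_times,
                hrf_kwargs,
            )
            peak_scale = peak
            cols[name] = reg / peak
            task_columns.append(name)

    if len(events) and correct_only and (~correct_mask).any():
        sel = events[~correct_mask]
        reg, peak = _convolve_events(
            sel["onset"].to_numpy(float) + 0.55, target_duration_s,
            frame_times, hrf_kwargs,
        )
        cols["incorrect"] = reg / peak

    if not task_columns and len(events):
        raise ValueError("no correct trials in any condition; cannot build contrasts")
    if not cols:
        # degenerate empty-event design: all-zero task columns, still usable
        cols["congruent_cued"] = np.zeros(n_volumes)
        cols["incongruent_cued"] = np.zeros(n_volumes)
        task_columns = ["congruent_cued", "incongruent_cued"]

    if nuisance is not None:
        for c in nuisance.columns:
            cols[str(c)] = np.asarray(nuisance[c], dtype=float)
    cols["constant"] = np.ones(n_volumes)

    matrix = pd.DataFrame(cols, index=np.arange(n_volumes))

    names = list(matrix.columns)
    cong = [c for c in task_columns if c.startswith("congruent")]
    incong = [c for c in task_columns if c.startswith("incongruent")]
    if len(events):
        # a condition that has trials but lost them all to the correctness
        # filter cannot carry its contrast weight
        for cond, cols in (("congruent", cong), ("incongruent", incong)):
            present = (events["condition"] == cond).any()
            if present and not cols:
                raise ValueError(
                    f"no correct {cond} trials: the contrasts cannot be built"
                )

    all_vec = np.zeros(len(names))
    for c in task_columns:
        all_vec[names.index(c)] = 1.0 / len(task_columns)
    contrasts = {"all_vs_baseline": all_vec}
    if cong and incong:
        exec_vec = np.zeros(len(names))
        for c in incong:
            exec_vec[names.index(c)] = 1.0 / len(incong)
        for c in cong:
            exec_vec[names.index(c)] -= 1.0 / len(cong)
        contrasts["executive"] = exec_vec
    elif not len(events):
        contrasts["executive"] = np.zeros(len(names))

    return DesignMatrix(
        matrix=matrix,
        contrasts=contrasts,
        task_columns=task_columns,
        frame_times=frame_times,
        event_peak_scale=peak_scale,
    )


# ---------------------------------------------------------------------------
# GLM


@dataclass
class StatMaps:
    """Per-subject GLM output: betas per regressor, cope/var/t/Z per contrast."""

    beta: dict[str, np.ndarray]
    cope: dict[str, np.ndarray]
    varcope: dict[str, np.ndarray]
    t: dict[str, np.ndarray]
    z: dict[str, np.ndarray]
    dof: int
    mask: np.ndarray
    column_names: list[str] = field(default_factory=list)


def z_from_t(t_values: np.ndarray, dof: int, zmax: float = 38.0) -> np.ndarray:
    """Map t-statistics to standard-normal deviates via tail probability.

    Computed on the |t| tail for numerical stability and clipped at
    ``zmax`` (beyond which double precision cannot represent the p-value).
    """
    t_values = np.asarray(t_values, dtype=float)
    p_tail = stats.t.sf(np.abs(t_values), dof)
    z = stats.norm.isf(np.clip(p_tail, 1e-320, 1.0))
    z = np.clip(z, -zmax, zmax)
    return np.sign(t_values) * z


def _ar1_transform(y: np.ndarray, x: np.ndarray, rho: float):
    """Cochrane-Orcutt quasi-difference of data and design."""
    yt = y[..., 1:] - rho * y[..., :-1]
    xt = x[1:] - rho * x[:-1]
    return yt, xt


def fit_glm(
    series: CombinedSeries,
    design: DesignMatrix,
    prewhiten: bool = False,
) -> StatMaps:
    """Voxel-wise OLS fit of the design with contrast t -> Z maps.

    With ``prewhiten`` an AR(1) Cochrane-Orcutt step is applied: rho is
    pooled over in-mask voxels from the OLS residual lag-1 autocorrelation
    and both data and design are quasi-differenced before refitting.
    """
    x = design.matrix.to_numpy(dtype=float)
    if x.shape[0] != series.n_volumes:
        raise ValueError(
            f"design rows ({x.shape[0]}) != series volumes ({series.n_volumes})"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"design is rank deficient (rank {rank} < {x.shape[1]} columns)")

    grid = series.grid_shape
    y = series.data.reshape(-1, series.n_volumes)

    if prewhiten:
        pinv = np.linalg.pinv(x)
        beta0 = y @ pinv.T
        resid0 = y - beta0 @ x.T
        r = resid0[series.mask.reshape(-1)]
        num = np.sum(r[:, 1:] * r[:, :-1])
        den = np.sum(r**2)
        rho = float(num / den) if den > 0 else 0.0
        y_fit, x_fit = _ar1_transform(y, x, rho)
    else:
        y_fit, x_fit = y, x

    n_eff = x_fit.shape[0]
    dof = n_eff - rank
    xtx_inv = np.linalg.pinv(x_fit.T @ x_fit)
    beta = y_fit @ (xtx_inv @ x_fit.T).T
    resid = y_fit - beta @ x_fit.T
    sigma2 = (resid**2).sum(axis=1) / max(dof, 1)

    names = design.columns
    beta_maps = {
        name: beta[:, j].reshape(grid) for j, name in enumerate(names)
    }
    cope, varcope, tmaps, zmaps = {}, {}, {}, {}
    for cname, cvec in design.contrasts.items():
        c = np.asarray(cvec, dtype=float)
        eff = beta @ c
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(invalid="ignore", divide="ignore"):
            tval = np.where(var > 0, eff / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        cope[cname] = eff.reshape(grid)
        varcope[cname] = var.reshape(grid)
        tmaps[cname] = tval.reshape(grid)
        zmaps[cname] = z_from_t(tval, dof).reshape(grid)

    return StatMaps(
        beta=beta_maps, cope=cope, varcope=varcope, t=tmaps, z=zmaps,
        dof=dof, mask=series.mask, column_names=names,
    )


def percent_signal_change(
    series: CombinedSeries,
    design: DesignMatrix,
    cluster_mask: np.ndarray,
    contrast: str = "all_vs_baseline",
    stats_maps: StatMaps | None = None,
) -> float:
    """Mean percent signal change of a contrast within a cluster.

    Because task columns are unit-isolated-event-peak scaled, the contrast
    estimate is the peak-to-baseline response in signal units; percent
    signal change per voxel is ``100 * cope / temporal mean`` and the
    cluster value is its mean over ``cluster_mask`` voxels.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    if stats_maps is None:
        stats_maps = fit_glm(series, design)
    cope = stats_maps.cope[contrast]
    baseline = series.data.mean(axis=3)
    vals = 100.0 * cope[cluster_mask] / baseline[cluster_mask]
    return float(vals.mean())
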