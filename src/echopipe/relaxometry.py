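"""T2* relaxometry and multi-echo combination.

A multi-echo EPI acquisition samples the mono-exponential transverse decay

    S(TE) = S0 * exp(-TE / T2*)

at several echo times per excitation.  This module estimates per-voxel
``S0`` and ``T2*`` maps from the echo images by a log-linear fit, and
fuses the echoes into one BOLD-sensitivity-weighted time series using the
weights

    w_n = (TE_n / T2*) * exp(-TE_n / T2*),

which peak at ``TE = T2*`` — the echo time of maximal BOLD contrast.  A
single-echo pass-through is provided so downstream stages can process a
conventional single-echo analysis through the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoSeries",
    "RelaxometryMaps",
    "CombinedSeries",
    "compute_mask",
    "fit_t2star",
    "weight_profile",
    "combine_weighted",
    "extract_single_echo",
]

#: Physiological clamp for the T2* estimate, ms.  Three points per voxel do
#: not constrain flat or noise-dominated decays; estimates are clipped here.
T2STAR_BOUNDS_MS = (5.0, 300.0)


@dataclass
class EchoSeries:
    """One echo of a multi-echo 4D acquisition.

    Parameters
    ----------
    data:
        Signal array of shape ``(x, y, z, t)``, arbitrary units.
    te:
        Echo time in milliseconds (positive).
    tr:
        Repetition time in milliseconds.
    mask:
        Boolean brain mask of shape ``(x, y, z)``.
    affine:
        4x4 voxel-to-world affine (NIfTI convention).
    """

    data: np.ndarray
    te: float
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"echo data must be 4D (x, y, z, t), got shape {self.data.shape}"
            )
        if self.te <= 0:
            raise ValueError(f"echo time must be positive, got {self.te} ms")
        if self.tr <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr} ms")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.data.shape[:3]}"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        """Volume acquisition times in seconds from run start."""
        return np.arange(self.n_volumes) * self.tr / 1000.0


@dataclass
class RelaxometryMaps:
    """Per-voxel mono-exponential decay parameters.

    ``fit_quality`` is the coefficient of determination of the log-linear
    fit of mean signal against echo time (1 for exact exponentials, 0 for
    degenerate voxels).
    """

    s0: np.ndarray
    t2star: np.ndarray
    fit_quality: np.ndarray


@dataclass
class CombinedSeries:
    """A single 4D time series produced by echo combination or extraction."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    method_tag: str = "weighted"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4D, got shape {self.data.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr / 1000.0

    def copy_with(self, data: np.ndarray, method_tag: str | None = None,
                  **provenance) -> "CombinedSeries":
        prov = dict(self.provenance)
        prov.update(provenance)
        return CombinedSeries(
            data=np.asarray(data, dtype=np.float64),
            tr=self.tr,
            mask=self.mask,
            affine=self.affine,
            method_tag=self.method_tag if method_tag is None else method_tag,
            provenance=prov,
        )


def check_aligned(echoes: list[EchoSeries]) -> None:
    """Raise if the echoes of a session disagree on grid, length, TR or mask."""
    if len(echoes) < 2:
        raise ValueError(f"need at least 2 echoes, got {len(echoes)}")
    first = echoes[0]
    tes = [e.te for e in echoes]
    if any(b <= a for a, b in zip(tes, tes[1:])):
        raise ValueError(f"echo times must be strictly increasing, got {tes}")
    for e in echoes[1:]:
        if e.data.shape != first.data.shape:
            raise ValueError("echoes do not share grid/volume count")
        if e.tr != first.tr:
            raise ValueError("echoes do not share TR")
        if not np.array_equal(e.mask, first.mask):
            raise ValueError("echoes do not share mask")


def compute_mask(echo: EchoSeries, fraction: float = 0.10) -> np.ndarray:
    """Intensity mask: voxels whose temporal-mean signal exceeds ``fraction``
    of the robust (98th percentile) maximum of the first echo."""
    mean_img = echo.data.mean(axis=3)
    robust_max = np.percentile(mean_img, 98)
    return mean_img > fraction * robust_max


def fit_t2star(
    echoes: list[EchoSeries],
    bounds_ms: tuple[float, float] = T2STAR_BOUNDS_MS,
) -> RelaxometryMaps:
    """Estimate S0 and T2* maps by a log-linear fit over echo time.

    The fit uses the time-averaged signal of each echo (one static map per
    run): ordinary least squares of ``ln(mean S)`` on TE gives slope
    ``-1/T2*`` and intercept ``ln S0``.  T2* is clamped to ``bounds_ms``;
    voxels with any non-positive mean signal are assigned the upper bound
    with ``fit_quality`` 0 (no decay information).

    Raises
    ------
    ValueError
        If fewer than two echoes are supplied or echoes are misaligned.
    """
    check_aligned(echoes)
    tes = np.array([e.te for e in echoes], dtype=float)
    lo, hi = bounds_ms

    mean_signals = np.stack([e.data.mean(axis=3) for e in echoes], axis=-1)
    grid = mean_signals.shape[:3]
    flat = mean_signals.reshape(-1, len(echoes))

    valid = np.all(flat > 0, axis=1)
    log_s = np.log(np.where(flat > 0, flat, 1.0))

    # OLS of log-signal on TE, vectorised over voxels.
    te_c = tes - tes.mean()
    denom = float(np.sum(te_c**2))
    slope = log_s @ te_c / denom
    intercept = log_s.mean(axis=1) - slope * tes.mean()

    fitted = intercept[:, None] + np.outer(slope, tes)
    ss_res = np.sum((log_s - fitted) ** 2, axis=1)
    ss_tot = np.sum((log_s - log_s.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    r2 = np.clip(np.nan_to_num(r2), 0.0, 1.0)

    with np.errstate(divide="ignore"):
        t2 = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), np.inf)
    t2 = np.clip(t2, lo, hi)

    t2[~valid] = hi
    r2[~valid] = 0.0
    s0 = np.exp(intercept)
    s0[~valid] = 0.0

    return RelaxometryMaps(
        s0=s0.reshape(grid),
        t2star=t2.reshape(grid),
        fit_quality=r2.reshape(grid),
    )


def weight_profile(te, t2star):
    """BOLD-sensitivity weight ``(TE/T2*) exp(-TE/T2*)``.

    Vectorised over either argument.  Maximal (value 1/e) at ``TE == T2*``.
    """
    te = np.asarray(te, dtype=float)
    t2star = np.asarray(t2star, dtype=float)
    if np.any(te <= 0) or np.any(t2star <= 0):
        raise ValueError("te and t2star must be positive")
    ratio = te / t2star
    out = ratio * np.exp(-ratio)
    return out if out.ndim else float(out)


def combine_weighted(
    echoes: list[EchoSeries],
    maps: RelaxometryMaps,
    normalize: bool = True,
) -> CombinedSeries:
    """Fuse echoes into one series with T2*-derived weights.

    Per voxel and TR the output is ``sum_n S(TR, TE_n) * w_n`` with
    ``w_n = (TE_n/T2*) exp(-TE_n/T2*)``; weights are static over time.
    With ``normalize`` (default) the sum is divided by ``sum_n w_n`` so a
    spatially uniform signal is preserved exactly and output stays in
    signal units; ``normalize=False`` gives the literal weighted sum.
    """
    check_aligned(echoes) if len(echoes) > 1 else None
    mask = echoes[0].mask
    t2 = np.asarray(maps.t2star, dtype=float)
    if t2.shape != echoes[0].grid_shape:
        raise ValueError("T2* map grid does not match echo grid")
    if np.any(t2[mask] <= 0):
        raise ValueError("non-positive T2* inside mask")

    safe_t2 = np.where(t2 > 0, t2, 1.0)
    weights = [
        (e.te / safe_t2) * np.exp(-e.te / safe_t2) for e in echoes
    ]
    wsum = np.sum(weights, axis=0)
    out = np.zeros_like(echoes[0].data)
    for e, w in zip(echoes, weights):
        out += e.data * w[..., None]
    if normalize:
        safe_wsum = np.where(wsum > 0, wsum, 1.0)
        out /= safe_wsum[..., None]

    return CombinedSeries(
        data=out,
        tr=echoes[0].tr,
        mask=mask,
        affine=echoes[0].affine,
        method_tag="weighted",
        provenance={
            "te_list_ms": [e.te for e in echoes],
            "normalized": bool(normalize),
            "t2star_source": "log-linear fit of time-mean signal",
        },
    )


def extract_single_echo(
    echoes: list[EchoSeries], te: float, tol_ms: float = 0.5
) -> CombinedSeries:
    """Pass-through copy of the echo whose TE matches ``te`` within ``tol_ms``."""
    tes = np.array([e.te for e in echoes])
    idx = int(np.argmin(np.abs(tes - te)))
    if abs(tes[idx] - te) > tol_ms:
        raise ValueError(
            f"no echo within {tol_ms} ms of TE={te} ms; available TEs: {list(tes)}"
        )
    e = echoes[idx]
    return CombinedSeries(
        data=e.data.copy(),
        tr=e.tr,
        mask=e.mask,
        affine=e.affine,
        method_tag=f"single_echo({e.te})",
        provenance={"te_ms": e.te},
    )
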