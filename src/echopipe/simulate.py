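"""Synthetic multi-echo flanker-task fMRI sessions with known ground truth.

The generator emulates a 3 T multi-echo EPI protocol: three echoes per
volume at TE = 13.82 / 35.35 / 56.89 ms, TR = 2300 ms, 185 volumes
(7 min 5.5 s), during an event-related attention-network (flanker) task
of 120 trials, two-thirds of them preceded by a warning cue, with
congruent/incongruent flankers counterbalanced 50/50 and exponentially
jittered inter-trial intervals on [0, 7360] ms with mean 900 ms.

The voxel signal model is mono-exponential decay with a BOLD effect
expressed as a fractional change in the relaxation rate R2* = 1/T2*:

    S_n(v, t) = S0(v) * (1 + physio(v, t))
                * exp(-TE_n / T2*(v)) * (1 + a(v) x(t)) ** (TE_n / T2*(v))
                + thermal noise,

so that the fractional signal change equals ``a(v) x(t)`` exactly at
TE = T2* and scales approximately linearly with TE — the property that
makes T2*-weighted echo combination worthwhile.  ``x(t)`` is the
HRF-convolved trial train normalized to unit isolated-event peak.
Cardiac and respiratory cycles enter as quasi-periodic, harmonically
rich fractional S0 modulations with smooth per-voxel coupling and
arrival-phase fields; the same oscillators are emitted as densely
sampled logs so the RETROICOR stage can be exercised closed-loop.
Rigid-body motion is emitted as a parameter trace only (volumes are not
resampled): frame-wise displacement QC needs nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .firstlevel import _convolve_events
from .physio import PhysioTrace
from .relaxometry import EchoSeries

__all__ = [
    "AcquisitionSpec",
    "TaskDesign",
    "SimulationTruth",
    "SimulatedSession",
    "GROUP_PROFILES",
    "n_volumes_for_duration",
    "iti_rate_for_mean",
    "sample_itis",
    "build_trial_schedule",
    "simulate_behavior",
    "default_truth",
    "render_echoes",
    "simulate_session",
    "removable_noise_session",
]

PROTOCOL_TE_MS = (13.82, 35.35, 56.89)
PROTOCOL_TR_MS = 2300.0
PROTOCOL_N_VOLUMES = 185
PHYSIO_SAMPLING_HZ = 50.0
#: correlation time (s) of spontaneous heart-rate / breathing-period drift
FREQ_MODULATION_TAU_S = 2.5

#: Behavioral profiles per group: correct-trial reaction time mean/SD (ms)
#: per congruency condition, and overall accuracy.
GROUP_PROFILES = {
    "HYA": {"congruent": (456.6, 39.0), "incongruent": (517.9, 46.2), "accuracy": 0.986},
    "HOA": {"congruent": (600.7, 71.0), "incongruent": (668.9, 71.3), "accuracy": 0.988},
    "WMH": {"congruent": (657.8, 83.2), "incongruent": (738.8, 86.7), "accuracy": 0.983},
}


def n_volumes_for_duration(duration_s: float, tr_ms: float) -> int:
    """Number of complete volumes acquired in ``duration_s`` at the given TR."""
    return int(np.floor(duration_s * 1000.0 / tr_ms + 1e-9))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Multi-echo EPI geometry and timing."""

    te_list: tuple[float, ...] = PROTOCOL_TE_MS
    tr: float = PROTOCOL_TR_MS
    n_volumes: int = PROTOCOL_N_VOLUMES
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_size: tuple[float, float, float] = (2.88, 2.88, 4.0)

    def __post_init__(self) -> None:
        tes = tuple(self.te_list)
        if any(te <= 0 for te in tes) or any(
            b <= a for a, b in zip(tes, tes[1:])
        ):
            raise ValueError(f"te_list must be positive and strictly increasing: {tes}")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if any(d < 1 for d in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def frame_times(self) -> np.ndarray:
        """Volume acquisition times, s."""
        return np.arange(self.n_volumes) * self.tr / 1000.0

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size, 1.0])
        return aff


@dataclass(frozen=True)
class TaskDesign:
    """Event-related flanker task structure.

    Trial timeline (ms from trial onset): fixation cross at 0, warning cue
    (cued trials) for ``cue_duration_ms``, flankers + target at
    ``target_onset_ms`` for ``target_duration_ms``, then
    ``post_target_ms`` of fixation; the inter-trial interval follows.
    """

    n_trials: int = 120
    cue_fraction: float = 2.0 / 3.0
    cue_duration_ms: float = 400.0
    target_onset_ms: float = 550.0
    target_duration_ms: float = 1550.0
    post_target_ms: float = 660.0
    iti_max_ms: float = 7360.0
    iti_mean_ms: float = 900.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cue_fraction <= 1.0:
            raise ValueError("cue_fraction must lie in [0, 1]")
        for name in ("cue_duration_ms", "target_onset_ms", "target_duration_ms",
                     "post_target_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iti_mean_ms < 0 or self.iti_max_ms < 0:
            raise ValueError("ITI parameters must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def trial_duration_ms(self) -> float:
        return self.target_onset_ms + self.target_duration_ms + self.post_target_ms


def iti_rate_for_mean(mean_ms: float, upper_ms: float) -> float:
    """Rate of an exponential truncated to [0, upper] whose mean is ``mean_ms``.

    The truncated mean ``1/lam - upper / (exp(lam*upper) - 1)`` is solved
    for ``lam`` numerically; it must be below ``upper/2`` (the uniform
    limit) for a solution to exist.
    """
    if not 0 < mean_ms < upper_ms / 2.0:
        raise ValueError(
            f"truncated-exponential mean must lie in (0, {upper_ms / 2}), got {mean_ms}"
        )

    def gap(lam: float) -> float:
        lu = lam * upper_ms
        tail = upper_ms / np.expm1(lu) if lu < 700 else 0.0
        return 1.0 / lam - tail - mean_ms

    return optimize.brentq(gap, 1e-8, 1.0, xtol=1e-14)


def sample_itis(n: int, design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-trial intervals (ms) from the truncated exponential."""
    if n == 0:
        return np.empty(0)
    if design.iti_mean_ms == 0:
        return np.zeros(n)
    lam = iti_rate_for_mean(design.iti_mean_ms, design.iti_max_ms)
    u = rng.random(n)
    return -np.log1p(-u * (-np.expm1(-lam * design.iti_max_ms))) / lam


def build_trial_schedule(
    design: TaskDesign,
    seed: int,
    run_duration_s: float | None = None,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Generate a trial table: onset (s), condition, cue.

    Conditions are split 50/50 congruent/incongruent and the cued fraction
    is counterbalanced within condition.  ITIs are drawn from the
    truncated exponential; when ``run_duration_s`` is given, whole ITI
    vectors are redrawn until the realized schedule fits the run (the
    stated mean ITI slightly overbooks the stated run length, so the
    realized mean ITI conditional on fitting is somewhat shorter).
    """
    rng = np.random.default_rng(seed)
    n = design.n_trials
    trial_s = design.trial_duration_ms / 1000.0

    if run_duration_s is not None:
        min_needed = n * trial_s
        if min_needed > run_duration_s:
            raise ValueError(
                f"schedule needs at least {min_needed:.1f} s but only "
                f"{run_duration_s:.1f} s are available"
            )

    for _ in range(max_tries):
        itis_s = sample_itis(n - 1, design, rng) / 1000.0
        onsets = np.concatenate([[0.0], np.cumsum(trial_s + itis_s)])
        total = onsets[-1] + trial_s
        if run_duration_s is None or total <= run_duration_s:
            break
    else:
        raise ValueError(
            f"could not fit {n} trials (needed ~{total:.1f} s) into "
            f"{run_duration_s:.1f} s after {max_tries} draws"
        )

    n_half = n // 2
    conditions = np.array(
        ["congruent"] * n_half + ["incongruent"] * (n - n_half), dtype=object
    )
    cue = np.empty(n, dtype=object)
    for cond in ("congruent", "incongruent"):
        idx = np.where(conditions == cond)[0]
        n_cued = int(round(design.cue_fraction * len(idx)))
        flags = np.array(["cued"] * n_cued + ["uncued"] * (len(idx) - n_cued),
                         dtype=object)
        rng.shuffle(flags)
        cue[idx] = flags
    order = rng.permutation(n)
    conditions = conditions[order]
    cue = cue[order]

    return pd.DataFrame(
        {
            "onset": onsets,
            "condition": conditions,
            "cue": cue,
        }
    )


def simulate_behavior(
    table: pd.DataFrame,
    group_profile: dict,
    accuracy: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill reaction times and correctness into a trial table.

    RTs are Gaussian per congruency condition, truncated to the response
    window (0, target duration]; correctness is Bernoulli.
    ``group_profile`` maps condition -> (mean ms, sd ms) and may carry an
    ``accuracy`` key (overridden by the explicit argument).
    """
    if accuracy is None:
        accuracy = float(group_profile.get("accuracy", 1.0))
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    rt = np.empty(len(out))
    upper = 1550.0
    for cond in ("congruent", "incongruent"):
        sel = out["condition"] == cond
        if not sel.any():
            continue
        mean, sd = group_profile[cond]
        if sd < 0:
            raise ValueError("RT standard deviation must be non-negative")
        if sd == 0:
            rt[sel.to_numpy()] = mean
        else:
            a, b = (0.0 - mean) / sd, (upper - mean) / sd
            rt[sel.to_numpy()] = stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=int(sel.sum()), random_state=rng
            )
    out["rt"] = rt
    out["correct"] = rng.random(len(out)) < accuracy
    return out


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one simulated session."""

    s0_map: np.ndarray
    t2star_map: np.ndarray
    activation_map: dict[str, np.ndarray]
    cardiac_freq: float = 1.0
    resp_freq: float = 0.25
    cardiac_freq_sd: float = 0.04
    resp_freq_sd: float = 0.15
    cardiac_task_entrain: float = 0.0
    resp_task_entrain: float = 0.0
    cardiac_harmonic: float = 0.5
    resp_harmonic: float = 0.5
    cardiac_drift: float = 0.05
    resp_drift: float = 0.0
    physio_amplitude: float = 0.01
    thermal_sd: float = 5.0
    structured_sd: float = 0.005
    structured_rho: float = 0.0
    motion_trace: np.ndarray | None = None
    mask: np.ndarray | None = None
    cardiac_weight: np.ndarray | None = None
    resp_weight: np.ndarray | None = None
    cardiac_phase_offset: np.ndarray | None = None
    resp_phase_offset: np.ndarray | None = None
    seed: int = 0


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Low-frequency random spatial field in [-scale, scale], roughly."""
    from scipy import ndimage

    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=2.0, mode="reflect")
    denom = np.abs(smooth).max() or 1.0
    return scale * smooth / denom


def default_truth(
    acq: AcquisitionSpec,
    seed: int = 0,
    activation: float = 0.01,
    physio_amplitude: float = 0.01,
    thermal_sd: float = 5.0,
    structured_sd: float = 0.005,
    structured_rho: float = 0.0,
    cardiac_freq: float = 1.0,
    resp_freq: float = 0.25,
    cardiac_freq_sd: float = 0.04,
    resp_freq_sd: float = 0.15,
    cardiac_task_entrain: float = 0.0,
    resp_task_entrain: float = 0.0,
    cardiac_harmonic: float = 0.5,
    resp_harmonic: float = 0.5,
    cardiac_drift: float = 0.05,
    resp_drift: float = 0.0,
    cardiac_coupling: float = 1.0,
    resp_coupling: float = 1.0,
    t2star_ms: float | None = None,
    motion_step_mm: float = 0.02,
    motion_step_rad: float = 2e-4,
) -> SimulationTruth:
    """Construct a plausible ground truth on the acquisition grid.

    An ellipsoidal "brain" of baseline signal 1000 (with 10% smooth
    spatial gain variation) sits in the grid; T2* is 45 ms with smooth
    +/-8 ms structure unless a constant ``t2star_ms`` is requested.  The
    activation region is a central sphere carrying fractional amplitude
    ``activation`` for both congruency conditions.  Motion is a Gaussian
    random walk in all six rigid-body parameters.
    """
    rng = np.random.default_rng(seed)
    shape = acq.grid_shape
    center = (np.array(shape) - 1) / 2.0
    coords = np.indices(shape).astype(float)
    semi = np.maximum(np.array(shape) * 0.45, 1.0)
    dist2 = sum(
        ((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3)
    )
    brain = dist2 <= 1.0

    s0 = np.where(brain, 1000.0 * (1.0 + _smooth_field(rng, shape, 0.10)), 0.0)
    if t2star_ms is None:
        t2 = np.clip(45.0 + _smooth_field(rng, shape, 8.0), 20.0, 80.0)
    else:
        t2 = np.full(shape, float(t2star_ms))

    radius_vox = max(min(shape) / 4.0, 1.5)
    act_region = (sum((coords[i] - center[i]) ** 2 for i in range(3))
                  <= radius_vox**2) & brain
    act = np.where(act_region, float(activation), 0.0)
    activation_map = {"congruent": act.copy(), "incongruent": act.copy()}

    motion = np.cumsum(
        rng.normal(
            0.0,
            [motion_step_mm] * 3 + [motion_step_rad] * 3,
            size=(acq.n_volumes, 6),
        ),
        axis=0,
    )

    def phase_field() -> np.ndarray:
        # smooth spatial field of physiological arrival phases covering the
        # full circle (pulse-wave/breathing coupling varies across the brain)
        g1 = _smooth_field(rng, shape, 1.0)
        g2 = _smooth_field(rng, shape, 1.0)
        return np.arctan2(g2, g1)

    def weight_field(scale: float = 1.0) -> np.ndarray:
        # smooth non-negative coupling strength, mean ~scale inside the brain
        return np.where(
            brain, scale * np.abs(1.0 + _smooth_field(rng, shape, 0.8)), 0.0
        )

    return SimulationTruth(
        s0_map=s0,
        t2star_map=t2,
        activation_map=activation_map,
        cardiac_freq=cardiac_freq,
        resp_freq=resp_freq,
        cardiac_freq_sd=cardiac_freq_sd,
        resp_freq_sd=resp_freq_sd,
        cardiac_task_entrain=cardiac_task_entrain,
        resp_task_entrain=resp_task_entrain,
        cardiac_harmonic=cardiac_harmonic,
        resp_harmonic=resp_harmonic,
        cardiac_drift=cardiac_drift,
        resp_drift=resp_drift,
        physio_amplitude=physio_amplitude,
        thermal_sd=thermal_sd,
        structured_sd=structured_sd,
        structured_rho=structured_rho,
        motion_trace=motion,
        mask=brain,
        cardiac_weight=weight_field(cardiac_coupling),
        resp_weight=weight_field(resp_coupling),
        cardiac_phase_offset=phase_field(),
        resp_phase_offset=phase_field(),
        seed=seed,
    )


@dataclass
class SimulatedSession:
    """Everything one simulated subject produces, plus the generating truth."""

    echoes: list[EchoSeries]
    events: pd.DataFrame
    cardiac_trace: PhysioTrace
    respiratory_trace: PhysioTrace
    motion_trace: np.ndarray
    truth: SimulationTruth
    acq: AcquisitionSpec
    cardiac_phase_true: np.ndarray = field(default=None)  # type: ignore[assignment]
    respiratory_phase_true: np.ndarray = field(default=None)  # type: ignore[assignment]


def render_echoes(
    truth: SimulationTruth,
    acq: AcquisitionSpec,
    events: pd.DataFrame,
) -> SimulatedSession:
    """Render the multi-echo volumes and physiological logs for a session.

    Deterministic given ``truth.seed``.  See the module docstring for the
    signal model.
    """
    for cond, amap in truth.activation_map.items():
        if amap.shape != acq.grid_shape:
            raise ValueError(f"activation map for {cond} does not match grid")
    mask = truth.mask if truth.mask is not None else truth.s0_map > 0
    if np.any(truth.t2star_map[mask] <= 0):
        raise ValueError("non-positive T2* inside mask")

    rng = np.random.default_rng(truth.seed)
    frame_times = acq.frame_times
    shape = acq.grid_shape

    # task modulation, unit isolated-event peak per condition
    target_dur_s = 1.55
    m = np.zeros(shape + (acq.n_volumes,))
    for cond, amap in truth.activation_map.items():
        sel = events[events["condition"] == cond] if len(events) else events
        if len(sel) == 0:
            continue
        reg, peak = _convolve_events(
            sel["onset"].to_numpy(float) + 0.55, target_dur_s, frame_times
        )
        m += amap[..., None] * (reg / peak)[None, None, None, :]
    if np.any(1.0 + m <= 0):
        raise ValueError("activation modulation drives signal non-positive")

    # physiological oscillators: quasi-periodic phase trajectories with two
    # physiological sources of irregularity — slow spontaneous
    # instantaneous-frequency modulation (heart-rate / breathing-period
    # variability) and task entrainment (breathing and heart rate speed up
    # during stimulus processing, the classic source of task-correlated
    # physiological artifact).  Both are emitted densely logged and sampled
    # at frame times.  With zero frequency SD and zero entrainment the
    # oscillator is strictly regular.
    from scipy import ndimage as _ndi

    t_log = np.arange(0.0, acq.duration_s + 1.0, 1.0 / PHYSIO_SAMPLING_HZ)

    # stimulus drive for entrainment: unit boxcar over each target
    # presentation, lightly smoothed (autonomic responses are sluggish)
    stim = np.zeros(len(t_log))
    if len(events):
        for onset in events["onset"].to_numpy(float):
            i0 = int(round((onset + 0.55) * PHYSIO_SAMPLING_HZ))
            i1 = int(round((onset + 0.55 + target_dur_s) * PHYSIO_SAMPLING_HZ))
            stim[i0:max(i1, i0 + 1)] = 1.0
        stim = _ndi.gaussian_filter1d(stim, sigma=1.0 * PHYSIO_SAMPLING_HZ,
                                      mode="reflect")
        stim -= stim.mean()

    def oscillator(f0: float, frac_sd: float, entrain: float,
                   drift: float = 0.0) -> np.ndarray:
        phi0 = rng.uniform(0, 2 * np.pi)
        mod = np.zeros(len(t_log))
        if drift != 0.0:
            # slow monotonic rate drift across the run (arousal decline),
            # sign randomized per subject; spans +/-drift fractionally
            sgn = rng.choice([-1.0, 1.0])
            mod = mod + sgn * drift * (2.0 * t_log / t_log[-1] - 1.0)
        if frac_sd > 0:
            slow = _ndi.gaussian_filter1d(
                rng.standard_normal(len(t_log)),
                sigma=FREQ_MODULATION_TAU_S * PHYSIO_SAMPLING_HZ, mode="reflect",
            )
            mod = mod + frac_sd * slow / (slow.std() or 1.0)
        if entrain > 0:
            mod = mod + entrain * stim
        inst_f = np.clip(f0 * (1.0 + mod), 0.2 * f0, 3.0 * f0)
        mid = 0.5 * (inst_f[1:] + inst_f[:-1]) * np.diff(t_log)
        return phi0 + 2 * np.pi * np.concatenate([[0.0], np.cumsum(mid)])

    phase_c_log = oscillator(
        truth.cardiac_freq, truth.cardiac_freq_sd, truth.cardiac_task_entrain,
        truth.cardiac_drift,
    )
    phase_r_log = oscillator(
        truth.resp_freq, truth.resp_freq_sd, truth.resp_task_entrain,
        truth.resp_drift,
    )
    cardiac_trace = PhysioTrace(
        time=t_log, value=np.sin(phase_c_log),
        modality="cardiac", sampling_rate=PHYSIO_SAMPLING_HZ,
    )
    resp_trace = PhysioTrace(
        time=t_log, value=np.sin(phase_r_log),
        modality="respiratory", sampling_rate=PHYSIO_SAMPLING_HZ,
    )
    wc = truth.cardiac_weight if truth.cardiac_weight is not None else mask.astype(float)
    wr = truth.resp_weight if truth.resp_weight is not None else mask.astype(float)
    psi_c = (
        truth.cardiac_phase_offset
        if truth.cardiac_phase_offset is not None
        else np.zeros(shape)
    )
    psi_r = (
        truth.resp_phase_offset
        if truth.resp_phase_offset is not None
        else np.zeros(shape)
    )
    phase_c_vol = np.interp(frame_times, t_log, phase_c_log)
    phase_r_vol = np.interp(frame_times, t_log, phase_r_log)

    def cycle_waveform(phase_vol, psi, harmonic):
        # non-sinusoidal cycle-locked artifact: fundamental plus second
        # harmonic, delayed per voxel by psi; unit RMS-equivalent scaling
        arg = phase_vol[None, None, None, :] + psi[..., None]
        w = np.sin(arg)
        if harmonic > 0:
            w = (w + harmonic * np.sin(2 * arg)) / np.sqrt(1 + harmonic**2)
        return w

    physio = truth.physio_amplitude * (
        wc[..., None] * cycle_waveform(phase_c_vol, psi_c, truth.cardiac_harmonic)
        + wr[..., None] * cycle_waveform(phase_r_vol, psi_r, truth.resp_harmonic)
    )

    # structured (non-physiological) noise: spatially smooth AR(1) fractional
    # fluctuations shared by all echoes — the noise floor RETROICOR cannot
    # and should not remove
    struct = np.zeros(shape + (acq.n_volumes,))
    if truth.structured_sd > 0:
        from scipy import ndimage

        white = rng.standard_normal(shape + (acq.n_volumes,))
        smooth = ndimage.gaussian_filter(
            white, sigma=(1.5, 1.5, 1.5, 0), mode="reflect"
        )
        rho = truth.structured_rho
        ar = np.empty_like(smooth)
        ar[..., 0] = smooth[..., 0]
        for t_i in range(1, acq.n_volumes):
            ar[..., t_i] = rho * ar[..., t_i - 1] + smooth[..., t_i]
        sd = ar.std(axis=-1, keepdims=True)
        ar /= np.where(sd > 0, sd, 1.0)
        struct = truth.structured_sd * ar

    # phase conventions: cardiac phase 0 at trace peaks; respiratory phase
    # pi at maximal amplitude (histogram-equalized convention)
    card_phase_true = (phase_c_vol - np.pi / 2) % (2 * np.pi)
    resp_phase_true = (phase_r_vol + np.pi / 2) % (2 * np.pi)

    safe_t2 = np.where(truth.t2star_map > 0, truth.t2star_map, 1.0)
    echoes = []
    for te in acq.te_list:
        ratio = (te / safe_t2)[..., None]
        signal = (
            truth.s0_map[..., None]
            * (1.0 + physio + struct)
            * np.exp(-ratio)
            * np.power(1.0 + m, ratio)
        )
        if truth.thermal_sd > 0:
            signal = signal + rng.normal(0.0, truth.thermal_sd, signal.shape)
        echoes.append(
            EchoSeries(
                data=signal, te=te, tr=acq.tr, mask=mask, affine=acq.affine
            )
        )

    motion = (
        truth.motion_trace
        if truth.motion_trace is not None
        else np.zeros((acq.n_volumes, 6))
    )
    if motion.shape[0] != acq.n_volumes:
        raise ValueError("motion trace length must equal n_volumes")

    return SimulatedSession(
        echoes=echoes,
        events=events,
        cardiac_trace=cardiac_trace,
        respiratory_trace=resp_trace,
        motion_trace=motion,
        truth=truth,
        acq=acq,
        cardiac_phase_true=card_phase_true,
        respiratory_phase_true=resp_phase_true,
    )


#: Per-subject physiological rate ranges (Hz) used by ``simulate_session``:
#: resting heart rates of roughly 60-84 bpm and breathing at 12-23
#: breaths/min.  Individual rates determine where each subject's cardiac
#: and respiratory cycles alias under TR sampling — across such a
#: population the aliases cover the whole sampled band, including the
#: low frequencies where the task regressor lives.
CARDIAC_RATE_RANGE_HZ = (1.0, 1.4)
RESP_RATE_RANGE_HZ = (0.20, 0.38)


def simulate_session(
    acq: AcquisitionSpec | None = None,
    design: TaskDesign | None = None,
    group: str = "HOA",
    seed: int = 0,
    truth: SimulationTruth | None = None,
    vary_physio_rates: bool = True,
    **truth_kwargs,
) -> SimulatedSession:
    """One-call convenience: schedule, behavior, truth, rendered echoes.

    Sub-seeds for schedule, behavior and rendering are derived from
    ``seed`` so one integer reproduces the whole session.  Unless
    explicit rates are passed (or ``vary_physio_rates`` is off), each
    subject receives their own baseline heart and breathing rate drawn
    from the population ranges above.
    """
    acq = acq or AcquisitionSpec()
    design = design or TaskDesign()
    ss = np.random.SeedSequence(seed)
    s_sched, s_beh, s_render, s_rate = (int(s) for s in ss.generate_state(4) % (2**31))
    events = build_trial_schedule(design, s_sched, run_duration_s=acq.duration_s)
    events = simulate_behavior(events, GROUP_PROFILES[group], seed=s_beh)
    if truth is None:
        if vary_physio_rates:
            rate_rng = np.random.default_rng(s_rate)
            truth_kwargs.setdefault(
                "cardiac_freq", float(rate_rng.uniform(*CARDIAC_RATE_RANGE_HZ))
            )
            truth_kwargs.setdefault(
                "resp_freq", float(rate_rng.uniform(*RESP_RATE_RANGE_HZ))
            )
        truth = default_truth(acq, seed=s_render, **truth_kwargs)
    return render_echoes(truth, acq, events)


def removable_noise_session(
    seed: int,
    acq: AcquisitionSpec | None = None,
    design: TaskDesign | None = None,
) -> SimulatedSession:
    """A subject from the method-comparison study population.

    This scenario realizes the premise of the voxel-wise Z-map comparison:
    the uncorrected single-echo reference carries noise that the denoising
    stages can actually remove.  Thermal noise (removable by T2*-weighted
    echo averaging) is set to a noisy-acquisition level (voxel tSNR ~25
    at the middle echo), and the cardiac artifact (removable by RETROICOR)
    is placed where it damages the task statistics: resting heart rates
    are drawn from 75.4-77.2 bpm, just below three cycles per two TRs at
    TR = 2.3 s, so the aliased cardiac power falls at 0.03-0.05 Hz — the
    band where the HRF-convolved trial regressor lives.  A small rate
    drift and jitter spread the aliased line over the neighbouring
    frequency bins.  Respiration (21.9-22.8 breaths/min, aliasing to
    0.055-0.07 Hz) couples at a third of the cardiac strength.

    Under these conditions the Z maps of both denoised arms regress on the
    raw single-echo Z map with slope below 1 for the vast majority of
    subjects — the method-comparison signature of noise removal.
    """
    acq = acq or AcquisitionSpec(grid_shape=(18, 18, 12))
    design = design or TaskDesign()
    rate_rng = np.random.default_rng(
        int(np.random.SeedSequence([seed, 7]).generate_state(1)[0] % (2**31))
    )
    return simulate_session(
        acq=acq,
        design=design,
        seed=seed,
        vary_physio_rates=False,
        cardiac_freq=float(rate_rng.uniform(1.257, 1.287)),
        resp_freq=float(rate_rng.uniform(0.365, 0.38)),
        physio_amplitude=0.007,
        thermal_sd=16.0,
        structured_sd=0.01,
        cardiac_freq_sd=0.003,
        cardiac_drift=0.01,
        resp_freq_sd=0.03,
        resp_drift=0.01,
        resp_coupling=0.3,
    )
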