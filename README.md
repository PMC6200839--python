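# echopipe

Multi-echo BOLD fMRI analysis for event-related task studies: T2*
relaxometry and BOLD-weighted echo combination, RETROICOR physiological
noise regression, a FEAT-style first-level GLM, and the voxel-wise
method-comparison and group-statistics framework — together with a
synthetic multi-echo session generator with known ground truth, so the
whole chain is testable end to end.

## Who this is for

Researchers analyzing multi-echo echo-planar BOLD data from event-related
designs (the bundled task model is a flanker / attention-network test:
congruent vs incongruent trials, two-thirds cued, jittered inter-trial
intervals), and anyone who wants a self-contained, fully seeded testbed
for multi-echo denoising claims.

## The core model

A multi-echo acquisition samples the decay S(TE) = S0·exp(−TE/T2*) at
several echo times per volume. The pipeline estimates per-voxel S0 and
T2* by a log-linear fit and fuses the echoes with the BOLD-sensitivity
weights

    w_n = (TE_n / T2*) · exp(−TE_n / T2*),

which peak at TE = T2*. Cardiac and respiratory noise is alternatively
removed from a single-echo series by RETROICOR: order-2 Fourier
expansions of the cardiac phase (linear between pulse peaks) and
respiratory phase (amplitude histogram equalization) regressed out of
every voxel. Each processed series goes through the same first level —
6-mm Gaussian smoothing, 50-s discrete-cosine high-pass (applied to data
and design), double-gamma HRF regressors per condition × cue cell
(correct trials only), voxel-wise OLS with contrast t → Z maps — and the
denoised Z maps are regressed voxel-by-voxel on the uncorrected
single-echo Z map: slope 1 means equivalent statistics, slope < 1 means
the denoised analysis yields systematically lower Z, the signature of
removed noise. Group stages provide the slope/R² test battery
(one-sample t vs 1, Welch t, ANOVA + Tukey), voxel-wise group contrasts
with a reaction-time covariate, permutation cluster-extent inference
(Z > 2.32, 26-connectivity, sign-flipping max-cluster-size null), and
behavior/BOLD Pearson correlations.

See `docs/methods.md` for the full model description, parameter
defaults, and design rationale.

## Worked example

One simulated subject from the method-comparison population, processed
through all three arms:

```python
import numpy as np
from echopipe.simulate import removable_noise_session
from echopipe import relaxometry as rx, physio as ph, firstlevel as fl, compare as cmp

sess = removable_noise_session(seed=7)
acq = sess.acq

maps = rx.fit_t2star(sess.echoes)
weighted = rx.combine_weighted(sess.echoes, maps)
single = rx.extract_single_echo(sess.echoes, 35.35)
print(f"median fitted T2* in brain: {np.median(maps.t2star[sess.echoes[0].mask]):.1f} ms")

phases = ph.phase_assignment(sess.cardiac_trace, sess.respiratory_trace,
                             single.frame_times)
cleaned = ph.remove_physio(single, ph.retroicor_regressors(phases, order=2))

design = fl.build_design(sess.events, tr_ms=acq.tr, n_volumes=acq.n_volumes)
design = fl.highpass_design(design, acq.tr, 50.0)
zmaps = {}
for name, series in [("weighted", weighted), ("retroicor", cleaned),
                     ("single_echo", single)]:
    pre = fl.highpass_temporal(fl.smooth_spatial(series, 6.0), 50.0)
    zmaps[name] = fl.fit_glm(pre, design).z["all_vs_baseline"]

mask = sess.echoes[0].mask
for name in ("weighted", "retroicor"):
    slope, icept, r2, n = cmp.zmap_regression(zmaps[name], zmaps["single_echo"], mask)
    print(f"{name:>10} vs single echo: slope {slope:.3f}, R^2 {r2:.3f} over {n} voxels")
```

prints

```
median fitted T2* in brain: 45.4 ms
  weighted vs single echo: slope 0.830, R^2 0.783 over 1488 voxels
 retroicor vs single echo: slope 0.942, R^2 0.930 over 1488 voxels
```

The fitted T2* recovers the simulated ~45 ms tissue value. Both denoised
arms regress on the raw single-echo Z map with slope below one — each
removes noise that inflated the raw statistics — and RETROICOR shares
more variance with the single-echo analysis (higher R²) than the
weighted combination, which changes the data more thoroughly.

## Command line

A thin CLI wraps the library: `echopipe simulate` writes a synthetic
session (NIfTI echoes + sidecars, FSL-style event files, physio logs,
motion trace); `combine`, `retroicor`, `firstlevel`, `compare`,
`grouplevel` run the individual stages on files; `echopipe run` drives a
multi-subject manifest through the whole pipeline with frame-wise
displacement QC (mean FD < 0.4 mm) and writes the method-comparison
table and a provenance log. All stages accept `--config <yaml>`;
unknown configuration keys are rejected.

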