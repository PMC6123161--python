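# irv4d

Evaluation of automatically propagated organ-at-risk (OAR) contours on
respiratory-correlated 4D MRI, and construction of internal organ-at-risk
volumes (IRVs) that account for intra-fraction organ motion.

Radiotherapy planning limits dose to nearby normal organs (lungs, heart,
liver, stomach), but those organs move with breathing.  Given a 10-bin 4D MR
series — one 3-D volume per respiratory amplitude bin, phase 0 = full
exhalation — this package:

1. **propagates contours** from the full-exhalation phase to every other
   phase with free-form intensity-based deformable registration (DIR),
   minimizing
   `E(u) = ∫ [I_B(x+u) − I_A(x)]² dx + λ Σᵢ ∫ |∇uᵢ|² dx` (λ = 0.1)
   via a demons-style multi-resolution solver whose steps are accepted only
   if the energy does not increase;
2. **estimates a reference ground truth** from multiple contour sets with
   binary STAPLE (EM over per-rater sensitivity p and specificity q) and
   thresholds the posterior at 0.95 — the S95 consensus;
3. **scores contours against S95** with Jaccard = |D∩G|/|D∪G|,
   sensitivity = |D∩G|/|G| and specificity = |D̄∩Ḡ|/|Ḡ| (complement counted
   in a box around D∪G), plus intra-observer volume variation
   %V = SD/mean × 100, inter-observer similarity difference
   %S = 2(S₁−S₂)/(S₁+S₂) × 100, and paired t-tests;
4. **builds IRVs** as the Boolean OR of per-phase contours and reports the
   increase (IRV/V̄ − 1) × 100 over the mean organ volume, along with organ
   COM trajectories and diaphragm dome excursions.

Because this class of volunteer imaging is IRB-protected and not publicly
deposited, the package includes a first-class **synthetic 4D respiratory
phantom** (analytic organs, exact ground-truth deformation fields,
volume-conserving heart/liver/stomach, simulated human raters, and a
bellows-rebinned series with slice mis-binning artifacts) plus a study
orchestrator that reproduces the full evaluation design on synthetic
subjects — navigator vs bellows, manual vs automatic, per-organ statistics.
It also ships CSV transcriptions of the reference study's printed
per-subject tables and recomputes every printed summary cell.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from irv4d import (PhantomConfig, generate_phantom, RegistrationParams,
                   register, warp_mask, jaccard, compute_irv,
                   diaphragm_excursion)

cfg = PhantomConfig(grid_shape=(64, 64, 64), spacing_mm=(2, 2, 3), seed=7)
subject = generate_phantom(cfg)            # 10 bins + ground truth

exhale, inhale = subject.phases[0], subject.phases[-1]
result = register(inhale, exhale, RegistrationParams(
    n_levels=3, iters_per_level=(60, 30, 10), stop_tol=5e-4))
propagated = warp_mask(subject.truths[0].masks["liver"], result.dvf)
truth = subject.truths[-1].masks["liver"]

print(f"energy: {result.energy_trace[0]:.3e} -> {result.energy_trace[-1]:.3e}")
print(f"liver Jaccard, propagated vs truth: {jaccard(propagated, truth):.3f}")
print(f"right diaphragm excursion: "
      f"{diaphragm_excursion(subject.truth_masks('right_lung'), 'right'):.0f} mm")
irv = compute_irv(subject.truth_masks("liver"))
print(f"liver IRV: {irv.irv_volume_mm3/1000:.0f} ml vs mean volume "
      f"{irv.mean_organ_volume_mm3/1000:.0f} ml (+{irv.increase_pct:.1f}%)")
```

prints

```
energy: 1.567e+09 -> 1.291e+09
liver Jaccard, propagated vs truth: 0.977
right diaphragm excursion: 15 mm
liver IRV: 73 ml vs mean volume 52 ml (+40.6%)
```

The registration energy decreases monotonically; the contour propagated from
full exhalation overlaps the full-inhalation truth at Jaccard 0.98; the
measured dome excursion matches the configured 16 mm right-dome amplitude to
within a slice; and sweeping the moving liver over the breathing cycle inflates its
envelope by ~41% over the organ volume — the motion margin the IRV captures.

The full study design (two simulated observers, DIR propagation, STAPLE/S95,
SSS metrics, navigator-vs-bellows arms) runs via

```python
from irv4d import run_study, scaled_study_config
report = run_study(scaled_study_config(n_subjects=5, seed=0))
print(report.summary)                     # per-organ mean/SD of Jaccard etc.
print(report.t_tests_manual_vs_auto)      # paired across subjects
```

or from the shell: `irv4d study --subjects 5 --seed 0 --out out/`.
Other CLI verbs: `simulate`, `register`, `propagate`, `staple`, `metrics`,
`irv`, `verify-tables` (all volumes/masks/fields as NIfTI, configs as YAML).

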