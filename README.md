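# nucleostruct

Quantification of nucleolar structure and dynamics in fluorescence and
electron microscopy, built around three measurement pipelines and a set of
synthetic-data generators with exact ground truth:

1. **FRAP fitting** — the nucleolus is a liquid-like condensate; bleaching
   the whole granular component (GC, marked by NPM1) probes exchange with the
   nucleoplasm, while bleaching half of it probes internal mixing. Whole-FRAP
   recovery is fit with a single exponential
   `F(t) = plateau · (1 − e^(−t/τ))`, and half-FRAP recovery with the
   constrained double exponential
   `F(t) = plateau − A₁·e^(−t/τ₁) − A₂·e^(−t/τ₂)`,
   where τ₂ is **fixed** to the whole-FRAP τ (nucleoplasmic exchange), τ₁ is
   the fast internal-mixing constant, and `A₁ + A₂ = plateau` pins
   `F(0) = 0` on the min–max normalized scale. Percent recovery is
   `100 · plateau`. An increase in τ₁ reports increased GC viscosity.
2. **Immunogold detection** — gold particles of two diameters (12 nm and
   6 nm) are localized in EM images with Laplacian-of-Gaussian filters
   (`σ_px = d / (2√2 · pixel_size)`), large particles first, with exclusion
   zones preventing re-detection at the small scale; detections are masked
   against a nucleolar outline and reported as particles/nm².
3. **Time-lapse morphometry** — per-channel components (UBF and FBL puncta,
   the NPM1 surface) are segmented per nucleus, measured (area, circularity /
   sphericity), tracked over time, summarized as mean ± 95% CI per frame, and
   each cell is classified as *normal*, *condensed* (one round NPM1
   component) or *fragmented* (many dispersed NPM1 puncta — the phenotype of
   a cell that divided without Pol I activity and could not reassemble its
   nucleolus).

Every pipeline is paired with a generator (`nucleostruct.sim`) that produces
the corresponding synthetic observations together with the generating truth,
so parameter recovery, detection fidelity, and classifier accuracy are all
testable without any downloaded data. Intended users: microscopists and
image analysts quantifying nucleolar phase-separation phenotypes.

## Worked example

```python
from nucleostruct.sim import FrapSimParams, simulate_frap_curve
from nucleostruct.frap import normalize_trajectory, fit_whole_frap, fit_half_frap

# whole FRAP: single exchange component, tau = 20 s
whole = FrapSimParams.whole(tau=20.0, plateau=0.9, noise_sd=0.0)
wfit = fit_whole_frap(normalize_trajectory(simulate_frap_curve(whole)))
print(f"tau = {wfit.tau:.3f} s, percent recovery = {wfit.percent_recovery:.1f}%")

# half FRAP: fast mixing (tau1) + exchange, tau2 fixed from the whole fit
half = FrapSimParams(geometry="half", tau1=3.33, tau2=20.0,
                     amp1=0.5, amp2=0.4, plateau=0.9, noise_sd=0.0)
hfit = fit_half_frap(normalize_trajectory(simulate_frap_curve(half)), tau2=wfit.tau)
print(f"tau1 = {hfit.tau1:.3f} s (tau2 fixed at {hfit.tau2_fixed:.3f} s)")
```

prints

```
tau = 20.000 s, percent recovery = 90.0%
tau1 = 3.330 s (tau2 fixed at 20.000 s)
```

i.e. the fitter recovers the generating constants exactly on noiseless
curves: the internal-mixing component (3.33 s) is six-fold faster than
exchange with the nucleoplasm (20 s), the liquid-like signature.

The same works from the shell. Simulating an EM field (30 × 12 nm and
60 × 6 nm particles inside the nucleolar outline, 20 outside) and detecting:

```sh
nucleostruct simulate em --out em --seed 3
nucleostruct gold detect --image em/em_image.tif --mask em/em_mask.tif --out det
# detected 30 x 12nm and 60 x 6nm particles in ROI (7.435e-05 and 1.487e-04 /nm^2)
```

End-to-end configured runs (`nucleostruct run --config cfg.yaml --out out/`)
execute simulate → fit/detect/measure stages in dependency order — whole-FRAP
fits always precede the constrained half-FRAP fits — and write a manifest
with config and output digests for reproducibility.

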