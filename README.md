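# pomscan

Quantitative mapping of particulate organic matter (POM) in
hyperspectral VisNIR/SWIR images of undisturbed soil cores.

Soil organic matter is usually characterised by cutting blocks out of a
profile and running density/ultrasonication fractionation — destructive,
slow, and blind to spatial structure below the block size.  Imaging
spectroscopy of an intact profile face offers a non-destructive
alternative: every 0.25 mm pixel carries a full SWIR spectrum in which
organic matter (cellulose/lignin absorption between 2000 and 2300 nm)
and phyllosilicate minerals (the Al-OH feature at 2204 nm) are
separable.  `pomscan` implements the full analysis chain for such
images, aimed at soil scientists and imaging-spectroscopy researchers:

1. **Calibration** — per-line reflectance against a white reference
   panel, ρ_obj = L_obj / L_ref · ρ_ref, cancelling along-track
   illumination non-uniformity exactly;
2. **Binning & masking** — n-pixel averaging for the √n
   signal-to-noise gain, plus removal of artefact bands;
3. **Unmixing** — fully constrained least squares (a ≥ 0, Σa = 1) on
   five diagnostic bands (2012, 2108, 2228, 2276 nm organic; 2204 nm
   mineral) with the closed-form two-endmember solution
   â = clamp(⟨s − E_min, E_om − E_min⟩/‖E_om − E_min‖², 0, 1);
4. **Segmentation** — connected components of pixels with organic
   abundance > 5% are "SpecPOM" particles, sized in pixels;
5. **Statistics** — line-wise cover depth profiles, per-ROI-block
   metrics, and Pearson correlations against physically fractionated
   carbon stocks (fPOM/oPOM/soPOM/MinRest).

Because no public dataset exists for this kind of study, the package
includes a first-class synthetic scene generator
(`pomscan.synthetic_scene`) producing ground-truthed endmember spectra,
depth-decaying elongated particle fields, rendered radiance cubes with
reference panel, and coupled fraction tables.  Every pipeline stage is
validated against this generator or an independent oracle (exhaustive
simplex search, flood-fill labeling, closed-form correlation design).

## Worked example

```python
import numpy as np
from pomscan import preprocess as pp, synthetic_scene as ss, unmix as ux
from pomscan import particles as pt, profile_stats as psx

cfg = ss.SceneConfig(lines=240, samples=120, seed=3)
truth, lib, cube, panel = ss.simulate_scene(cfg)

calib = pp.calibrate(cube, pp.ReferencePanel(panel, ss.PANEL_RHO))
amap = ux.unmix_image(calib, lib)
pm = pt.label_particles(pt.threshold_abundance(amap, 0.05))

print("true cover     :", round(truth.abundance.mean(), 4))
print("mapped cover   :", round(amap.a_om.mean(), 4))
print("RMSE vs truth  :",
      round(float(np.sqrt(np.mean((amap.a_om - truth.abundance) ** 2))), 4))
print("particles      :", pm.count, "(truth:", truth.n_particles, ")")
```

prints

```
true cover     : 0.0465
mapped cover   : 0.0504
RMSE vs truth  : 0.0079
particles      : 28 (truth: 35 )
```

The per-pixel RMSE of 0.008 at sensor noise σ = 0.005 sits below the
propagated least-squares error σ/‖E_om − E_min‖ ≈ 0.011.  The mapped
cover overshoots the truth by 0.004: the simplex constraint rectifies
noise on POM-free pixels (a clamped estimate cannot go below 0), a
small positive bias that vanishes as σ → 0.  Nearby particles whose
noisy halos touch at the 5% threshold merge into single components
(no watershed splitting — see `docs/methods.md`).

## Analysis drivers

`analysis/01_simulate_scene.py` … `05_profile_statistics.py` run a
complete desk-scale study — four simulated 30 cm profile faces (two
grazed, two ungrazed), calibration, unmixing, segmentation and the
image-vs-lab correlation matrix — writing tables to `results/` and
large regenerable intermediates to `scratch/`.  Run them in order from
the repository root.

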