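# petalign

Maximum-likelihood calibration of PET detector-block alignment from
time-of-flight (TOF) list-mode coincidence data.

Mechanical tolerances leave the detector blocks of a PET scanner a little
off their designed positions and orientations, which misplaces lines of
response and visibly costs resolution in sub-millimetre systems. Given a
*known* tracer distribution (point sources, or a thin tube phantom whose
shape was characterized beforehand), the per-block rigid deviations can be
estimated directly from an ordinary static acquisition — no motion stages,
no manual bookkeeping. `petalign` implements this estimator together with
everything needed to validate it end-to-end on synthetic scanners: a
back-to-back coincidence simulator, fan-sum efficiency estimation, TOF
list-mode OSEM reconstruction, and Procrustes-based evaluation metrics.

## Model

A scanner blueprint fixes block positions `P_d` and orthonormal local axes
`(X_d, Y_d, Z_d)`. The realized geometry is modelled per block as

    P̂_d = P_d + T_d ,   (X̂, Ŷ, Ẑ)_d = R(R_d) · (X, Y, Z)_d

with unknown translations `T ∈ R^{Ndet×3}` (mm) and rotations
`R ∈ R^{Ndet×3}` (degrees about the block's own axes). Crystal voxels map
into global space through a per-block lookup table. The expected count of
a coincidence bin `(λ1, λ2, t)` is

    L(λ1, λ2, t) = s · E_λ1 E_λ2 · e^{−∫A dl} · ∫ K_TOF(x, t) F(x) dl

(tracer `F`, attenuation `A`, per-crystal efficiencies `E`, Gaussian TOF
kernel with FWHM = c·CTR/2, global scale `s`), integrated along lines
between points sampled inside the two crystal voxels. `(T, R)` minimize
the Poisson negative log-likelihood `Σ [L − C·log L]` over bins by
gradient-based optimization with analytic derivatives; the estimate is
compared to a reference only after closed-form rigid Procrustes
registration, since a common rigid motion of scanner-plus-phantom is
unidentifiable. See `docs/methods.md` for the estimation details.

## Worked example

```python
import numpy as np
import petalign as pa

# an 8-block ring scanner with 1 x 2 x 1 mm crystal voxels
bp  = pa.make_cylindrical_blueprint(8, 1, 40.0, (24.0, 10.0, 24.0))
lut = pa.CrystalLUT.regular((24.0, 10.0, 24.0), (24, 5, 24))
tof = pa.TOFModel(ctr_ps=250.0, range_mm=45.0)

# ground truth = blueprint + Gaussian misalignment; simulate coincidences
rng = np.random.default_rng(0)
r, th = np.sqrt(rng.uniform(0, 1, 8)) * 13.0, rng.uniform(0, 2 * np.pi, 8)
centers = np.stack([r * np.cos(th), r * np.sin(th), rng.uniform(-9, 9, 8)], axis=1)
spec  = pa.PhantomSpec.point_sources(centers, radii=0.125)
truth = pa.apply_alignment(bp, pa.perturb_alignment(bp.n_detectors, 1.0, 1.0, rng))
ev    = pa.simulate_events(truth, lut, spec, None, None, tof, 400_000, rng)
hist  = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)

# fit the alignment from the blueprint, knowing only the phantom
model = pa.DetectorAlignmentModel(hist, bp, lut,
                                  pa.voxelize_phantom(spec, 0.3))
res = model.fit(pa.OptimizerConfig(
    iterations=20, batch_size=6000, n_crystal_samples=2,
    lr_translation=0.1, lr_rotation=0.02, lr_schedule="cosine",
    samples_per_voxel=1.0, blur_stages=((1.0, 1.0),),
    polish_iterations=22, polish_batch_size=90000,
    polish_blurs=((0.5, False), (0.5, True), (0.0, True)),
    polish_crystal_samples=2, polish_final_reps=2, seed=0))

print(pa.alignment_errors(bp, truth))    # error of the blueprint init
print(res.errors_vs(truth))              # error of the estimate
```

Output (a few minutes on one CPU core):

```
dT (mm): [0.7355, 0.6779, 0.4880]   dR (deg): [1.413, 1.415, 1.786]
dT (mm): [0.0370, 0.0356, 0.0055]   dR (deg): [0.190, 0.261, 0.209]
```

— the first line is the per-axis mean position/orientation error of the
uncalibrated blueprint against the realized geometry, the second the
Procrustes-aligned error after calibration: sub-millimetre block
misalignments of ~0.5–0.7 mm and ~1.5° recovered to tens of microns and a
fraction of a degree, from nothing but coincidence data and the phantom
description. `res.summary()` prints the per-block parameter table and the
NLL trace.

A command-line interface wraps the same pipeline:

```
petalign experiment --phantom point_sources --events 2000000 --seed 1 --out-dir run1
petalign calibrate --histogram h.csv --geometry g.json --lut l.json \
    --activity F.json --tof-ctr 250 --seed 1 --out result.json
```

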