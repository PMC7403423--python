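# fdot

Frequency-domain diffuse optical tomography (DOT) of the compressed breast,
from raw multi-channel IQ data to an absorption map fused with a digital
breast tomosynthesis (DBT) slice — plus the reader-study statistics used to
evaluate DBT/DOT fusion reading.

## Who this is for

Groups building or evaluating parallel-plate near-infrared breast imagers:
the package implements the full computational chain of a 64-source /
40-detector, 70 MHz frequency-domain system at three wavelengths
(785/808/850 nm), and a digital-phantom simulator that stands in for the
scanner, so every stage can be developed and validated against known ground
truth.

## The model

Photon transport is the frequency-domain diffusion equation

    −∇·κ(r)∇Φ(r,ω) + (μa(r) + iω/c_m) Φ(r,ω) = q₀(r,ω),
    κ = 1/(3(μa + μs′)),

with a Robin boundary condition (photons exit to air and do not return).
The chain is:

1. **Calibration** — per-channel factors from a homogeneous phantom of
   known properties, CF = (A/A_model)/mean(A/A_model), additive phase
   offsets; air-gap-corrupted peripheral channels rejected by an
   amplitude-versus-model rule.
2. **Bulk estimation** — Newton–Raphson slope matching:
   argmin over (μa, μs′) of [d ln(ρφ)/dρ − model]² + [dθ/dρ − model]²,
   giving the homogeneous initialization.
3. **Reconstruction** — dual-mesh (2 mm forward / 5 mm inverse) FEM with a
   Levenberg–Marquardt iteration on Rytov-form data ln(Φ/Φ₀), exact adjoint
   Jacobian, sensitivity-normalized damping, positivity by projection.
4. **Display** — maximum-intensity projection along the compression axis,
   rendered as a colour overlay on the DBT slice (rigid similarity
   registration, per-breast colour normalization).
5. **Reader statistics** — sensitivity/specificity/PPV/NPV with Wilson CIs,
   binary-rating AUC = (sens+spec)/2 with DeLong intervals, Fleiss/Cohen
   kappa with bootstrap CIs, exact McNemar / Fisher / paired DeLong tests.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate a 40 mm-thick breast with a 7.5 mm-radius tumour-like absorber
(2× background absorption) on a reduced 5×5-source / 4×3-detector paddle,
calibrate against a paired homogeneous phantom exam, estimate bulk
properties, reconstruct, and project:

```python
import numpy as np
from fdot.optics import OpticalProperties
from fdot.measurement import (default_probe_geometry, iq_to_amplitude_phase,
                              compute_calibration, apply_calibration,
                              select_channels)
from fdot.phantom import (make_phantom, Inclusion, NoiseModel, simulate_exam,
                          make_calibration_exam, peripheral_airgap_channels)
from fdot.bulk_fit import estimate_bulk_slab_all
from fdot.recon import ReconSettings, reconstruct, absorption_peak_centroid
from fdot.fusion import rasterize, mip

geometry = default_probe_geometry(slab_thickness=40.0, wavelengths=(785.0,),
                                  source_grid=(5, 5), detector_grid=(4, 3),
                                  pitch=12.0)
phantom = make_phantom(lateral_extent=(70, 70), thickness=40.0,
                       n_wavelengths=1,
                       inclusions=[Inclusion((0.0, 0.0, 20.0), 7.5, 2.0)])
airgaps = peripheral_airgap_channels(geometry, 3)
exam = simulate_exam(phantom, geometry,
                     NoiseModel(seed=7, gain_seed=100,
                                airgap_channels=airgaps),
                     mesh_spacing=1.5)
cal_exam = make_calibration_exam(OpticalProperties(0.005, 1.0), geometry,
                                 NoiseModel(seed=8, gain_seed=100),
                                 mesh_spacing=1.5, lateral_extent=(70, 70))

cal = compute_calibration(cal_exam.raw, OpticalProperties(0.005, 1.0))
meas = apply_calibration(iq_to_amplitude_phase(exam.raw), cal)
bulk = estimate_bulk_slab_all(meas)
meas = meas.with_mask(select_channels(meas, bulk[0]))
print(f"bulk estimate: mu_a = {bulk[0].mu_a:.5f} mm^-1, "
      f"mu_s' = {bulk[0].mu_s_prime:.3f} mm^-1")
print(f"channels retained: {meas.mask.n_retained} / {meas.mask.keep.size}")

settings = ReconSettings(fine_spacing=3.0, coarse_spacing=6.0,
                         lateral_extent=(70, 70), sensitivity_floor=0.2,
                         jacobian_refresh=1)
result = reconstruct(meas, settings, bulk=bulk,
                     provenance_spacing=exam.mesh_spacing)
centroid, peak, background = absorption_peak_centroid(result)
print(f"peak mu_a = {peak:.5f} mm^-1 at centroid "
      f"({centroid[0]:.1f}, {centroid[1]:.1f}, {centroid[2]:.1f}) mm "
      f"[truth (0.0, 0.0, 20.0)]")

mip_image = mip(rasterize(result, 3.0), "z")
print(f"MIP: {mip_image.values.shape} pixels, "
      f"max {mip_image.values.max():.5f} mm^-1")
```

Output:

```
bulk estimate: mu_a = 0.00536 mm^-1, mu_s' = 1.039 mm^-1
channels retained: 297 / 300
peak mu_a = 0.02685 mm^-1 at centroid (3.4, 1.4, 18.7) mm [truth (0.0, 0.0, 20.0)]
MIP: (25, 25) pixels, max 0.02192 mm^-1
```

Reading the numbers: the slab-model slope fit recovers the background
optics within ~7% (truth 0.005 / 1.0); the three air-gap channels are the
only ones masked; the reconstructed absorber peaks within ~4 mm of the true
centre with its depth slightly biased toward the source paddle (the known
weak axis of parallel-plate DOT); and the MIP carries the hotspot into the
2-D craniocaudal frame for overlay on a DBT image
(`fdot.fusion.fuse_overlay`).

The same pipeline is available from the shell:

```sh
fdot simulate --out exam.h5 --calibration-out cal_exam.h5 --inclusion 0,0,25,7.5,2
fdot calibrate --phantom cal_exam.h5 --props mua=0.005,musp=1.0 -o cal.json
fdot preprocess --in exam.h5 --cal cal.json --tol 1.0 -o meas.h5
fdot reconstruct --meas meas.h5 -o result.h5
fdot fuse --result result.h5 --alpha 0.5 -o fusion.png
fdot stats --ratings ratings.csv -o tables/
```

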