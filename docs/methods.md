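# Methods

`fdot` implements the computational chain of a frequency-domain diffuse
optical tomography (DOT) system for the compressed breast, from raw
in-phase/quadrature (IQ) channel data to an absorption image fused with a
digital breast tomosynthesis (DBT) slice, together with the reader-study
statistics used to evaluate such a system. This note records the models, the
numerical choices, and what the synthetic phantom studies do and do not
demonstrate.

## Physical model

Light transport is modelled by the frequency-domain diffusion approximation

    -∇·κ(r) ∇Φ(r,ω) + (μa(r) + iω/c_m) Φ(r,ω) = q₀(r,ω),

with absorption μa (mm⁻¹), diffusion coefficient κ = 1/(3(μa+μs′)) (mm),
reduced scattering μs′ (mm⁻¹), modulation frequency ω = 2π·70 MHz, and
in-medium light speed c_m = c/n with refractive index n = 1.4 by default.
The air–tissue boundary carries the Robin condition κ ∂Φ/∂n + Φ/(2A) = 0
(photons exit and do not return), with the impedance factor
A = (1+R_eff)/(1−R_eff) from the Groenhuis polynomial fit for R_eff(n);
A ≈ 3.25 at n = 1.4. Sources are isotropic points embedded one reduced
scattering length (1/μs′ = 1 mm at default properties) beneath the source
paddle — the standard diffusion-theory surrogate for a collimated beam.

**Sign convention.** With the +iω/c_m sign above, the homogeneous Green's
function is Φ = exp(−kρ)/(4πκρ), k = sqrt((μa + iω/c_m)/κ), and arg Φ
*decreases* with distance. The instrument-facing phase everywhere in this
package is the demodulated **lag** θ = −arg Φ, which grows with distance at
slope +Im k; ln(ρΦ) falls at slope −Re k. Raw IQ frames store A·e^{iθ}.

## Measurement model and calibration

A homodyne channel (source s, detector d, wavelength λ) reports one complex
IQ value. Real channels differ by fixed gains and phase offsets (laser
power, APD sensitivity, RF path length). Calibration measures a homogeneous
phantom of known properties and forms, per channel,

    CF_amplitude = (A_meas / A_model) / mean(A_meas / A_model),

where the mean runs over all channels of one wavelength and A_model is a
homogeneous-slab prediction at the channel's own geometry. Two reference
models are provided: the analytic extrapolated-boundary image series
(z_b = 2Aκ, 15 image pairs; instantaneous, laterally infinite) and the FEM
slab channel model on a finite slab. The analytic reference is the default;
when the data feed a FEM reconstruction the FEM reference must be used,
because the two references disagree by per-optode factors of up to tens of
percent for channels near the lateral boundary — structure that would
otherwise pass through calibration and dwarf the perturbation signal the
reconstruction is trying to fit (on simulated exams it is the difference
between seed-stable ~3 mm localization and reconstructions that wander by
~10 mm in depth). Dividing by the model *first* makes channels at
different source–detector distances commensurable; the raw ratio-to-mean
form of the printed factors is stored alongside. Phase is corrected subtractively — the per-channel
offset is θ_meas − θ_model on the phantom — because RF path-length errors
are additive; a ratio of wrapped phases is not gauge-invariant. The mean
measured-to-model amplitude ratio is kept as a per-wavelength scale, so
calibrated amplitudes live in the absolute units of the homogeneous model
(unit source strength), which is what the reconstruction's data-model
coupling expects. Phases are unwrapped along increasing distance within
each source group (adjacent lags differ by ≪ π at this geometry, so
cumulative unwrapping is safe).

**Channel rejection.** Air gaps at the breast periphery attenuate channels
by orders of magnitude. A channel is kept iff its amplitude exceeds a floor
(10⁻⁶ of the maximum by default) and its log-ratio against the
homogeneous-slab model at the bulk estimate lies within ±1.0 (natural log).
The per-wavelength median of the log-ratio is subtracted before
thresholding: this makes the rule invariant to any residual global scale
and robust to a biased bulk guess, while a handful of corrupted channels
cannot move the median of thousands. Enlarging the tolerance never removes
a retained channel.

## Bulk (homogeneous) property estimation

The initial guess for reconstruction matches measured and modelled distance
slopes in least squares:

    argmin_{μa,μs′} [d ln(ρφ)/dρ − c_a(μ)]² + [dθ/dρ − c_p(μ)]²,

solved by damped Newton–Raphson (step halving on objective increase,
parameter box μa ∈ [10⁻⁴, 0.1], μs′ ∈ [0.1, 5] mm⁻¹, convergence at
relative update < 10⁻⁶ or objective < 10⁻¹⁴). Measured slopes are ordinary
least-squares fits of ln(ρφ) and θ against ρ over retained channels.

Two model choices for the slope functions c(μ) are provided:

* `estimate_bulk` — infinite-medium closed form c_a = −Re k, c_p = +Im k.
  Exactly invertible and fast, but biased high on parallel-plate
  transmission data, where boundary images steepen the apparent slopes
  (≈ +60% in μa at a 40–50 mm slab).
* `estimate_bulk_slab` — same objective with slopes predicted by the
  analytic slab model at the actual channel layout, solved by bounded
  least squares. Unbiased on slab data (within a few percent at the
  default conditions) and therefore the default initializer used by
  `reconstruct`.

Wavelengths are fitted independently throughout; nothing couples them.

## FEM forward solver

Structured slab meshes: each cubic cell is split into six Kuhn tetrahedra
sharing the main diagonal, which keeps the triangulation conforming and
makes point location closed-form (the containing tetrahedron follows from
the sort order of the local cell coordinates). First-order Galerkin
assembly uses element-mean κ for the stiffness term, the exact third-order
barycentric integrals for the nodally varying absorption mass term, and
triangle mass matrices scaled by 1/(2A) for the Robin boundary. The
assembled matrix is complex symmetric (asserted to 10⁻¹² in tests), so
source–detector reciprocity holds exactly at the discrete level; channel
predictions therefore come from the n_detector adjoint solves rather than
the n_source direct solves whenever fields are not otherwise needed.

Linear systems up to 12k nodes are solved by sparse LU. Larger systems
(the 2 mm reconstruction meshes at ~44k nodes and the 1 mm simulation
meshes at ~335k nodes) use a geometric multilevel scheme: meshes coarsened
by doubling the spacing until the coarsest level is direct-solvable,
Galerkin (RᵀAP) coarse operators, V(2,2) cycles with damped-Jacobi
smoothing (ω = 0.8) run in single precision, driving a minimal-residual
block-Richardson iteration carried in double precision. The solver contract
is method-agnostic: every returned column has residual ≤ rtol·‖RHS‖, with
rtol = 10⁻¹⁰ by default (the true residual is re-verified before
convergence is declared); reconstruction inner solves use 10⁻⁸. At ~44k
nodes the multilevel solve of a 104-column block takes seconds where sparse
LU needs ~50 s and ~3 GB of fill.

The infinite-medium Green's function and the image-series slab solution
are kept as analytic oracles; the FEM solution's interior distance slopes
match the analytic wavenumber within 2% (log-amplitude) at 2 mm spacing,
and refinement convergence toward the oracle is monotone.

## Inverse problem

The data vector per retained channel is the Rytov form
[ln(A_meas/A_model); θ_meas − θ_model] — real and (negated) imaginary parts
of ln(Φ/Φ₀) under the lag convention. Absorption is represented on a coarse
mesh (default 5 mm) and prolonged barycentrically onto the fine forward
mesh (default 2 mm, both inside the system's 2–5 mm bracket) for every
solve; κ is held at its bulk value (absorption-only reconstruction — this
transmission geometry determines scattering too weakly, and a scattering
flag is deliberately not implemented).

**Jacobian.** d ln Φ_ch/dμ_j = −(Φ_d ᵀ ∂K/∂μ_j Φ_s)/Φ_ch with the exact
consistent derivative of the discrete Galerkin system (the same third-order
integrals used in assembly), accumulated element-wise in single precision
and restricted to the coarse basis. Because it is the exact derivative of
the discrete forward map, it matches central finite differences to
truncation error — the 2% validation tolerance is met with orders of
magnitude to spare, at every iterate.

**Step.** Levenberg–Marquardt: (JᵀJ + λ·max diag(JᵀJ)·I) δ = Jᵀr, with
λ starting at 10, divided by 10 on accepted steps (projection error
decreased) and multiplied by 10 on rejections. Before stepping, Jacobian
columns are normalized by their norms, floored at 0.1 of the largest
(spatially variant regularization): without it the update concentrates in
the high-sensitivity nodes under the optodes and the image develops surface
artifacts; the floor keeps near-null corner columns from being amplified
into spikes (sparser optode arrays need a higher floor, ~0.2). The
Jacobian is refreshed every third accepted step (it varies slowly between
iterates and dominates the per-iteration cost; classic every-step refresh
is one setting away). Updates are clipped to μa ∈ [10⁻⁴, 0.1] mm⁻¹
(positivity by projection, not log-parameterization — simpler and directly
testable). Iteration stops when the relative image update of an accepted
step falls below 0.02, when an accepted step improves the projection error
by less than 1% (the practical reading of "marginal updates"), or at 20
iterations. The projection error is non-increasing over accepted
iterations by construction, and the whole loop is deterministic —
identical inputs give bit-identical logs.

**Data–model coupling.** At the bulk-initialized first iteration the mean
log-amplitude and mean phase residuals are removed from the data, once, and
kept fixed (the unknown global source scale). A linear-in-distance variant
exists but is not the default: distance trends also carry perturbation
signal, and removing them measurably flattens the recovered contrast. The
mean removal slightly reduces recovered contrast (the inclusion's own
signal contributes to the mean), acceptable against the ≥30%-of-truth
contrast contract.

**Field of view.** A handful of coarse nodes at the lateral image boundary
— inside the source footprint but beyond the detector rows, where no
source–detector pair constrains the image locally — can accumulate values
comparable to the lesion peak. Hotspot readouts therefore use the *sensing
aperture* (the intersection of the source and detector lateral footprints,
`fusion.sensing_aperture`) and the above-half-maximum excess centroid
(`fusion.hotspot_centroid`), which is also the natural reading of a colour
overlay. An option to freeze nodes outside the aperture during the
inversion exists but is off by default (it merely moves the
weakly-determined boundary inward).

## Rasterization, MIP, fusion

The coarse-mesh image is rasterized barycentrically onto a regular grid (at
or below the coarse spacing — values are convex combinations of nodal
values, so the volume never exceeds the nodal range), collapsed along the
compression axis by per-column maximum (MIP), and rendered over the DBT
slice: background normalized to its own range, foreground normalized
per-image to [min, max] (readers judge activity relative to surrounding
parenchyma, so relative contrast is displayed; a constant MIP renders as a
uniform colour), blended with α = 0.5 under a perceptually uniform
colormap ("inferno"). DBT and DOT are acquired under separate compressions,
so registration is a rigid 2-D similarity transform in physical
coordinates with user-adjustable scale/rotation/translation; automatic
intensity-based registration is out of scope by design.

## Synthetic data generator

The generator emulates the 64-source / 8×5-detector parallel-plate scanner
(10 mm pitch, both grids centred — the published system states the counts
but not the layout) on digital slab phantoms with spherical inclusions.
Defaults are the study conditions: background μa = 0.005 mm⁻¹,
μs′ = 1.0 mm⁻¹ at all three wavelengths (literature-typical healthy
breast), thickness 50 mm (clinical mean ≈ 51 mm, admissible range
20–74 mm), tumour contrast 2.0× in μa with 7.5 mm radius. The noise chain
applies, in order: fixed log-normal per-channel gains (20% spread) and
normal phase offsets (0.1 rad) drawn from a *gain seed* shared between a
calibration exam and its paired patient exam; ×0.01 attenuation on listed
air-gap channels; then 1% multiplicative amplitude noise and 0.5° additive
phase noise per measurement. All draws flow from the recorded seeds and
exams are bit-reproducible.

The simulation forward solve runs on a 1 mm mesh — half the reconstruction
fine spacing — and the exam records that provenance; `reconstruct` refuses
data whose provenance spacing equals its fine spacing unless explicitly
overridden (the inverse-crime guard). Reconstructions of simulated data
therefore contend with genuine discretization mismatch (~5–10% per-channel
between 1 mm and 2 mm solutions) on top of the injected noise.

What the generator does **not** emulate: breast-shaped boundaries and
chest-wall truncation (slabs only; the two-layer breast/chest-wall model is
out of scope), spectrally varying chromophore contrast (wavelengths share
properties by default), detector nonlinearity and drift, and spatially
correlated air-gap physics (corruption is a per-channel attenuation
factor). Passing phantom tests demonstrate the correctness of the
computational chain under the stated noise model — not clinical imaging
performance.

## Reader-study statistics

Binary ratings (positive/negative per subject, reader, modality) are
evaluated with: sensitivity/specificity/PPV/NPV with Wilson score 95% CIs
(Wilson reproduces the printed clinical intervals, e.g. 12/13 →
92.3 (66.7–98.6); exact Clopper–Pearson is available behind a flag);
single-operating-point AUC = (sens+spec)/2, verified equal to the
Mann–Whitney statistic of binary ratings, with DeLong standard errors;
Fleiss' multi-rater κ with a percentile bootstrap CI over subjects (the
two-rater Cohen form is also provided — for two readers the common clinical
packages compute that form, and the two differ only in the third decimal on
pooled-vs-product marginals); exact binomial McNemar on discordant pairs
(p = 1 when none, by convention), Fisher's exact test, and the paired
DeLong test for correlated AUCs. Zero-denominator metrics are reported as
undefined, never as zero. Display rounding: one decimal for percentages,
three for AUC/κ.

The ratings generator draws a latent subject difficulty u ~ N(0, s²) plus
unit-normal reader noise against thresholds set from the target
sensitivity/specificity; s controls inter-reader agreement at fixed
marginal accuracy.

## Problem sizes and budgets

Test and acceptance runs use: forward-oracle checks on an 80×80×60 mm slab
at 2 mm; bulk round-trips on a 5×5 property grid plus 100 noisy
replicates; calibration/rejection checks on 2 mm simulations; the
inclusion-recovery study at the full 64×40-channel geometry on an
80×80×50 mm slab (1 mm simulation, 2 mm/5 mm dual mesh); and reduced
optode grids (e.g. 5×5/4×3 on a 70×70×40 mm slab) for unit-level recovery
tests. These sizes were chosen so the full chain, simulator included, runs
on a single CPU in well under half an hour while remaining at the clinical
geometry for the headline phantom study.

## Known limitations

* Depth localization of the recovered absorber is the weakest axis: it is
  acutely sensitive to any reference mismatch left in the calibrated data
  (see the calibration-reference discussion above) and, even with a
  consistent reference, carries a residual bias of a few mm — the familiar
  sensitivity asymmetry of parallel-plate DOT, only partially compensated
  by column normalization.
* Recovered peak contrast is resolution- and regularization-dependent;
  with a 5 mm coarse mesh a 2× absorber typically reconstructs with
  over-unity apparent contrast concentrated in fewer nodes than the true
  sphere. The contract tested is localization and ≥30% contrast, not
  quantitative μa accuracy.
* The slab bulk estimator inherits the extrapolated-boundary
  approximation; at very thin slabs (< 25 mm) its bias grows.
* The multilevel solver assumes the structured slab topology; arbitrary
  meshes would need a different coarsening.
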