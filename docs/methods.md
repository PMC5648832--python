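# Methods

This note records the models behind `marginscan`, the defaults and the
reasoning for every genuinely open design choice, and what the synthetic
validation does and does not demonstrate.

## Photon transport and probe design

`photon_transport` implements a weighted hop-drop-spin Monte Carlo walk
(exponential step sampling, absorption by weight at interaction sites,
Henyey-Greenstein phase function, Fresnel reflection/refraction at the
surface and at internal index mismatches, Russian roulette at weight
1e-4 with survival 0.1) in a layered semi-infinite medium. The kernel is
serial, numba-compiled and explicitly seeded: identical inputs give
bit-identical results. Weight bookkeeping is exact — every launched unit
of weight ends in a named ledger bucket (reflected, absorbed,
transmitted below the depth cutoff, roulette-killed, step-capped), with
roulette survival boosts recorded separately, so the energy balance
closes to floating-point precision rather than only in expectation.

Semi-infinite media are truncated at a configurable depth cutoff
(default 20 mm). For the breast preset the diffusion penetration depth
is `1/sqrt(3*mua*(mua+mus'))` ≈ 5.7 mm, so the cutoff sits at ~3.5
penetration depths and the weight lost from paths that would have
returned to a detector within a few mm of the source is negligible; the
truncated weight is reported as transmitted, keeping the ledger exact.

Tissue optical properties at 785 nm are not uniquely established;
the shipped `breast_785nm` preset — absorption 0.01/mm, scattering
10/mm with anisotropy 0.9 (reduced scattering 1.0/mm), refractive index
1.4 — is a documented stand-in with typical soft-tissue values, and all
values are configurable. Consequences: the *shape* of the PCE-offset
curve (monotone decay, approximately `a + b*ln(offset)`) and the design
logic built on it are reproduced, but absolute relative-PCE percentages
at the ring offsets depend on the unknown optics and are treated as
qualitative. The PCE is defined per unit annulus area (annulus width =
fibre diameter, default 0.1 mm), normalised to 100% at the 0.75 mm
reference offset. Detection accepts all exit angles (no fibre NA
model), and the launch is a normal-incidence pencil beam with no
specular term (source fibre in contact).

Fibre allocation searches all integer count vectors (1..8 per ring) and
minimises the spread of `count x relative PCE`, tie-broken by smallest
total count and then lexicographically; for the ring PCE values
68.6/45.7/34.3% this yields 2/3/4 — the probe's 36 fibres over 4
quadrants.

Depth statistics use each detected photon's maximum penetration depth.
At the stand-in optics, the fraction of outer-ring signal from a
[2,3] mm slab is ~0.23 — the probe's 5% sampling-depth rule derives from
different (unpublished) optics — so the Monte Carlo layer asserts the
*ordering* (deeper fractions grow with S-D offset; depth-band fractions
partition to 1), while the absolute 5% anchor is imposed where it is
actually used, in the scan generator's calibrated depth weights (below).

## Probe model

Contact area is `pi*(d/2)^2`; the full-coverage point budget divides the
specimen surface area by the contact area *at its displayed precision*
(0.1 mm^2) and rounds to the nearest integer, reproducing the device's
stated budgets (5600 mm^2 / 38.5 mm^2 → 145; a 5 cm sphere / 38.5 mm^2
→ 204).
The depth-averaged spectrum is the unweighted arithmetic mean of the 12
ring-quadrant spectra at a point; weighting by fibre count per ring was
considered and rejected because the acquisition averages recorded
spectra, not fibres.

## Spectral pipeline

Order: calibration → response correction → smoothing → baseline
subtraction → AUC normalisation, enforced by provenance tags (an
operation refuses input that has already passed a later stage;
normalisation is idempotent). Defaults: Savitzky-Golay window 7,
polyorder 3; modified-polynomial baseline order 5, max 100 iterations,
tolerance 1e-4. These defaults are recorded in each spectrum's metadata
and are configurable — the device's exact parameters are not public.

Numerical notes on the baseline: convergence is judged per spectrum on
the movement of the fitted baseline between iterations (in units of the
spectrum's maximum); raw polynomial-coefficient deltas on the scaled
Vandermonde basis do not settle at realistic noise levels and would
always exhaust the iteration budget. The polynomial is estimated on
every 3rd wavenumber in single precision — it is a smooth order-5
polynomial, so decimation changes it negligibly (verified: an exact
polynomial input is reproduced to ~1e-7 relative) — and evaluated on the
full axis in double precision. Non-convergence is flagged in metadata,
never raised.

Band features use band means over ±4 1/cm rather than single bins, for
robustness to 1 1/cm axis shifts.

## Component library

The pure-component spectra are parametric gaussian band sets — synthetic
stand-ins anchored to standard fingerprint assignments, not fitted to
any measurement. The tissue pair encodes the contrasts that carry the
classification: fibroadenomatoid (protein-rich) has a phenylalanine band
at 1006 1/cm, a higher 1265/1304 ratio, a weaker CH2 band at 1445 1/cm,
and a broader amide I band with a 1630 1/cm left shoulder; fatty tissue
is dominated by 1304/1445/1746 lipid bands. Paraffin has sharp alkane
bands (1062/1133/1296/1441), the film is PET-like, the paper
cellulose-like. Every entry is scaled to unit AUC on the default
900-1800 1/cm axis (1 1/cm step), so CLS coefficient shares coincide
with mixing fractions and "relative spectral contribution" is
unambiguous.

## Unmixing and margin rules

Unconstrained CLS is the exact least-squares solution (residual
orthogonal to the library span); classification uses the non-negative
fit, whose coefficient shares read as a composition. Batch NNLS is
solved exactly by support enumeration (valid and fast for the <= 6
component libraries used here; equal to the iterative solver to machine
precision). Cumulative variance explained is computed on mean-centered
intensities: `100*(1 - pooled residual SS / pooled centered total SS)`.
Margin rules: tissue — fatty iff fat fraction >= 0.5 (boundary
inclusive); phantom — paraffin-positive iff paraffin contribution
>= 0.05.

## Surface reconstruction, planning, co-registration

Coordinates are right-handed millimetres with the rotation axis along x
and the mounting pole at -x; the camera is orthographic with known
scale. A voxel survives carving iff its center back-projects inside
every silhouette; marching cubes on the padded occupancy yields a
watertight mesh. The visual hull over-approximates the object —
concavities cannot be recovered from silhouettes — while the extracted
isosurface sits within half a voxel of the occupancy boundary, so
containment holds up to one voxel of discretisation. Default 36 views
at 10° spacing; voxel 0.25 mm for the phantom, 0.5 mm for tissue-scale
work.

Planning mirrors the two-motor traversal: bands along the rotation axis
at equal meridian arc spacing, points along each band's cross-section
perimeter at equal arc spacing, rotation-major order. Cross-sections are
computed by a vectorised plane-triangle slicer with vertices ordered by
azimuth — correct for sections star-shaped about the axis, which covers
the convex-ish visual hulls in scope. Planned points lie exactly on mesh
faces; nearest-neighbour spacing stays within [0.5, 1.5] of the step. A
7 mm mounting disc at the -x pole is excluded and flagged as requiring a
manual measurement. Degenerate steps (up to the specimen circumference)
produce a single band rather than an error.

Co-registration colours every mesh face and vertex by its nearest
planned point's label (green fatty/clean — RGB 0,170,0; blue
fibroadenomatoid/paraffin — 0,0,200). Spot localisation clusters
positive points by single linkage (cutoff 2.5 steps), takes
fraction-weighted centroids, projects them to the mesh surface, matches
them to ground truth by minimum-cost assignment, and compares all
pairwise 3D Euclidean inter-spot distances (per-pair absolute error,
maximum, coefficient of determination). Euclidean chords, not geodesics,
are the gated quantity — how the physical reference distances were taped
or calipered is unknown, so the convention is declared rather than
inferred.

## Synthetic specimens and the depth-weight model

The generator is a pure function of (configuration, seed).

Per-point acquisition replaces per-point Monte Carlo with an exponential
depth weight per ring, for desk-scale speed. Calibration: the outer ring
(3.5 mm offset) decay length solves `exp(-2/l) - exp(-3/l) = 0.05` —
a 1 mm tissue slab at 2 mm depth contributes exactly 5% of detected
weight, the probe's sampling-depth rule (l ≈ 0.742 mm); inner-ring decay
lengths scale by the ratios of mean maximum penetration depth measured
with the Monte Carlo module at the breast preset (0.605/0.832/1.0 for
1.57/2.68/3.5 mm, recomputable via `calibrate_decay_ratios`), so inner
rings are strictly more surface-weighted. Materials carry an effective
attenuation/yield factor; the clear polymer film gets 0.15. A transparent
film neither attenuates like turbid tissue nor emits much Raman signal
per unit thickness, which is exactly why paraffin under a 2 mm film is
readily detected on the physical phantom — a turbid-tissue depth weight
applied to the film would make even a 12 mm spot fall below the 5%
threshold, contradicting the observed detections. Lateral footprints are
discs of radius equal to the ring offset, sampled with 200 quasi-uniform
(sunflower) points split into quadrants; spots are circular with
diameter equal to the stated lateral extent. Ground-truth labels are
the margin rules applied to the true (noiseless) depth-averaged
fractions, so with zero noise and zero baseline the full pipeline
reproduces them exactly (the forward model is linear and smoothing is a
linear operator applied to both data and library).

Defaults emulate the study conditions: 5 cm sphere, 2 mm film, four
paraffin spots of 12/9/6/3 mm placed without overlap in the equatorial
belt (|x| <= 10 mm, seeded rejection sampling); fluorescence baseline
amplitude 0.05 (a smooth decreasing polynomial, ~3x the strongest tissue
band of a unit-AUC spectrum); scanning noise sigma 1e-3 per channel
(~SNR 17 at the lipid band for a single 0.5 s ring spectrum, ~60 after
depth averaging). The labelled biopsy study (5 specimens, 28 spots,
13 fatty / 15 fibroadenomatoid) draws each spot's true fat fraction at
an offset `effect_size*(0.03 + 0.45*Beta(2,3))` from the 50% boundary —
semi-quantitative histopathological grading works in coarse steps, so
compositions at exactly the boundary are rare — with per-specimen
multiplicative gain (lognormal sigma 0.15) and fluorescence amplitude
(lognormal sigma 0.3) that AUC normalisation and baseline subtraction
are there to remove. Single-point biopsy spectra use noise sigma 1e-4
(longer dwell than scanning); this default was calibrated so the
lambda = 0.01 classifier operates in its intended regime — occasional
single-spot errors rather than perfection or collapse. At sigma 1e-3
the L1 penalty's small posterior margins are overwhelmed by test-time
noise and LOSO degrades to chance; the twin documents this sensitivity
rather than hiding it (see Limitations).

## SMLR

Binary multinomial logistic regression with the negative (fatty) class
as reference, no intercept, raw spectral features ("direct kernel"),
and an L1 (Laplacian-prior) penalty `lambda * ||w||_1`, lambda = 0.01.
Solved by L-BFGS-B on the split `w = u - v, u, v >= 0` parametrisation
from a zero start — deterministic, with a monotone objective trace.
Posterior threshold 0.5; exact ties go to fibroadenomatoid (the
suspicion-first call). LOSO holds out all spots of one specimen per
fold and asserts per fold that the held-out specimen is absent from
training. Cohen's kappa uses marginal-based expected agreement; display
rounding is whole percents and two-decimal kappa.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the computational chain is self-
consistent and recovers known ground truth under the modelled
conditions: linear mixtures of the synthetic library, exponential depth
weights, orthographic silhouettes of convex quadrics, gaussian noise,
polynomial fluorescence. They do not demonstrate performance on real
tissue: real margin spectra contain non-tissue signatures (blood,
cautery), spatially correlated composition, specimen deformation over
time, camera calibration error and detector artifacts, none of which
are modelled. The real-device error rates for biopsy-validated spots are a property of that study's data, not something a synthetic
twin can certify.

## Known limitations

* The L1 classifier at lambda = 0.01 selects very few wavenumber
  channels; its generalisation is sensitive to per-channel noise, and
  the twin's operating point had to be calibrated accordingly.
* Visual hulls cannot represent concavities; localisation accuracy is
  stated for convex-ish specimens.
* The scan planner's cross-section ordering assumes sections star-shaped
  about the rotation axis.
* Monte Carlo elastic transport is a proxy for Raman-shifted photon
  transport (no re-emission wavelength shift), as in the probe-design
  literature it follows.
* The ~8666-point full-sphere traversal of the physical device does not
  match any simple tiling of a 5 cm sphere; point counts are validated
  against geometry (area / step^2 with the band parametrisation), not
  against that number.
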