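# marginscan

A desk-scale digital twin of an automated 3D spatially offset Raman
spectroscopy (SORS) scanner for intraoperative assessment of breast
tumour margins. During breast-conserving surgery the excised specimen's
outer surface (the *margin*) must be free of tumour; `marginscan`
re-implements the computational chain of such a scanner and validates it
end to end on ground-truthed synthetic specimens:

* **Probe design** — Monte Carlo photon transport in a breast-like
  turbid medium gives the photon collection efficiency (PCE) versus
  source-detector (S-D) offset; an exhaustive search assigns integer
  fibre counts per detector ring so that `count x PCE` is equalised
  (2/3/4 fibres per quadrant at 1.57/2.68/3.5 mm → a 36-fibre,
  4-quadrant, 3-ring probe), and depth-resolved detection statistics
  anchor the probe's sampling-depth rule.
* **Surface reconstruction and scan planning** — binary silhouettes at
  many rotation angles are carved into a watertight visual-hull mesh;
  measurement points are laid out in rotation bands at a configurable
  step, mirroring the scanner's two-motor kinematics.
* **Spectral pipeline** — wavenumber calibration, system-response
  correction, Savitzky-Golay smoothing, iterative modified-polynomial
  fluorescence subtraction, and area-under-curve (AUC) normalisation,
  with provenance tags that enforce the stage order.
* **Unmixing and classification** — classical least squares (CLS)
  against pure-component libraries yields relative spectral
  contributions; threshold rules call margins (fatty iff fat fraction
  >= 50%; paraffin-positive iff paraffin contribution >= 5%), and a
  sparse multinomial logistic regression (SMLR; L1/Laplacian prior,
  lambda = 0.01, no bias, raw spectral features) is evaluated by
  leave-one-specimen-out (LOSO) cross-validation with confusion-matrix
  metrics (sensitivity, specificity, accuracy, Cohen's kappa).
* **Synthetic specimens** — a seeded generator produces the validation
  phantom (5 cm sphere, four 3-12 mm paraffin spots under a 2 mm clear
  film), ellipsoidal tissue specimens with shallow fibroadenomatoid
  inclusions, and the 28-spot / 5-specimen labelled biopsy study, all
  with exact ground truth.

## Worked example

```sh
python examples/phantom_scan.py
```

builds the default phantom, reconstructs it from 36 silhouettes at
0.25 mm voxels, scans the spot-bearing band at a 0.5 mm step (~22,000
points), unmixes every depth-averaged spectrum against the
film/paper/paraffin library and scores the result:

```
scan points: 22435
spots detected: 4 of 4
true inter-spot distances (mm): [32.09, 39.12, 47.48, 12.54, 41.81, 33.6]
per-pair |error| (mm):          [0.287, 0.183, 0.064, 0.111, 0.094, 0.052]
max |error|: 0.287 mm (sub-voxel localisation on the reconstructed surface)
R^2 predicted vs true distances: 0.9998
CLS cumulative variance explained: 98.7 % (3-component film/paper/paraffin library)
```

All four embedded spots are found; inter-spot distances measured on the
reconstructed surface agree with the physical ground truth to well under
half a millimetre, and the three-component CLS model accounts for
essentially all structured variance in the 22k scan spectra. The other
examples (`probe_design.py`, `preprocess_and_unmix.py`,
`tissue_study.py`, `surface_reconstruction.py`) exercise the remaining
capabilities; each prints a few annotated numbers in under a minute.

A thin CLI mirrors the workflow stage by stage
(`marginscan probe-design | make-phantom | render | reconstruct | plan |
simulate-scan | preprocess | unmix | classify | report | run-all`); every
command is reproducible from its seed.

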