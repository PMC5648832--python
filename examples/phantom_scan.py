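"""The phantom validation twin, end to end.

Builds the default 5 cm spherical phantom (four paraffin spots of
3-12 mm under a 2 mm clear film), renders 36 silhouettes, reconstructs
the visual hull at 0.25 mm voxels, scans the spot-bearing band at a
0.5 mm step, classifies every point by CLS, and scores the predicted
spot positions against the ground truth. Takes ~30 s.
"""

import numpy as np

from marginscan import run_phantom_pipeline

res = run_phantom_pipeline(seed=1)

print(f"scan points: {len(res.sim)}")
print(f"spots detected: {res.n_detected_spots} of {len(res.spec.spots)}")
print("true inter-spot distances (mm): "
      f"{np.round(res.spec.true_pairwise_distances(), 2).tolist()}")
print("per-pair |error| (mm):          "
      f"{np.round(res.localisation.pair_errors, 3).tolist()}")
print(f"max |error|: {res.max_distance_error:.3f} mm "
      "(sub-voxel localisation on the reconstructed surface)")
print(f"R^2 predicted vs true distances: {res.r_squared:.4f}")
print(f"CLS cumulative variance explained: {res.variance_explained:.1f} % "
      "(3-component film/paper/paraffin library)")
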