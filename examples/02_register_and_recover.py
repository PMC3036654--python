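"""Superimpose the phantom pair on the anterior cranial base and score it.

The workflow mirrors semi-automated clinical superimposition: rough landmark
alignment, then rigid registration maximizing mutual information of the
grey values inside the registration-zone ROI.  Because the phantom's true
transform is known, the result is scored as translation/rotation error and
target registration error (TRE) at the evaluation-structure centroids.
"""

import numpy as np

from voxelreg import (
    PhantomSpec,
    default_landmarks,
    evaluate_recovery,
    generate_phantom_pair,
    register,
    rough_align,
    structure_centroids,
    zone_roi,
)

spec = PhantomSpec.coarse(
    true_angles_zyx_deg=(4.0, 0.0, 0.0), true_translation_mm=(2.0, -3.0, 1.2), seed=1
)
fixed, moving, truth = generate_phantom_pair(spec)

roi = zone_roi(truth.structure_masks, "anterior-cranial-base")  # mask + 2-voxel margin
landmarks = default_landmarks(spec)
rng = np.random.default_rng(0)
clicked = truth.true_transform.inverse().apply(landmarks) + rng.normal(0, 1.0, landmarks.shape)
init, rms = rough_align(landmarks, clicked)
print(f"rough landmark alignment: RMS residual {rms:.2f} mm")

estimate, diag = register(fixed, moving, roi, init)
print(f"MI: {diag.initial_mi:.3f} -> {diag.final_mi:.3f} bits over "
      f"{diag.sample_counts[-1]} ROI samples")

report = evaluate_recovery(truth, estimate, structure_centroids(truth))
print(f"translation error {report.translation_error_mm:.3f} mm, "
      f"rotation error {report.rotation_error_deg:.3f} deg, "
      f"TRE {report.tre_mm:.3f} mm")
# Sub-voxel errors (well under the 0.8 mm voxel size here) mean the two scans
# are aligned more precisely than the scanner resolution.
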