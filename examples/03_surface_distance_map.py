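"""Measure and export the surface distance map of a superimposed pair.

After registration the two bone models are compared: per-vertex exact
closest-point distances from the follow-up iso-surface to the baseline
iso-surface, summarized per anatomic region and exported as a color-banded
PLY (green = follow-up in front of baseline, red = behind; 0.5 mm bands).
"""

import tempfile
from pathlib import Path

import numpy as np

from voxelreg import PhantomSpec, generate_phantom_pair, export_distance_map
from voxelreg.pipeline import evaluate_superimposition

spec = PhantomSpec.coarse(
    true_angles_zyx_deg=(3.0, 0.0, 0.0), true_translation_mm=(1.5, -2.0, 1.0),
    noise_sd=30.0, seed=3,
)
fixed, moving, truth = generate_phantom_pair(spec)

# Evaluate at the TRUE transform: the residual distances show the measurement
# floor (mesh discretization + noise), i.e. what "perfectly registered" means.
summary, mesh = evaluate_superimposition(
    fixed, moving, truth.true_transform, truth.evaluation_masks()
)
print(summary.per_region.to_string(index=False))
print("(mean absolute mm per region at the exact transform: the floor of the method)")

out = Path(tempfile.mkdtemp()) / "distance_map.ply"
mesh.signed_distance_mm = np.nan_to_num(mesh.signed_distance_mm, nan=0.0)
export_distance_map(mesh, out, band_width_mm=0.5)
print(f"color-banded mesh written to {out} (+ .legend.json sidecar)")
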