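# voxelreg

Voxel-based superimposition of serial CBCT (cone-beam CT) volumes, for
orthodontists, maxillofacial surgeons and imaging researchers who need to
compare a follow-up scan with a baseline scan of the same patient: assess
surgical or treatment changes, and quantify how accurate and reproducible the
superimposition itself is.

The package implements the full semi-automated workflow as a library:

1. **Bone model construction** — voxels at or above a lower Hounsfield-unit
   threshold (clinically chosen in 250–350 HU; default 300 HU) form the bone
   segmentation, and marching cubes extracts the 3D bone model.
2. **Voxel-based rigid registration** — after a rough landmark alignment
   (orthogonal Procrustes), the rigid transform *T* = (R, t) mapping the
   follow-up volume onto the baseline volume is estimated by maximizing the
   Shannon mutual information of the joint grey-value histogram inside a
   registration zone Ω (anterior cranial base, or left zygomatic arch =
   zygomatic bone + zygomatic process of the temporal bone):

   *T̂* = argmax<sub>T</sub> MI( F(x), M(T⁻¹x) ; x ∈ Ω ),
   MI = Σ<sub>a,b</sub> p(a,b) log₂ [ p(a,b) / (p(a) p(b)) ]

   with hard 64-bin histograms, trilinear interpolation, and a
   coarse-to-fine Powell search.
3. **Surface distance maps** — exact per-vertex closest-point distances from
   the superimposed follow-up model to the baseline model, signed by the
   baseline's outward normal (positive/green = in front, negative/red =
   behind), summarized as mean ± SD per anatomic region (anterior cranial
   base CB, forehead FH, left/right zygomatic arches ZL/ZR) and exportable
   as color-banded PLY meshes (0.5 mm or 1 mm graduations).
4. **Reproducibility statistics** — paired-sample t-tests with 95%
   confidence intervals on repeated superimpositions, and Pearson
   correlations of the regional means across repeats.

Because patient scans cannot be shipped, the package includes a synthetic
skull phantom (cranial vault shell with basal ridges, forehead patch,
zygomatic arches with zygomatic bodies, and a jaw block that moves between
timepoints) with a *known* rigid transform between the two volumes, so
registration accuracy becomes a ground-truth parameter-recovery experiment
scored as translation/rotation error and target registration error (TRE).

## Worked example

```sh
python examples/02_register_and_recover.py
```

```
rough landmark alignment: RMS residual 1.28 mm
MI: 0.958 -> 1.731 bits over 34868 ROI samples
translation error 0.086 mm, rotation error 0.513 deg, TRE 0.176 mm
```

A half-resolution (0.8 mm) phantom pair with a known 3.8 mm / 3.8° motion is
roughly aligned from noisy landmarks (1 mm click noise), then registered on
the anterior cranial base. Mutual information rises from 0.96 to 1.73 bits,
and the recovered transform reproduces the ground truth to a fraction of a
voxel: the residual displacement at the four anatomic evaluation regions
(TRE) is 0.18 mm. The other examples generate phantoms
(`01_generate_phantom.py`), measure and export surface distance maps
(`03_surface_distance_map.py`), and run a miniature repeated-superimposition
study with the full statistical tables (`04_reproducibility_study.py`).

A thin CLI wraps the same pipeline for shell use:

```sh
voxelreg phantom --coarse --seed 1 --out pair/
voxelreg superimpose pair/fixed.nii.gz pair/moving.nii.gz \
    --roi-mask pair/mask_CB.nii.gz --init-landmarks f.txt m.txt --out reg/
voxelreg evaluate pair/fixed.nii.gz pair/moving.nii.gz \
    --transform reg/transform.txt --region-mask CB pair/mask_CB.nii.gz --out eval/
voxelreg reproduce-study --cases 16 --seed 0 --out study/
```

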