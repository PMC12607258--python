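# bonemicro

Quantitative analysis of bone microarchitecture from HR-pQCT-like 3D
volumes (isotropic voxels, default 60.7 µm), for researchers studying
trabecular and cortical bone quality — e.g. skeletal fragility in
type 1 diabetes.

The package implements the full analysis chain:

* **Binarization** — a Laplace–Hamming pipeline (Hamming-windowed
  low-pass, Laplacian edge enhancement, robust thresholding) that
  retains fine trabecular detail, plus the standard density-threshold
  approach for comparison.
* **Cortical segmentation** — a 3-step algorithm: automated
  periosteal/endosteal contouring, intracortical pore identification,
  and integration into a refined cortical compartment mask.
* **ITS** (individual trabecula segmentation) — digital topological
  analysis decomposes the trabecular network into plate-like and
  rod-like elements: a surface-preserving 3D thinning produces the
  skeleton, each skeleton voxel is classified as surface, curve or
  junction from its local topology, junctions split the skeleton into
  elements, and labels propagate back onto every bone voxel.  Outputs:
  pBV/TV, rBV/TV, aBV/TV, pBV/BV, rBV/BV, P–R ratio, pTb.N, rTb.N
  (= (count/BV)^⅓), pTb.Th, rTb.Th, mean plate area, mean rod length,
  and P–P / P–R / R–R junction densities.
* **CPS** (cortical pore skeletonization) — the identical machinery
  applied to the pore space inside the cortex classifies each pore as
  tube-like (Haversian canal; curve skeleton) or slab-like (merged
  canals; surface skeleton), with tube–tube and slab–tube junction
  counts, per-type counts/volumes and the slabs/tubes ratios.
* **CLA** (cortical laminar analysis) — the cortical compartment is
  split into three equal-width concentric layers (endosteal,
  midcortical, periosteal) by normalized transmural depth; each pore is
  assigned to the layer containing its centroid; per-layer pore area,
  number, average size and layer-area-normalized densities are reported.
* **Phantoms** — synthetic trabecular networks, cortical shells with
  canals/voids, and two-group cohorts with known ground truth, so every
  stage is testable end to end without any scan data.
* **Stats** — covariate-adjusted group differences (identity-link GEE
  with exchangeable working correlation over matched pairs and sandwich
  standard errors, or OLS) and linear risk-factor association models
  with configurable per-unit scaling.  No multiple-testing adjustment
  is applied.

## Worked example

```python
import numpy as np
from bonemicro import (PhantomSpec, make_trabecular_phantom, make_cortical_phantom,
                       segment_cortex, its_parameters, cps_analyze_with_elements,
                       cla_analyze, decompose, BinaryMask)

# trabecular network with known composition: 5 plates + 7 rods
spec = PhantomSpec(kind="trabecular", n_plates=5, n_rods=7, seed=42)
mask, truth = make_trabecular_phantom(spec)
em = decompose(mask)                       # plate/rod element map
bulk = BinaryMask(np.ones(mask.shape, bool), mask.spacing_mm)
its = its_parameters(em, bulk)
print(f"plates={its.n_plates} rods={its.n_rods}")
print(f"BV/TV={its.bv_tv:.4f}  pBV/BV={its.p_bv_bv:.3f}  rBV/BV={its.r_bv_bv:.3f}")
print(f"P-R ratio={its.pr_bv_ratio:.3f}  pTb.Th={its.p_tb_th_mm:.4f} mm")

# cortical shell with 5 canals at controlled transmural depths
cort = PhantomSpec(kind="cortical", n_tube_canals=5, shape=(96, 96, 48),
                   pore_depth_fracs=(0.2, 0.35, 0.5, 0.65, 0.8), seed=42)
cmask, _ = make_cortical_phantom(cort)
masks = segment_cortex(cmask)
cps, pore_em = cps_analyze_with_elements(masks)
cla = cla_analyze(masks, pore_em)
print(f"porosity={masks.porosity:.4f}  tubes={cps.n_tube_pores} slabs={cps.n_slab_pores}")
```

printing

```
plates=5 rods=7
BV/TV=0.0050  pBV/BV=0.575  rBV/BV=0.425
P-R ratio=1.354  pTb.Th=0.1214 mm
porosity=0.0186  tubes=5 slabs=0
```

The analyzer recovers the constructed network exactly: 5 plates and 7
rods, a plate tissue fraction of 0.575 (the plates' share of the bone
volume), the generated plate thickness of 2 voxels (0.1214 mm at
60.7 µm), and all 5 canals classified as tube-like with none slab-like.
Per-layer CLA numbers additionally satisfy the additive structure: the
endosteal + midcortical + periosteal pore counts (1 + 3 + 1) equal the
entire-compartment count.

A command-line interface mirrors the library
(`bonemicro binarize|cortseg|its|cps|cla|phantom|stats|analyze|batch`);
see `bonemicro --help`.

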