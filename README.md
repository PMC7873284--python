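# srp3d

3D nuclear texture description and chromatin-condensation quantification
for volumetric fluorescence microscopy (e.g. DAPI stacks).

A volume is tiled into 5×5×z cubic patches. Inside each patch, sampling
planes ("hyperplanes") connect every column of the bottom slice with every
column of the top slice along 3D Bresenham lines (25 planes per lateral
family), and the axial slices form a third family. Each plane is summarised
by five sorted intensity/difference patterns (global, square-ring,
circular-ring, angular differences, radial differences) compressed by fixed
±1 random projections; per plane family the projected values are pooled
into 16-bin histograms, giving an 80-dim block per family and a 240-dim
descriptor per patch. A pseudo-3D variant keeps only the slice-wise family
(80-dim). On top of the patch descriptors the package provides:

- **BOVW / Fisher-vector encoding** of a volume's descriptor set
  (k-means codebook with automated elbow selection of k; diagonal-GMM
  Fisher vectors of dimension 2·G·D),
- **chromatin condensation ratios** per nucleus — an intensity measure and
  an aggregation (gradient) measure, both thresholded at the minimum
  non-zero per-patch maximum of the retained projected values — with
  Wilcoxon rank-sum group comparison,
- **SVM-RBF classification** under grouped 10-fold cross-validation
  (image-level folds, per-fold codebook/scaler/gamma fitting with the
  median heuristic), plus Kruskal–Wallis and paired-design t-test model
  comparisons,
- **synthetic nucleus phantoms** — ellipsoidal nuclei with controllable
  condensed-chromatin foci — so the whole pipeline is testable without
  external data.

## Library quick start

```python
import numpy as np
from srp3d import make_rp_bank, describe_volume
from srp3d.chromatin import measure_volume, compare_groups
from srp3d.phantoms import generate_cohorts

bank = make_rp_bank(n=2, seed=42)          # one bank per analysis run
vols = generate_cohorts(10, seed=7)        # 10 condensed + 10 open phantoms

dset = describe_volume(vols[0].values, bank, mode="3d")
print(dset.matrix().shape)                 # (n_patches, 240)
print(measure_volume(dset))                # HC/EC intensity + aggregation
```

## CLI

The console script `srp3d` ties the pipeline together. All commands take
`--seed` and are byte-reproducible.

```sh
# generate labelled phantom cohorts (TIFF stacks + labels.csv + params.json)
srp3d simulate --out cohort/ --n-per-class 10 --seed 7

# per-patch descriptors, one TSV per volume (origin x,y,z + 240 values)
srp3d features cohort/*.tif --out-dir feats/ --mode 3d --seed 42

# encode descriptor tables into one vector per image (BOVW or FV)
srp3d encode feats/*.descriptors.tsv --out encoded.csv --method bovw --k 64

# condensation ratios per nucleus + rank-sum group comparison
srp3d chromatin cohort/*.tif --labels cohort/labels.csv --out ratios.csv

# grouped 10-fold CV from a feature table (id, group, label, features...)
srp3d classify table.csv --out cv.json --folds 10 --seed 42
```

Volumes are multi-page grayscale TIFFs, read as `(x, y, z)` arrays with z
the page index. Nuclei can be cropped from full fields with
`srp3d.io.crop_objects(volume, label_mask, pad)` given a precomputed
instance label mask (segmentation itself is out of scope).

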