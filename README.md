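# condquant

Quantitative analysis of nuclear biomolecular condensates from
multichannel 3D fluorescence microscopy, with companion statistics for
FRAP dynamics and in vitro DNA-binding selections. The package was built
for studies of oncogenic fusion proteins (e.g. ZFTA–RELA in ependymoma)
that form nuclear puncta, but every component is generic.

It provides four analyses plus the synthetic ground-truth generators used
to validate them:

1. **Puncta detection and density** — nucleus segmentation from DAPI,
   in-nucleus spot detection (built-in quantile detector or imported
   pixel-classifier masks), per-cell density as puncta per 100 µm³, and
   the two QC exclusions applied before comparisons: nuclei < 200 µm³ and
   the lowest intensity third of expressing cells per condition.
2. **Condensate-centered colocalization profiles** — for each condensate a
   61×61-px box gathers a partner channel over the condensate's z-extent,
   min–max normalized per locus and averaged into a heatmap matrix. An
   equal number of unique random in-nucleus loci per cell, with matched
   random z-windows, provides the null. An RNA-FISH mode centers boxes on
   FISH loci and gathers reporter intensities instead.
3. **FRAP recovery curves** — double normalization
   v(t) = [(ROI−bg)/(nucleus−bg)] / prebleach mean, which cancels
   acquisition photobleaching exactly; ensemble mean ± s.d. with a LOESS
   smooth, and an optional exponential fit reporting mobile fraction and
   half-time.
4. **CSI/SELEX motif ranking** — demultiplex barcoded amplicon reads,
   extract the 20-bp randomized region between constant flanks, count
   k-mers (default k = 6) and rank them by the frequency ratio
   (f_pos + p)/(f_neg + p) against the fusion-negative control pool,
   per selection round.

## Worked example

Run the whole pipeline on a self-generated synthetic dataset:

```sh
condquant all --seed 1 -o run1
```

which writes per-stage artifacts (OME-TIFF stack and ground truth, label
masks, puncta/cell CSVs, QC table, profile matrices, FRAP ensemble,
enrichment TSVs) plus a manifest of seeds and checksums, and prints

```
run complete; manifest at run1/manifest.json
```

The library surface mirrors the stages. For example, planting perfect
colocalization and recovering it:

```python
from condquant.synthetic_data import SyntheticImageParams, generate_image
from condquant import segmentation as seg, coloc_profile as cp
from condquant.io_images import rescale_16bit

params = SyntheticImageParams(coloc_fraction=1.0, n_puncta_per_nucleus=10,
                              min_center_distance=9.0, seed=42)
stack, truth = generate_image(params)
nuclei = seg.segment_nuclei(stack.channel("dapi"))
mask = seg.segment_puncta_builtin(rescale_16bit(stack.channel("reporter")), nuclei)
cells = seg.extract_puncta(mask, nuclei, stack.channel("reporter"), params.voxel_size)

mats, _ = cp.condensate_profiles(cells, stack.channel("partner"))
null_mats, _ = cp.null_profiles(cells, stack.channel("partner"), seed=2)
print(len(mats), cp.ratio_of_means(mats)[0], cp.ratio_of_means(null_mats)[0])
```

prints (for this seed)

```
10 4.137270365837064 0.9254846749075644
```

i.e. all ten planted puncta were detected, the partner signal is ~4-fold
enriched at condensate centers relative to the box edge, while the matched
random-locus null is consistent with 1 (no enrichment), as it must be when
colocalization is real rather than an intensity artifact.

The `csi` stage ends with a one-line summary, e.g.

```
top 6-mer in round 3: GGCCCC (enrichment 122.000 over the fusion-negative pool)
```

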