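# Methods

This note documents the models, conventions and numerical choices behind
`condquant`. It is the package's own account of what it computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Conventions

Voxel coordinates are 0-based and `(z, y, x)` ordered; bounding boxes are
half-open `(z0, z1, y0, y1, x0, x1)`. Physical voxel sizes are micrometres
per axis, default `(0.2, 0.11, 0.11)` µm — 110-nm lateral pixels with
0.2-µm z steps, typical of spinning-disk confocal acquisition at 100×.
All 3D connectivity is 26-neighbour. Channel intensity rescaling maps the
channel minimum to 0 and maximum to 65535 with round-half-even; a constant
channel maps to all zeros, and the same degenerate min==max rule is used
wherever a min–max normalization appears.

## Synthetic data

The generators define the conditions under which every pipeline property
is tested, so their assumptions matter.

**Image stacks.** Nuclei are axis-aligned ellipsoids of constant DAPI
level. Puncta are isotropic-in-pixels 3D Gaussians (default σ = 1.5
voxels, amplitude 8000 on background 200) truncated at 4σ; this mimics the
diffraction-limited appearance of condensates without a full PSF model.
Punctum centers are integer voxels sampled uniformly inside the ellipsoid
(scaled by 0.95 so centers stay strictly interior); an optional minimum
center separation supports resolvability experiments (6σ separation
guarantees the detector cannot merge spots). The partner channel places
`round(coloc_fraction * n)` of its spots exactly at reporter centers and
the rest at fresh uniform in-nucleus positions, so the colocalized mass
fraction is within `1/n` of the requested value by construction. Noise is
additive Gaussian clipped to the unsigned 16-bit range; Poisson shot
noise, camera gain, chromatic shift and drift are deliberately out of
scope. Recorded ground-truth z-extents are computed from the Gaussian
profile as the slices where the spot can exceed background + 3·noise_sd
(capped at the 4σ truncation), so they bound the detectable support.

**FRAP traces.** The bleach-ROI signal is
`background + scale·e^(−β t)·s(t) + ε`, where β is the whole-field
acquisition photobleaching rate and `s(t)` is 1 before the bleach and
`(1−d) + d·m·(1−e^(−k(t−t_b)))` after it (d bleach depth, m mobile
fraction, k recovery rate). The whole-nucleus signal carries only the β
decay. Defaults: 5 prebleach frames, 1 s per frame, scale 100,
background 50. `d = 0` is allowed as the no-bleach control that
demonstrates the double normalization cancels acquisition photobleaching
exactly.

**Selection read pools.** Each read is
`barcode + left flank + 20-bp variable region + right flank` with constant
Q37 qualities, written as gzip FASTQ (header mtime pinned to zero so
reruns are byte-identical). A planted motif is embedded at a uniform
random offset in a per-round fraction of positive-sample reads (default
0.05 / 0.15 / 0.40 over three rounds, emulating progressive selection);
the negative-control sample carries the motif in no read at any round,
modelling fusion-negative lysate. All other bases are i.i.d. uniform —
real selections also enrich motif variants and carry sequencing error,
neither of which is modelled, so motif-recovery results here bound the
idealized case only.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2), Otsu threshold, 3D hole filling,
26-connected components, removal below `min_volume_vox` (default 1000),
labels renumbered by descending volume with ties broken by first-voxel
raster order. Touching nuclei are not split (no watershed) — a documented
limitation.

Puncta: the reference detector thresholds each nucleus at its own
`threshold_quantile` (default 0.995) of reporter intensity and keeps
26-connected components of at least `min_spot_vox` (default 5) voxels.
Because the threshold is a rank statistic, detection is invariant under
constant intensity offsets. These defaults give recall = precision = 1.0
on planted spots at SNR ≥ 10 with ≥ 6σ separation (verified in the
acceptance suite). Externally trained pixel-classifier output can be
imported instead, either as a probability volume (thresholded at 0.5 and
relabelled) or as a label volume (size-filtered only); both are cropped to
nuclei exactly like the built-in path, so downstream geometry is
comparable.

Per-punctum centroids are intensity-weighted by default (binary centroids
by flag); a punctum straddling two nuclei is assigned to the nucleus
holding its centroid and flagged. "Cell volume" means nucleus volume
throughout: the DAPI mask is the only compartment segmented, and no
whole-cell marker is modelled.

## Density and QC

Puncta density is `100 × n_puncta / nucleus volume` (per 100 µm³). Two
exclusions apply before any comparison, in order: (1) nuclei with volume
strictly below 200 µm³ (mis-segmented or out-of-frame cells); (2) per
condition, the `floor(n/3)` cells with the lowest mean reporter intensity
among the remaining expressing cells (dim cells pick up diffuse signal
from bright neighbours and yield false-positive spots). The tercile is
rank-based; ties break by cell id, and an optional expression floor
excludes non-expressing cells from the ranking without dropping them. Both
filters commute with cell relabelling, and the expression filter is
invariant under any strictly monotone intensity transform.

## Colocalization box profiles

For each condensate, a 61×61-pixel box is centered on the centroid
(rounded to the nearest voxel). Target-channel intensities are gathered
over the condensate's own bounding-box z-slices, the whole per-locus block
is min–max normalized to [0, 1], averaged along z, and the per-locus
matrices are averaged into one profile. Normalizing per locus (rather than
globally) makes the profile invariant under affine intensity transforms
and lets loci of different brightness contribute equally; it is also the
only normalization that is well defined before the cross-locus average.
Loci closer than 30 px to a lateral border are skipped and counted, not
padded — padding would distort the normalization.

The null profile repeats the identical gathering code path at an equal
number of unique random locations per cell. Each candidate center must
keep the full 61×61 footprint inside the 2D projection of the nucleus mask
over the sampled z-window; the window's integer length is uniform between
the smallest and largest condensate z-extent of that cell, and the window
is centered on the nucleus mid-plane at that `(y, x)` (shifted to stay
inside the stack) — only the length is prescribed by the matching rule, so
the placement is a declared choice. Rejection sampling from a per-cell
seeded generator makes accepted centers uniform over the feasible region
and the whole construction reproducible.

The RNA-FISH mode swaps roles: boxes center on FISH loci (detected by the
same spot detector on the FISH channel) and gather reporter intensities,
with a matched null.

The scalar summary is the mean over the central 11×11 patch divided by the
mean over the outermost 1-pixel ring; `ratio_of_means` pools per-locus
patch means and reports a delta-method standard error for the ratio. On
synthetic data the centered ratio increases strictly with the planted
colocalized fraction (≈1.0 / ≈2.2 / ≈3.6 at fractions 0 / 0.5 / 1 under
the default conditions) while the null ratio stays within sampling error
of 1.

## FRAP

Normalization is done twice: `v(t) = [(ROI−bg)/(nucleus−bg)](t)` divided
by its prebleach mean (all prebleach frames), so the prebleach level is 1
exactly, shared gain cancels, and any multiplicative whole-field decay
common to ROI and nucleus cancels identically. The nucleus term is
measured on the single imaged plane (FRAP movies are 2D). The ensemble
curve is the pointwise mean ± s.d. across cells with a LOESS smooth
through the means (span 0.3 by default; the method, not the span, is the
convention). An optional single-exponential fit
`v(t') = v_b + (plateau − v_b)(1 − e^(−k t'))` reports
`mobile fraction = (plateau − v_b)/(1 − v_b)` and `half-time = ln2/k`;
reaction–diffusion models and bleach-spot geometry corrections are out of
scope.

## Motif enrichment

Reads are demultiplexed by exact 5' barcode (a mismatch tolerance exists
but barcodes must remain prefix-free at that level; ambiguous reads are
dropped and counted). The 20-bp variable region is accepted when both
flanks match within one mismatch and the region is pure ACGT. k-mers
(default k = 6, the length of the identified GGCCCC binding site;
configurable 4–10) are counted over all sliding windows; counts always sum
to the number of scored windows. Enrichment of a k-mer is
`(f_pos + p)/(f_neg + p)` with frequencies per window and symmetric
pseudofrequency `p = 1/max(total windows)` of the two pools — a ratio
rather than a difference so the statistic is depth-free, with the
pseudofrequency guarding rare k-mers. Tables are ranked by descending
enrichment with lexicographic tie-break. The round trajectory reports each
k-mer's enrichment per round against the matched negative round and flags
strictly increasing trajectories. Reverse-complement counting is off by
default: selection acts on double-stranded DNA but the binding site is
reported single-strandedly.

## Pipeline determinism

Every stochastic stage draws from a seed derived by SHA-256 from
`master_seed:stage_name` (taken mod 2³¹), so adding a stage never perturbs
another stage's draws. OME-TIFF UUIDs are content-derived and gzip headers
carry no timestamp, so a rerun with the same config and master seed
reproduces every artifact checksum; the run manifest records config,
seeds, library versions and per-artifact SHA-256.

## Problem sizes

Test and acceptance runs use stacks of 24×192×192–24×224×224 voxels with
1–2 nuclei and 6–40 puncta per nucleus, 19-cell FRAP ensembles of 125
frames, and selection pools of 10 000 reads per round — sizes chosen so
each statistic is estimated with comfortable margin while a full run of
the suite plus the acceptance script completes in about a minute.

## Known limitations

Uniform-in-ellipsoid spot placement makes the random-locus null exactly
matched by construction; real chromatin and staining textures are not
uniform, so passing the null-flatness checks here demonstrates
correctness of the construction, not that real backgrounds are flat.
No watershed splitting of touching nuclei; no Poisson noise; no motif
variants or sequencing error in the selection model; single-exponential
FRAP recovery only.
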