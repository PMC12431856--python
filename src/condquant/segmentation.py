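"""Nucleus and puncta segmentation, and per-punctum geometry extraction.

The nucleus path is classical: Gaussian smoothing, Otsu threshold, 3D hole
filling, 26-connected components, small-object removal.  Puncta come either
from the built-in per-nucleus quantile-threshold detector or from an
imported label/probability volume produced by an external pixel classifier;
both paths feed the same geometry extraction so results are directly
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure

from .io_images import read_mask

__all__ = [
    "NucleusRegion",
    "Punctum",
    "PunctaSet",
    "segment_nuclei",
    "segment_puncta_builtin",
    "import_puncta_mask",
    "extract_puncta",
    "puncta_to_frame",
]

#: 26-connectivity structuring element used for all 3D labelling.
_STRUCT3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleusRegion:
    """One segmented nucleus: mask, physical volume and intensity means."""

    nucleus_id: int
    mask: np.ndarray  # boolean, full stack shape
    volume_um3: float
    bbox: tuple  # half-open (z0, z1, y0, y1, x0, x1)
    mean_intensity_by_channel: dict = field(default_factory=dict)


@dataclass
class Punctum:
    """One detected condensate with voxel geometry and intensity stats."""

    punctum_id: int
    nucleus_id: int
    centroid: tuple  # (z, y, x), possibly fractional
    bbox: tuple  # half-open (z0, z1, y0, y1, x0, x1)
    z_extent: int
    volume_um3: float
    mean_intensity: float
    max_intensity: float
    flagged_straddling: bool = False


@dataclass
class PunctaSet:
    """All puncta of one cell plus the cell itself."""

    cell: NucleusRegion
    puncta: list
    condition: str = ""


def _relabel_by_volume(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n by descending voxel count.

    Ties broken by ascending first-voxel raster order, so the output is a
    pure function of the geometry.
    """
    flat = labels.ravel()
    ids, first_voxel, counts = np.unique(flat, return_index=True, return_counts=True)
    keep = ids > 0
    ids, first_voxel, counts = ids[keep], first_voxel[keep], counts[keep]
    if ids.size == 0:
        return labels.astype(np.int32)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], first_voxel[i]))
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new, i in enumerate(order, start=1):
        lut[ids[i]] = new
    return lut[labels]


def segment_nuclei(
    dapi_channel: np.ndarray,
    min_volume_vox: int = 1000,
    smoothing_sigma: float = 2.0,
) -> np.ndarray:
    """Segment nuclei from a 3D DAPI channel.

    Gaussian smoothing, Otsu threshold, 3D hole filling, 26-connected
    components, removal of components below ``min_volume_vox``; surviving
    labels are numbered by descending volume.
    """
    if dapi_channel.ndim != 3:
        raise ValueError("dapi_channel must be 3D (z, y, x)")
    smoothed = filters.gaussian(dapi_channel.astype(np.float64), sigma=smoothing_sigma,
                                preserve_range=True)
    if smoothed.max() == smoothed.min():
        warnings.warn("constant DAPI channel: no nuclei found", stacklevel=2)
        return np.zeros(dapi_channel.shape, dtype=np.int32)
    bw = smoothed > filters.threshold_otsu(smoothed)
    bw = ndi.binary_fill_holes(bw)
    labels, _ = ndi.label(bw, structure=_STRUCT3D)
    if min_volume_vox > 1:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_volume_vox]
        if small.size:
            labels[np.isin(labels, small)] = 0
    labels = _relabel_by_volume(labels)
    if labels.max() == 0:
        warnings.warn("all-background segmentation result", stacklevel=2)
    return labels


def segment_puncta_builtin(
    reporter_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    threshold_quantile: float = 0.995,
    min_spot_vox: int = 5,
) -> np.ndarray:
    """Detect puncta inside nuclei by per-nucleus quantile thresholding.

    Within each nucleus, voxels above that nucleus's ``threshold_quantile``
    intensity quantile become spot candidates; 26-connected components below
    ``min_spot_vox`` voxels are dropped.  Voxels outside nuclei are never
    labelled.  Because the threshold is a rank statistic, the label count is
    invariant under any constant intensity offset.
    """
    if reporter_channel.shape != nucleus_mask.shape:
        raise ValueError(
            f"nucleus_mask shape {nucleus_mask.shape} does not match "
            f"reporter {reporter_channel.shape}"
        )
    candidates = np.zeros(reporter_channel.shape, dtype=bool)
    for nid in np.unique(nucleus_mask[nucleus_mask > 0]):
        inside = nucleus_mask == nid
        vals = reporter_channel[inside]
        if vals.max() == vals.min():
            continue
        th = np.quantile(vals, threshold_quantile)
        candidates |= inside & (reporter_channel > th)
    labels, _ = ndi.label(candidates, structure=_STRUCT3D)
    if min_spot_vox > 1:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_spot_vox]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return _relabel_by_volume(labels)


def import_puncta_mask(
    source: str | Path | np.ndarray,
    nucleus_mask: np.ndarray,
    probability_cutoff: float = 0.5,
    min_spot_vox: int = 5,
    kind: str = "auto",
) -> np.ndarray:
    """Import an externally generated puncta mask (pixel-classifier output).

    ``kind`` is ``"probability"`` (float volume in [0, 1], thresholded at
    ``probability_cutoff`` and relabelled), ``"labels"`` (integer label
    volume, size-filtered only) or ``"auto"`` (floats are probabilities,
    integers are labels).  Either way the result is cropped to the nuclei,
    exactly as the built-in detector.
    """
    volume = read_mask(source) if isinstance(source, (str, Path)) else np.asarray(source)
    if volume.shape != nucleus_mask.shape:
        raise ValueError(
            f"mask shape {volume.shape} does not match nuclei {nucleus_mask.shape}"
        )
    if kind == "auto":
        kind = "probability" if volume.dtype.kind == "f" else "labels"
    if kind == "probability":
        if volume.min() < 0.0 or volume.max() > 1.0:
            raise ValueError("probability volume has values outside [0, 1]")
        bw = (volume > probability_cutoff) & (nucleus_mask > 0)
        labels, _ = ndi.label(bw, structure=_STRUCT3D)
    elif kind == "labels":
        labels = volume.astype(np.int64).copy()
        labels[nucleus_mask == 0] = 0
    else:
        raise ValueError(f"kind must be 'probability', 'labels' or 'auto', not {kind!r}")
    if min_spot_vox > 1:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_spot_vox]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return _relabel_by_volume(labels)


def extract_puncta(
    puncta_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    reporter_channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    intensity_weighted: bool = True,
    condition: str = "",
    extra_channels: dict | None = None,
) -> list[PunctaSet]:
    """Turn label masks into one :class:`PunctaSet` per nucleus.

    Centroids are intensity-weighted by default (binary-mask centroids with
    ``intensity_weighted=False``).  A punctum whose voxels straddle two
    nuclei is assigned to the nucleus holding its centroid and flagged.
    Nuclei without puncta still yield a PunctaSet so cell-level metrics stay
    computable.
    """
    if puncta_mask.shape != nucleus_mask.shape or reporter_channel.shape != nucleus_mask.shape:
        raise ValueError("puncta_mask, nucleus_mask and reporter must share a shape")
    dz, dy, dx = voxel_size
    voxel_vol = dz * dy * dx

    cells: dict[int, PunctaSet] = {}
    for nid in np.unique(nucleus_mask[nucleus_mask > 0]):
        mask = nucleus_mask == nid
        nzyx = np.argwhere(mask)
        lo = nzyx.min(axis=0)
        hi = nzyx.max(axis=0) + 1
        means = {"reporter": float(reporter_channel[mask].mean())}
        for label, chan in (extra_channels or {}).items():
            means[label] = float(chan[mask].mean())
        cell = NucleusRegion(
            nucleus_id=int(nid),
            mask=mask,
            volume_um3=float(mask.sum()) * voxel_vol,
            bbox=(int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2])),
            mean_intensity_by_channel=means,
        )
        cells[int(nid)] = PunctaSet(cell=cell, puncta=[], condition=condition)

    for prop in measure.regionprops(puncta_mask, intensity_image=reporter_channel):
        centroid = prop.centroid_weighted if intensity_weighted else prop.centroid
        z0, y0, x0, z1, y1, x1 = (*prop.bbox[:3], *prop.bbox[3:])
        anchor = tuple(int(np.rint(c)) for c in centroid)
        anchor = tuple(np.clip(a, 0, s - 1) for a, s in zip(anchor, nucleus_mask.shape))
        owners = np.unique(nucleus_mask[tuple(prop.coords.T)])
        owners = owners[owners > 0]
        nid = int(nucleus_mask[anchor])
        if nid == 0:
            if owners.size == 0:
                continue  # punctum entirely outside nuclei: ignore
            # centroid voxel fell in background; use the majority owner
            counts = [(int((nucleus_mask[tuple(prop.coords.T)] == o).sum()), int(o))
                      for o in owners]
            nid = max(counts)[1]
        straddles = owners.size > 1
        p = Punctum(
            punctum_id=int(prop.label),
            nucleus_id=nid,
            centroid=tuple(float(c) for c in centroid),
            bbox=(z0, z1, y0, y1, x0, x1),
            z_extent=int(z1 - z0),
            volume_um3=float(prop.area) * voxel_vol,
            mean_intensity=float(prop.intensity_mean),
            max_intensity=float(prop.intensity_max),
            flagged_straddling=bool(straddles),
        )
        if nid in cells:
            cells[nid].puncta.append(p)
    return [cells[k] for k in sorted(cells)]


def puncta_to_frame(puncta_sets: list[PunctaSet]) -> pd.DataFrame:
    """Flatten PunctaSets into one row per punctum for CSV export."""
    rows = []
    for ps in puncta_sets:
        for p in ps.puncta:
            rows.append(
                {
                    "condition": ps.condition,
                    "nucleus_id": p.nucleus_id,
                    "punctum_id": p.punctum_id,
                    "centroid_z": p.centroid[0],
                    "centroid_y": p.centroid[1],
                    "centroid_x": p.centroid[2],
                    "z0": p.bbox[0], "z1": p.bbox[1],
                    "y0": p.bbox[2], "y1": p.bbox[3],
                    "x0": p.bbox[4], "x1": p.bbox[5],
                    "z_extent": p.z_extent,
                    "volume_um3": p.volume_um3,
                    "mean_intensity": p.mean_intensity,
                    "max_intensity": p.max_intensity,
                    "flagged_straddling": p.flagged_straddling,
                }
            )
    return pd.DataFrame(rows)
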