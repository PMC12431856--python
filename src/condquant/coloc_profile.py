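"""Locus-centered box profiles and the matched in-nucleus random null.

For every detected condensate a 61×61-pixel box is placed around its
centroid; the target-channel intensities in that box are gathered over the
condensate's own z-slices, min–max normalized to [0, 1] per locus, averaged
along z, and finally averaged over all loci into one matrix (rendered as a
heatmap downstream).  The null repeats the identical gathering at an equal
number of unique random in-nucleus locations per cell, with a random
z-window length drawn between the smallest and largest condensate z-extent
of that cell.  An RNA-FISH mode swaps the roles: boxes centered on FISH
loci, intensities gathered from the reporter channel.

Per-locus normalization makes every profile invariant under affine
intensity transforms of the target channel, so loci of very different
brightness contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .segmentation import NucleusRegion, Punctum, PunctaSet

__all__ = [
    "BoxProfile",
    "RandomLocus",
    "EnrichmentSummary",
    "LocusOutOfBounds",
    "extract_box_profile",
    "condensate_profiles",
    "average_profiles",
    "sample_random_loci",
    "profile_random_null",
    "fish_locus_profiles",
    "enrichment_summary",
    "ratio_of_means",
]


class LocusOutOfBounds(ValueError):
    """Raised when a box footprint would leave the lateral image bounds."""


@dataclass
class BoxProfile:
    """An averaged, per-locus-normalized box profile."""

    matrix: np.ndarray  # box_size x box_size, entries in [0, 1]
    n_loci: int
    channel: str = ""
    mode: str = "condensate-centered"  # | "random-null" | "fish-centered"

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter=",")
        return path

    def save_heatmap(self, path: str | Path, cmap: str = "magma") -> Path:
        """Render the averaged matrix as a PNG heatmap (no smoothing)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.matrix, cmap=cmap, interpolation="nearest")
        ax.set_title(f"{self.mode} ({self.channel}, n={self.n_loci})", fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, fraction=0.046)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return Path(path)


@dataclass
class RandomLocus:
    """A random in-nucleus measurement box matched to one condensate."""

    cell_id: int
    center: tuple  # (y, x) voxels
    z0: int
    z1: int  # half-open z-window

    @property
    def z_length(self) -> int:
        return self.z1 - self.z0


@dataclass
class EnrichmentSummary:
    """Scalar center-vs-edge summary of a BoxProfile."""

    central_mean: float
    edge_mean: float
    ratio: float
    degenerate_edge: bool = False


def _normalized_box(
    channel: np.ndarray, center_yx: tuple, z0: int, z1: int, box_size: int
) -> np.ndarray:
    """Gather, normalize and z-average one box; shared by every profile mode.

    Takes the ``box_size``² patch around ``center_yx`` on each z-slice in
    ``[z0, z1)``, min–max normalizes the whole per-locus block to [0, 1]
    (constant block → all zeros), and averages along z.
    """
    half = box_size // 2
    y, x = center_yx
    nz, ny, nx = channel.shape
    if y - half < 0 or y + half >= ny or x - half < 0 or x + half >= nx:
        raise LocusOutOfBounds(
            f"box footprint at (y={y}, x={x}) leaves the {ny}x{nx} image"
        )
    if not 0 <= z0 < z1 <= nz:
        raise ValueError(f"invalid z-window [{z0}, {z1}) for nz={nz}")
    block = channel[z0:z1, y - half : y + half + 1, x - half : x + half + 1]
    block = block.astype(np.float64)
    lo, hi = block.min(), block.max()
    if hi == lo:
        return np.zeros((box_size, box_size))
    return ((block - lo) / (hi - lo)).mean(axis=0)


def extract_box_profile(
    punctum: Punctum, channel: np.ndarray, box_size: int = 61
) -> np.ndarray:
    """The normalized box profile of one condensate.

    The box is centered on the centroid rounded to the nearest voxel and
    spans the punctum's own bounding-box z-slices.  Raises
    :class:`LocusOutOfBounds` when the centroid is nearer than
    ``box_size // 2`` pixels to a lateral border (callers skip and count
    such loci rather than pad, which would distort the normalization).
    """
    if punctum.z_extent < 1:
        raise ValueError("punctum with empty z-extent")
    _, y, x = (int(np.rint(c)) for c in punctum.centroid)
    z0, z1 = punctum.bbox[0], punctum.bbox[1]
    return _normalized_box(channel, (y, x), z0, z1, box_size)


def condensate_profiles(
    puncta_sets: list[PunctaSet], channel: np.ndarray, box_size: int = 61
) -> tuple[list[np.ndarray], int]:
    """Box profiles for every punctum; returns (matrices, n_skipped).

    Loci too close to the lateral border are skipped and counted.
    """
    matrices, skipped = [], 0
    for ps in puncta_sets:
        for p in ps.puncta:
            try:
                matrices.append(extract_box_profile(p, channel, box_size))
            except LocusOutOfBounds:
                skipped += 1
    return matrices, skipped


def average_profiles(
    matrices: list[np.ndarray], mode: str, channel: str = ""
) -> BoxProfile:
    """Element-wise mean over per-locus matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    return BoxProfile(
        matrix=np.mean(matrices, axis=0), n_loci=len(matrices),
        channel=channel, mode=mode,
    )


def _mid_plane(mask: np.ndarray, y: int, x: int) -> int | None:
    zs = np.flatnonzero(mask[:, y, x])
    if zs.size == 0:
        return None
    return int((zs[0] + zs[-1]) // 2)


def sample_random_loci(
    cell: NucleusRegion,
    puncta: list[Punctum],
    box_size: int = 61,
    seed: int = 0,
    max_tries_per_locus: int = 2000,
) -> list[RandomLocus]:
    """Sample one unique random in-nucleus locus per condensate of a cell.

    Each locus gets a z-window whose integer length is uniform between the
    smallest and largest condensate z-extent of the cell, centered on the
    nucleus-mask mid-plane at the sampled (y, x) and shifted to stay inside
    the stack.  The full ``box_size``² footprint must fall inside the
    nucleus mask's 2D projection over that z-window; candidates are drawn
    by rejection sampling from a per-cell deterministic generator, so the
    accepted centers are uniform over the feasible region.
    """
    if not puncta:
        raise ValueError("cell has no puncta; the null is matched per punctum")
    rng = np.random.default_rng(seed)
    mask = cell.mask
    nz, ny, nx = mask.shape
    half = box_size // 2
    zmin = min(p.z_extent for p in puncta)
    zmax = max(p.z_extent for p in puncta)
    proj_any = mask.any(axis=0)
    ys, xs = np.nonzero(proj_any)
    y_lo, y_hi = ys.min(), ys.max()
    x_lo, x_hi = xs.min(), xs.max()

    loci: list[RandomLocus] = []
    used: set = set()
    budget = max_tries_per_locus * len(puncta)
    while len(loci) < len(puncta):
        if budget <= 0:
            raise RuntimeError(
                f"cell {cell.nucleus_id}: could not place {len(puncta)} "
                f"{box_size}x{box_size} boxes inside the nucleus "
                "(nucleus too small for the box)"
            )
        budget -= 1
        y = int(rng.integers(max(y_lo, half), min(y_hi, ny - 1 - half) + 1)) \
            if y_hi >= y_lo and min(y_hi, ny - 1 - half) >= max(y_lo, half) else None
        if y is None:
            raise RuntimeError(
                f"cell {cell.nucleus_id}: nucleus 2D extent smaller than the "
                f"{box_size}x{box_size} box"
            )
        if min(x_hi, nx - 1 - half) < max(x_lo, half):
            raise RuntimeError(
                f"cell {cell.nucleus_id}: nucleus 2D extent smaller than the "
                f"{box_size}x{box_size} box"
            )
        x = int(rng.integers(max(x_lo, half), min(x_hi, nx - 1 - half) + 1))
        if (y, x) in used:
            continue
        mid = _mid_plane(mask, y, x)
        if mid is None:
            continue
        length = int(rng.integers(zmin, zmax + 1))
        z0 = mid - (length - 1) // 2
        z0 = min(max(z0, 0), nz - length)  # shift to stay inside the stack
        z1 = z0 + length
        window_proj = mask[z0:z1].any(axis=0)
        if window_proj[y - half : y + half + 1, x - half : x + half + 1].all():
            loci.append(RandomLocus(cell_id=cell.nucleus_id, center=(y, x), z0=z0, z1=z1))
            used.add((y, x))
    return loci


def profile_random_null(
    cell: NucleusRegion,
    puncta: list[Punctum],
    channel: np.ndarray,
    box_size: int = 61,
    seed: int = 0,
) -> tuple[BoxProfile, list[RandomLocus]]:
    """The matched random-locus null profile for one cell.

    Identical gathering, normalization and z-averaging code path as the
    condensate-centered profile; only the box centers differ.
    """
    loci = sample_random_loci(cell, puncta, box_size=box_size, seed=seed)
    matrices = [
        _normalized_box(channel, locus.center, locus.z0, locus.z1, box_size)
        for locus in loci
    ]
    return average_profiles(matrices, mode="random-null"), loci


def null_profiles(
    puncta_sets: list[PunctaSet],
    channel: np.ndarray,
    box_size: int = 61,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[RandomLocus]]:
    """Per-locus null matrices pooled over cells (cells without puncta skip)."""
    matrices: list[np.ndarray] = []
    all_loci: list[RandomLocus] = []
    for ps in puncta_sets:
        if not ps.puncta:
            continue
        loci = sample_random_loci(
            ps.cell, ps.puncta, box_size=box_size, seed=seed + ps.cell.nucleus_id
        )
        for locus in loci:
            matrices.append(
                _normalized_box(channel, locus.center, locus.z0, locus.z1, box_size)
            )
        all_loci.extend(loci)
    return matrices, all_loci


def fish_locus_profiles(
    fish_puncta: list[PunctaSet],
    reporter_channel: np.ndarray,
    box_size: int = 61,
    seed: int = 0,
) -> tuple[BoxProfile, BoxProfile]:
    """Reporter-channel profiles centered on RNA-FISH loci, plus the null.

    The same machinery with the roles swapped: FISH loci (detected by the
    segmentation module on the FISH channel) define the box centers and the
    reporter channel supplies the intensities.  Cells without FISH loci
    contribute nothing.
    """
    matrices, _ = condensate_profiles(fish_puncta, reporter_channel, box_size)
    if not matrices:
        raise ValueError("no FISH loci usable for profiling")
    fish_profile = average_profiles(matrices, mode="fish-centered", channel="reporter")
    null_mats, _ = null_profiles(fish_puncta, reporter_channel, box_size, seed=seed)
    null_profile = average_profiles(null_mats, mode="random-null", channel="reporter")
    return fish_profile, null_profile


def ratio_of_means(matrices: list[np.ndarray], central_size: int = 11) -> tuple[float, float]:
    """Center/edge enrichment ratio pooled over loci, with its standard error.

    The ratio is mean(central) / mean(edge) over per-locus central-patch and
    edge-ring means (identical to the ratio of the averaged profile); the
    standard error comes from the delta method for a ratio of correlated
    means.
    """
    if not matrices:
        raise ValueError("no matrices")
    n = matrices[0].shape[0]
    c, h = n // 2, central_size // 2
    central = np.array([m[c - h : c + h + 1, c - h : c + h + 1].mean() for m in matrices])
    edge = np.array([
        np.concatenate([m[0, :], m[-1, :], m[1:-1, 0], m[1:-1, -1]]).mean()
        for m in matrices
    ])
    if edge.mean() == 0:
        return float("inf"), float("nan")
    ratio = central.mean() / edge.mean()
    k = len(matrices)
    if k < 2:
        return float(ratio), float("nan")
    vc = central.var(ddof=1) / k
    ve = edge.var(ddof=1) / k
    cov = np.cov(central, edge, ddof=1)[0, 1] / k
    var = ratio**2 * (
        vc / central.mean() ** 2 + ve / edge.mean() ** 2
        - 2.0 * cov / (central.mean() * edge.mean())
    )
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def enrichment_summary(profile: BoxProfile, central_size: int = 11) -> EnrichmentSummary:
    """Center-vs-edge scalar summary of a profile matrix.

    ``central_mean`` averages the centered ``central_size``² patch,
    ``edge_mean`` the outermost 1-pixel ring; ``ratio`` is their quotient
    (+inf sentinel with a flag when the edge is exactly zero).
    """
    m = profile.matrix
    n = m.shape[0]
    if central_size % 2 == 0 or central_size >= n:
        raise ValueError("central_size must be odd and smaller than the box")
    c = n // 2
    h = central_size // 2
    central = float(m[c - h : c + h + 1, c - h : c + h + 1].mean())
    ring = np.concatenate([m[0, :], m[-1, :], m[1:-1, 0], m[1:-1, -1]])
    edge = float(ring.mean())
    if edge == 0.0:
        return EnrichmentSummary(central, edge, float("inf"), degenerate_edge=True)
    return EnrichmentSummary(central, edge, central / edge)
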