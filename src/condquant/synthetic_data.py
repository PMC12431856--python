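"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Three generators, each a pure function of its parameter object (the seed
fully determines the output):

* :func:`generate_image` — multichannel 3D stacks containing ellipsoidal
  nuclei with diffraction-limited Gaussian puncta in a reporter channel and
  a partner channel whose spot mass colocalizes with the reporter puncta at
  a tunable fraction;
* :func:`generate_frap` — photobleaching recovery traces with known bleach
  depth, mobile fraction, recovery rate and whole-field acquisition
  photobleaching;
* :func:`generate_selex` — barcoded amplicon read pools over selection
  rounds with a planted motif whose abundance grows round over round in the
  positive sample and stays at zero in the negative control.

Spots are isotropic-in-pixels 3D Gaussians truncated at 4σ — the
diffraction-limited appearance without a full PSF model.  Noise is additive
Gaussian, clipped to the unsigned 16-bit range.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_images import ImageStack

__all__ = [
    "SyntheticImageParams",
    "ImageGroundTruth",
    "generate_image",
    "SyntheticFrapParams",
    "generate_frap",
    "SyntheticSelexParams",
    "generate_selex",
]

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# 3D image stacks

@dataclass
class SyntheticImageParams:
    """Parameters of a planted-puncta multichannel z-stack.

    ``nuclei`` is a list of ``(center, semi_axes, dapi_level)`` with center
    and semi-axes in voxels, ``(z, y, x)`` ordered.  ``coloc_fraction`` is
    the fraction of partner-channel spot mass placed exactly at reporter
    punctum centers; the remainder goes to uniform random in-nucleus
    positions.  The default voxel size mirrors spinning-disk acquisition at
    110-nm pixels with 0.2-µm z steps.
    """

    stack_shape: tuple[int, int, int] = (24, 192, 192)
    voxel_size: tuple[float, float, float] = (0.2, 0.11, 0.11)
    nuclei: list = field(
        default_factory=lambda: [((12, 96, 96), (9.0, 70.0, 70.0), 3000.0)]
    )
    n_puncta_per_nucleus: int = 10
    spot_sigma: tuple[float, float, float] = (1.5, 1.5, 1.5)
    spot_amplitude: float = 8000.0
    coloc_fraction: float = 1.0
    background_level: float = 200.0
    noise_sd: float = 50.0
    #: optional minimum voxel distance between planted reporter centers
    #: (set to 6x spot_sigma to guarantee resolvable, non-merging spots)
    min_center_distance: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_puncta_per_nucleus < 0:
            raise ValueError("n_puncta_per_nucleus must be non-negative")
        if any(s <= 0 for s in self.spot_sigma):
            raise ValueError("spot_sigma components must be positive")
        for i, (_, semi, _) in enumerate(self.nuclei):
            if any(a < 2 for a in semi):
                raise ValueError(f"nucleus {i}: all semi-axes must be >= 2 voxels")


@dataclass
class ImageGroundTruth:
    """Everything planted into a synthetic stack, in voxel coordinates."""

    nucleus_labels: np.ndarray
    #: per nucleus: list of (z, y, x) integer reporter punctum centers
    punctum_centers: list
    #: per nucleus: list of half-open (z0, z1) punctum z-extents
    punctum_z_extents: list
    #: per nucleus: partner spot centers (colocalized ones first)
    partner_centers: list
    #: per nucleus: how many partner spots sit at reporter centers
    n_coloc: list

    def all_centers(self) -> list:
        return [c for percell in self.punctum_centers for c in percell]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "punctum_centers": [[list(c) for c in cell] for cell in self.punctum_centers],
            "punctum_z_extents": [[list(e) for e in cell] for cell in self.punctum_z_extents],
            "partner_centers": [[list(c) for c in cell] for cell in self.partner_centers],
            "n_coloc": list(self.n_coloc),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _sample_in_ellipsoid(rng, center, semi, n, margin=0.95, min_distance=None):
    """Integer voxel positions strictly inside the ellipsoid (scaled by margin).

    With ``min_distance`` set, candidates closer than that (Euclidean, in
    voxels) to an already placed point are rejected.
    """
    out: list = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                f"could not place {n} points at min_distance={min_distance} "
                "inside the nucleus"
            )
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u ** 2).sum() > 1.0:
            continue
        p = tuple(int(round(c + m * a * margin)) for c, a, m in zip(center, semi, u))
        if min_distance is not None and any(
            sum((a - b) ** 2 for a, b in zip(p, q)) < min_distance**2 for q in out
        ):
            continue
        out.append(p)
    return out


def _add_spot(volume: np.ndarray, center, sigma, amplitude) -> None:
    """Add a 3D Gaussian truncated at 4σ (Mahalanobis) around an integer center."""
    nz, ny, nx = volume.shape
    cz, cy, cx = center
    hz, hy, hx = (int(math.ceil(4.0 * s)) for s in sigma)
    z0, z1 = max(cz - hz, 0), min(cz + hz + 1, nz)
    y0, y1 = max(cy - hy, 0), min(cy + hy + 1, ny)
    x0, x1 = max(cx - hx, 0), min(cx + hx + 1, nx)
    dz = (np.arange(z0, z1) - cz) / sigma[0]
    dy = (np.arange(y0, y1) - cy) / sigma[1]
    dx = (np.arange(x0, x1) - cx) / sigma[2]
    m2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2)
    spot = amplitude * np.exp(-0.5 * m2)
    spot[m2 > 16.0] = 0.0  # truncate at 4 sigma
    volume[z0:z1, y0:y1, x0:x1] += spot


def generate_image(params: SyntheticImageParams) -> tuple[ImageStack, ImageGroundTruth]:
    """Render a (reporter, partner, dapi) z-stack with planted puncta.

    Returns the stack (uint16, channel-first) and the ground truth listing
    every planted center, punctum z-extent and nucleus label volume.
    """
    shape = tuple(params.stack_shape)
    rng = np.random.default_rng(params.seed)

    nucleus_labels = np.zeros(shape, dtype=np.uint16)
    dapi = np.zeros(shape, dtype=np.float64)
    for i, (center, semi, level) in enumerate(params.nuclei):
        for ax in range(3):
            if center[ax] - semi[ax] < 0 or center[ax] + semi[ax] > shape[ax] - 1:
                raise ValueError(
                    f"nucleus {i} ellipsoid (center {tuple(center)}, semi-axes "
                    f"{tuple(semi)}) is not fully inside the stack {shape}"
                )
        mask = _ellipsoid_mask(shape, center, semi)
        nucleus_labels[mask] = i + 1
        dapi[mask] += level

    reporter = np.zeros(shape, dtype=np.float64)
    partner = np.zeros(shape, dtype=np.float64)

    sz = params.spot_sigma
    # z half-extent of the voxels a spot can raise above background + 3*noise_sd
    if params.noise_sd > 0 and params.spot_amplitude > 3.0 * params.noise_sd:
        h = sz[0] * math.sqrt(2.0 * math.log(params.spot_amplitude / (3.0 * params.noise_sd)))
        h = min(h, 4.0 * sz[0])
    else:
        h = 4.0 * sz[0]  # truncation radius bounds the support

    centers_per_cell: list = []
    zext_per_cell: list = []
    partner_per_cell: list = []
    n_coloc_per_cell: list = []
    n = params.n_puncta_per_nucleus
    for center, semi, _level in params.nuclei:
        centers = _sample_in_ellipsoid(
            rng, center, semi, n, min_distance=params.min_center_distance
        )
        for c in centers:
            _add_spot(reporter, c, sz, params.spot_amplitude)
        zexts = [
            (max(int(math.floor(c[0] - h)), 0), min(int(math.ceil(c[0] + h)) + 1, shape[0]))
            for c in centers
        ]
        # partner: round(f*n) spots at reporter centers, rest at random positions
        n_coloc = int(round(params.coloc_fraction * n))
        chosen = list(rng.choice(n, size=n_coloc, replace=False)) if n else []
        pcenters = [centers[j] for j in chosen]
        pcenters += _sample_in_ellipsoid(rng, center, semi, n - n_coloc)
        for c in pcenters:
            _add_spot(partner, c, sz, params.spot_amplitude)
        centers_per_cell.append(centers)
        zext_per_cell.append(zexts)
        partner_per_cell.append(pcenters)
        n_coloc_per_cell.append(n_coloc)

    channels = []
    for plane in (reporter, partner, dapi):
        img = plane + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=shape)
        channels.append(np.clip(np.rint(img), 0, 65535).astype(np.uint16))

    stack = ImageStack(
        data=np.stack(channels, axis=0),
        voxel_size=params.voxel_size,
        channel_labels=("reporter", "partner", "dapi"),
        layout="czyx",
    )
    truth = ImageGroundTruth(
        nucleus_labels=nucleus_labels,
        punctum_centers=centers_per_cell,
        punctum_z_extents=zext_per_cell,
        partner_centers=partner_per_cell,
        n_coloc=n_coloc_per_cell,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP traces

@dataclass
class SyntheticFrapParams:
    """Parameters of a single-exponential recovery trace.

    The corrected bleach-ROI signal is
    ``scale * exp(-photobleach_rate * t)`` before the bleach and
    ``scale * exp(-photobleach_rate * t) * [(1 - bleach_depth) +
    bleach_depth * mobile_fraction * (1 - exp(-recovery_rate * (t - t_bleach)))]``
    afterwards; the whole-nucleus signal decays with the acquisition
    photobleaching only.  ``background_level`` is added to both, Gaussian
    noise of ``noise_sd`` on top.
    """

    n_pre: int = 5
    n_post: int = 60
    dt: float = 1.0
    bleach_depth: float = 0.8
    mobile_fraction: float = 0.7
    recovery_rate: float = 0.2
    photobleach_rate: float = 0.0
    background_level: float = 50.0
    scale: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1 (prebleach normalization undefined)")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in [0, 1]")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_frap(params: SyntheticFrapParams):
    """Simulate one FRAP trace; returns (FrapTrace, ground-truth dict)."""
    from .frap import FrapTrace  # deferred: frap also imports nothing from here

    rng = np.random.default_rng(params.seed)
    n = params.n_pre + params.n_post
    t = np.arange(n) * params.dt
    t_bleach = t[params.n_pre]
    decay = np.exp(-params.photobleach_rate * t)

    shape_fn = np.ones(n)
    post = slice(params.n_pre, None)
    recovered = params.bleach_depth * params.mobile_fraction * (
        1.0 - np.exp(-params.recovery_rate * (t[post] - t_bleach))
    )
    shape_fn[post] = (1.0 - params.bleach_depth) + recovered

    roi = params.background_level + params.scale * decay * shape_fn
    nucleus = params.background_level + params.scale * decay
    background = np.full(n, params.background_level)
    if params.noise_sd > 0:
        roi = roi + rng.normal(0.0, params.noise_sd, n)
        nucleus = nucleus + rng.normal(0.0, params.noise_sd, n)
        background = background + rng.normal(0.0, params.noise_sd, n)

    trace = FrapTrace(
        time=t,
        roi_mean=roi,
        nucleus_mean=nucleus,
        background_mean=background,
        bleach_index=params.n_pre,
        cell_id=f"synthetic-{params.seed}",
    )
    truth = {
        "mobile_fraction": params.mobile_fraction,
        "recovery_rate": params.recovery_rate,
        "plateau": (1.0 - params.bleach_depth)
        + params.bleach_depth * params.mobile_fraction,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# SELEX read pools

@dataclass
class SyntheticSelexParams:
    """Parameters of a barcoded in vitro selection read pool.

    Each read is ``barcode + left_flank + variable region + right_flank``.
    In the positive sample a fraction of reads per round (monotone
    non-decreasing across rounds) carries the planted motif at a uniform
    random offset inside the 20-bp randomized region; the negative-control
    sample carries the motif in no read at any round, modelling
    fusion-negative lysate.
    """

    motif: str = "GGCCCC"
    variable_length: int = 20
    left_flank: str = "ACACGACGCTCTTCC"
    right_flank: str = "AGATCGGAAGAGC"
    barcodes: dict = field(
        default_factory=lambda: {"pos": "ACGTAC", "neg": "TGCAGT"}
    )
    positive_sample: str = "pos"
    negative_sample: str = "neg"
    n_reads_per_round: int = 10000
    motif_fraction_by_round: tuple = (0.05, 0.15, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        alphabet = set("ACGT")
        if len(self.motif) > self.variable_length:
            raise ValueError("motif longer than the variable region")
        for name, seq in (
            ("motif", self.motif),
            ("left_flank", self.left_flank),
            ("right_flank", self.right_flank),
            *((f"barcode {s}", b) for s, b in self.barcodes.items()),
        ):
            if not set(seq) <= alphabet:
                raise ValueError(f"{name} must be over {{A,C,G,T}}: {seq!r}")
        fr = list(self.motif_fraction_by_round)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("motif fractions must lie in [0, 1]")
        if any(b > a for a, b in zip(fr[1:], fr)):
            raise ValueError("positive motif fractions must be monotone non-decreasing")
        bcs = list(self.barcodes.values())
        for i, a in enumerate(bcs):
            for j, b in enumerate(bcs):
                if i != j and b.startswith(a):
                    raise ValueError(f"barcode collision: {a!r} is a prefix of {b!r}")
        for s in (self.positive_sample, self.negative_sample):
            if s not in self.barcodes:
                raise ValueError(f"sample {s!r} has no barcode")


def _random_regions(rng, n: int, length: int) -> np.ndarray:
    return _DNA[rng.integers(0, 4, size=(n, length))]


def generate_selex(params: SyntheticSelexParams, outdir: str | Path):
    """Write gzip FASTQ files, one per (sample, round).

    Returns ``(paths, truth)`` where ``paths`` maps ``(sample, round)`` to
    the file written (rounds are 1-based) and ``truth`` records the motif,
    the per-round motif fractions and exact motif-carrying read counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    n_rounds = len(params.motif_fraction_by_round)
    fractions = {
        params.positive_sample: list(params.motif_fraction_by_round),
        params.negative_sample: [0.0] * n_rounds,
    }
    motif = np.frombuffer(params.motif.encode(), dtype=np.uint8)
    k = len(motif)
    L = params.variable_length
    paths: dict = {}
    planted_counts: dict = {}
    for sample in (params.positive_sample, params.negative_sample):
        barcode = params.barcodes[sample]
        prefix = barcode + params.left_flank
        suffix = params.right_flank
        read_len = len(prefix) + L + len(suffix)
        qual = "F" * read_len  # constant Phred-33 Q37
        for r in range(n_rounds):
            n = params.n_reads_per_round
            frac = fractions[sample][r]
            regions = _random_regions(rng, n, L)
            n_motif = int(round(frac * n))
            if n_motif:
                offsets = rng.integers(0, L - k + 1, size=n_motif)
                for i, off in enumerate(offsets):
                    regions[i, off : off + k] = motif
                # shuffle so motif reads are not a prefix block of the file
                regions = regions[rng.permutation(n)]
            path = outdir / f"{sample}_round{r + 1}.fastq.gz"
            # mtime=0 keeps the gzip header reproducible across reruns
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as gz, io.TextIOWrapper(gz) as fh:
                for i in range(n):
                    seq = prefix + regions[i].tobytes().decode() + suffix
                    fh.write(f"@{sample}_r{r + 1}_{i}\n{seq}\n+\n{qual}\n")
            paths[(sample, r + 1)] = path
            planted_counts[(sample, r + 1)] = n_motif
    truth = {
        "motif": params.motif,
        "fractions": fractions,
        "planted_counts": planted_counts,
    }
    return paths, truth
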