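"""Box profiles, the random-locus null, and their enrichment summaries."""

import numpy as np
import pytest

from condquant import coloc_profile as cp
from condquant import segmentation as seg
from condquant.io_images import rescale_16bit
from condquant.segmentation import NucleusRegion, PunctaSet, Punctum
from condquant.synthetic_data import SyntheticImageParams, generate_image

from conftest import centered_delta


def _punctum(z, y, x, z0=None, z1=None):
    z0 = z if z0 is None else z0
    z1 = z + 1 if z1 is None else z1
    return Punctum(
        punctum_id=1, nucleus_id=1, centroid=(float(z), float(y), float(x)),
        bbox=(z0, z1, y - 1, y + 2, x - 1, x + 2), z_extent=z1 - z0,
        volume_um3=0.01, mean_intensity=1.0, max_intensity=1.0,
    )


def naive_box_profile(channel, punctum, box_size=61):
    """Brute-force triple-loop reference for extract_box_profile."""
    half = box_size // 2
    _, y, x = (int(np.rint(c)) for c in punctum.centroid)
    z0, z1 = punctum.bbox[0], punctum.bbox[1]
    values = []
    for z in range(z0, z1):
        for i in range(y - half, y + half + 1):
            for j in range(x - half, x + half + 1):
                values.append(float(channel[z, i, j]))
    lo, hi = min(values), max(values)
    out = np.zeros((box_size, box_size))
    if hi == lo:
        return out
    for z in range(z0, z1):
        for i in range(box_size):
            for j in range(x - half, x + half + 1):
                out[i, j - (x - half)] += (
                    float(channel[z, y - half + i, j]) - lo
                ) / (hi - lo)
    return out / (z1 - z0)


class TestExtractBoxProfile:
    def test_constant_patch_maps_to_zeros(self):
        channel = np.full((5, 80, 80), 3.0)
        m = cp.extract_box_profile(_punctum(2, 40, 40), channel)
        assert m.shape == (61, 61)
        assert not m.any()

    def test_single_bright_voxel_peaks_at_box_center(self):
        channel = np.zeros((5, 80, 80))
        channel[2, 40, 40] = 10.0
        m = cp.extract_box_profile(_punctum(2, 40, 40), channel)
        assert np.unravel_index(m.argmax(), m.shape) == (30, 30)

    def test_matches_triple_loop_oracle_bit_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            channel = rng.integers(0, 10_000, size=(6, 90, 90)).astype(np.float64)
            z = int(rng.integers(0, 6))
            z1 = int(rng.integers(z + 1, 7))
            y, x = (int(v) for v in rng.integers(30, 60, size=2))
            p = _punctum(z, y, x, z0=z, z1=z1)
            fast = cp.extract_box_profile(p, channel)
            slow = naive_box_profile(channel, p)
            np.testing.assert_array_equal(fast, slow)

    def test_border_locus_raises(self):
        channel = np.zeros((3, 80, 80))
        with pytest.raises(cp.LocusOutOfBounds):
            cp.extract_box_profile(_punctum(1, 10, 40), channel)


class TestAverageProfiles:
    def test_identical_matrices_average_to_themselves(self):
        m = np.random.default_rng(0).random((61, 61))
        prof = cp.average_profiles([m, m, m], mode="condensate-centered")
        np.testing.assert_allclose(prof.matrix, m)
        assert prof.n_loci == 3

    def test_complementary_matrices_average_to_half(self):
        m = np.random.default_rng(1).random((61, 61))
        prof = cp.average_profiles([m, 1.0 - m], mode="condensate-centered")
        np.testing.assert_allclose(prof.matrix, 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cp.average_profiles([np.zeros((61, 61)), np.zeros((31, 31))], mode="x")


class TestRandomLoci:
    def test_locus_count_matches_puncta_and_footprints_inside(self, segmented):
        _, _, sets = segmented
        (ps,) = sets
        loci = cp.sample_random_loci(ps.cell, ps.puncta, seed=3)
        assert len(loci) == len(ps.puncta)
        assert len({l.center for l in loci}) == len(loci)
        zmin = min(p.z_extent for p in ps.puncta)
        zmax = max(p.z_extent for p in ps.puncta)
        half = 61 // 2
        for l in loci:
            assert zmin <= l.z_length <= zmax
            proj = ps.cell.mask[l.z0 : l.z1].any(axis=0)
            y, x = l.center
            # exhaustive voxel check of the whole footprint
            assert proj[y - half : y + half + 1, x - half : x + half + 1].all()

    def test_small_nucleus_is_infeasible(self):
        mask = np.zeros((4, 50, 50), dtype=bool)
        mask[:, 10:40, 10:40] = True
        cell = NucleusRegion(1, mask, 10.0, (0, 4, 10, 40, 10, 40), {})
        with pytest.raises(RuntimeError, match="smaller than the"):
            cp.sample_random_loci(cell, [_punctum(1, 20, 20)], seed=0)

    def test_same_seed_same_loci(self, segmented):
        _, _, sets = segmented
        (ps,) = sets
        a = cp.sample_random_loci(ps.cell, ps.puncta, seed=11)
        b = cp.sample_random_loci(ps.cell, ps.puncta, seed=11)
        assert a == b

    def test_centers_uniform_over_feasible_region(self):
        # big box nucleus so the feasible region is a rectangle we can bin
        mask = np.zeros((6, 200, 200), dtype=bool)
        mask[:, 20:180, 20:180] = True
        cell = NucleusRegion(1, mask, 10.0, (0, 6, 20, 180, 20, 180), {})
        puncta = [_punctum(2, 100, 100) for _ in range(400)]
        # uniqueness forces distinct centers; sample many loci in batches
        from scipy import stats

        loci = cp.sample_random_loci(cell, puncta, seed=21, max_tries_per_locus=5000)
        ys = np.array([l.center[0] for l in loci])
        xs = np.array([l.center[1] for l in loci])
        half = 30
        lo, hi = 20 + half, 180 - half  # feasible interval [50, 149]
        assert ys.min() >= lo and xs.min() >= lo
        assert ys.max() < hi and xs.max() < hi
        grid = np.histogram2d(
            ys, xs, bins=4, range=[[lo, hi], [lo, hi]]
        )[0].ravel()
        chi2 = ((grid - grid.mean()) ** 2 / grid.mean()).sum()
        assert stats.chi2.sf(chi2, df=15) > 0.01


class TestNullProfile:
    def test_null_on_pure_noise_is_flat(self, segmented):
        _, _, sets = segmented
        (ps,) = sets
        rng = np.random.default_rng(13)
        noise = rng.normal(1000.0, 100.0, size=ps.cell.mask.shape)
        mats, _ = cp.null_profiles([ps], noise, seed=5)
        deltas = [centered_delta(m) for m in mats]
        diff = np.array([c - e for c, e in deltas])
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * max(se, 1e-12)

    def test_null_matched_and_deterministic(self, small_image, segmented):
        _, stack, _ = small_image
        _, _, sets = segmented
        (ps,) = sets
        partner = stack.channel("partner")
        prof1, loci1 = cp.profile_random_null(ps.cell, ps.puncta, partner, seed=9)
        prof2, loci2 = cp.profile_random_null(ps.cell, ps.puncta, partner, seed=9)
        assert loci1 == loci2
        np.testing.assert_array_equal(prof1.matrix, prof2.matrix)
        assert prof1.n_loci == len(ps.puncta)

    def test_colocalized_partner_enriched_only_at_condensates(self, small_image, segmented):
        params, stack, _ = small_image
        _, _, sets = segmented
        partner = stack.channel("partner")
        mats, _ = cp.condensate_profiles(sets, partner)
        centered = cp.enrichment_summary(
            cp.average_profiles(mats, "condensate-centered")
        )
        null_mats, _ = cp.null_profiles(sets, partner, seed=2)
        null = cp.enrichment_summary(cp.average_profiles(null_mats, "random-null"))
        assert centered.ratio > 1.5
        assert abs(null.ratio - 1.0) < 0.5


class TestFishProfiles:
    def test_fish_loci_at_puncta_peak_at_center(self, small_image, segmented):
        params, stack, _ = small_image
        _, _, sets = segmented
        # partner spots sit exactly at reporter puncta (coloc_fraction=1), so
        # partner-channel loci play FISH loci at zero offset
        nuclei = seg.segment_nuclei(stack.channel("dapi"))
        fish_mask = seg.segment_puncta_builtin(
            rescale_16bit(stack.channel("partner")), nuclei
        )
        fish_sets = seg.extract_puncta(
            fish_mask, nuclei, stack.channel("partner"), params.voxel_size
        )
        fish_prof, null_prof = cp.fish_locus_profiles(
            fish_sets, stack.channel("reporter"), seed=6
        )
        peak = np.unravel_index(fish_prof.matrix.argmax(), fish_prof.matrix.shape)
        assert max(abs(peak[0] - 30), abs(peak[1] - 30)) <= 1
        assert cp.enrichment_summary(fish_prof).ratio > cp.enrichment_summary(null_prof).ratio

    def test_distant_fish_loci_show_no_enrichment(self):
        p = SyntheticImageParams(
            stack_shape=(24, 192, 192),
            nuclei=[((12, 96, 96), (9.0, 72.0, 72.0), 3000.0)],
            n_puncta_per_nucleus=8,
            coloc_fraction=0.0,  # partner spots land far from reporter puncta
            min_center_distance=9.0,
            seed=77,
        )
        stack, _ = generate_image(p)
        nuclei = seg.segment_nuclei(stack.channel("dapi"))
        fish_mask = seg.segment_puncta_builtin(
            rescale_16bit(stack.channel("partner")), nuclei
        )
        fish_sets = seg.extract_puncta(
            fish_mask, nuclei, stack.channel("partner"), p.voxel_size
        )
        fish_prof, _ = cp.fish_locus_profiles(fish_sets, stack.channel("reporter"), seed=6)
        ratio = cp.enrichment_summary(fish_prof).ratio
        assert 0.3 < ratio < 2.0

    def test_cells_without_fish_loci_contribute_nothing(self, segmented):
        nuclei, _, sets = segmented
        (ps,) = sets
        empty = PunctaSet(cell=ps.cell, puncta=[])
        reporter = np.random.default_rng(0).random(ps.cell.mask.shape)
        prof, null = cp.fish_locus_profiles([ps, empty], reporter, seed=1)
        assert prof.n_loci == len(ps.puncta)


class TestEnrichmentSummary:
    def test_constant_matrix_ratio_one(self):
        prof = cp.BoxProfile(np.full((61, 61), 0.5), 1)
        assert cp.enrichment_summary(prof).ratio == pytest.approx(1.0)

    def test_center_delta_gives_infinite_ratio(self):
        m = np.zeros((61, 61))
        m[30, 30] = 1.0
        s = cp.enrichment_summary(cp.BoxProfile(m, 1))
        assert np.isinf(s.ratio) and s.degenerate_edge

    def test_matches_brute_force(self):
        m = np.random.default_rng(4).random((61, 61))
        s = cp.enrichment_summary(cp.BoxProfile(m, 1), central_size=11)
        central, edge = centered_delta(m, 11)
        assert s.central_mean == pytest.approx(central)
        assert s.edge_mean == pytest.approx(edge)
        assert s.ratio == pytest.approx(central / edge)

    def test_even_central_size_rejected(self):
        with pytest.raises(ValueError):
            cp.enrichment_summary(cp.BoxProfile(np.zeros((61, 61)), 1), central_size=10)
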