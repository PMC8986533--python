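"""Nuclear segmentation, focus detection, damage index and colocalization."""

import numpy as np
import pytest
from scipy import stats

import wgdscan as w
from wgdscan._errors import DegenerateInputError, InvalidArgumentError


def _disk_image(centres, radius, value, shape=(120, 200)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cy, cx in centres:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentNuclei:
    def test_separated_nuclei_found_with_accurate_areas(self):
        bundle = w.simulate_focus_image(
            shape=(512, 512), n_nuclei=10, foci_per_nucleus=0, noise_sd=5.0, seed=0
        )
        nuclei = w.segment_nuclei(bundle.channels["dna"])
        assert len(nuclei) == 10
        truth_areas = sorted(
            int((bundle.nuclei_labels == i).sum())
            for i in range(1, 11)
        )
        found_areas = sorted(n.area_px for n in nuclei)
        for t, f in zip(truth_areas, found_areas):
            assert abs(f - t) / t < 0.10

    def test_blank_image_returns_empty_list(self):
        assert w.segment_nuclei(np.zeros((100, 100))) == []

    def test_touching_nuclei_split_by_watershed(self):
        img = _disk_image([(60, 80), (60, 118)], radius=20, value=200.0)
        img += np.random.default_rng(0).normal(0, 2.0, img.shape)
        nuclei = w.segment_nuclei(img, min_area=100)
        assert len(nuclei) == 2

    def test_masks_disjoint(self):
        bundle = w.simulate_focus_image(shape=(300, 300), n_nuclei=4, seed=1)
        nuclei = w.segment_nuclei(bundle.channels["dna"])
        total = np.zeros((300, 300), dtype=int)
        for n in nuclei:
            total += n.mask
        assert total.max() <= 1


class TestDetectFoci:
    def test_planted_spots_recovered_at_high_snr(self):
        # SNR 5: amplitude 50 on noise sd 10; spots planted resolvably apart
        recovered, total, errors = 0, 0, []
        for seed in range(10):
            b = w.simulate_focus_image(
                shape=(300, 300), n_nuclei=4, foci_per_nucleus=12, focus_sigma=2.0,
                focus_intensity=50.0, noise_sd=10.0, seed=seed, min_spot_separation=8.0,
            )
            for lab in range(1, 5):
                mask = b.nuclei_labels == lab
                detections, _ = w.detect_foci(b.channels["damage"], mask)
                for spot in b.damage_foci[lab - 1]:
                    total += 1
                    if len(detections):
                        d = np.sqrt(((detections - spot) ** 2).sum(axis=1)).min()
                        if d <= 2.0:
                            recovered += 1
                            errors.append(d)
        assert recovered / total >= 0.95
        assert np.mean(errors) <= 2.0

    def test_no_spots_no_detections(self):
        false_positives, n_nuclei = 0, 0
        for seed in range(30):
            b = w.simulate_focus_image(
                shape=(200, 200), n_nuclei=2, foci_per_nucleus=0, noise_sd=10.0, seed=seed
            )
            for lab in range(1, 3):
                detections, _ = w.detect_foci(b.channels["damage"], b.nuclei_labels == lab)
                false_positives += len(detections)
                n_nuclei += 1
        assert false_positives / n_nuclei < 0.1

    def test_close_pair_merges_into_one(self):
        img = np.random.default_rng(1).normal(0, 1.0, (80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        for cy, cx in [(40, 39), (40, 41)]:  # 2 px apart < min_separation
            img += 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0)
        mask = np.ones((80, 80), dtype=bool)
        detections, _ = w.detect_foci(img, mask, min_separation=3)
        assert len(detections) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidArgumentError):
            w.detect_foci(np.zeros((50, 50)), np.zeros((50, 50), dtype=bool))


class TestDamageIndex:
    def test_worked_example(self):
        # 100-px mask, 20 positive px at 50 a.u.: coverage 20%, index 1000
        img = np.zeros((10, 10))
        img[:2, :] = 50.0
        mask = np.ones((10, 10), dtype=bool)
        coverage, mean_pos, index = w.damage_index(img, mask, threshold=10.0)
        assert (coverage, mean_pos, index) == (20.0, 50.0, 1000.0)

    def test_no_positive_pixels(self):
        img = np.zeros((10, 10))
        mask = np.ones((10, 10), dtype=bool)
        assert w.damage_index(img, mask, threshold=10.0) == (0.0, 0.0, 0.0)

    def test_all_pixels_positive_constant(self):
        img = np.full((10, 10), 7.0)
        mask = np.ones((10, 10), dtype=bool)
        coverage, _, index = w.damage_index(img, mask, threshold=1.0)
        assert coverage == 100.0 and index == pytest.approx(700.0)

    def test_intensity_scale_equivariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, (40, 40))
        mask = np.ones((40, 40), dtype=bool)
        cov1, _, idx1 = w.damage_index(img, mask, threshold=60.0)
        cov3, _, idx3 = w.damage_index(3 * img, mask, threshold=180.0)
        assert cov3 == cov1
        assert idx3 == pytest.approx(3 * idx1)


class TestNormalizedCounts:
    def test_per_area(self):
        nucleus = w.NucleusRecord(1, np.ones((10, 10), dtype=bool), 100, 5000.0)
        per_area, per_dna = w.normalized_counts(10, nucleus)
        assert per_area == pytest.approx(0.1)
        assert per_dna == pytest.approx(10 / 5000)

    def test_doubling_area_halves_density(self):
        small = w.NucleusRecord(1, np.ones((10, 10), dtype=bool), 100, 5000.0)
        big = w.NucleusRecord(2, np.ones((10, 20), dtype=bool), 200, 5000.0)
        assert w.normalized_counts(10, big)[0] == pytest.approx(
            w.normalized_counts(10, small)[0] / 2
        )

    def test_zero_dna_intensity_rejected(self):
        nucleus = w.NucleusRecord(1, np.ones((10, 10), dtype=bool), 100, 0.0)
        with pytest.raises(InvalidArgumentError):
            w.normalized_counts(10, nucleus)


class TestFractionAboveThreshold:
    def _records(self, counts):
        return [
            w.FociQuantRecord(i, c, 0.0, 0.0, 0.0) for i, c in enumerate(counts)
        ]

    def test_boundary_inclusive(self):
        assert w.fraction_above_threshold(self._records([9, 10, 11])) == pytest.approx(2 / 3)

    def test_all_zero(self):
        assert w.fraction_above_threshold(self._records([0, 0, 0])) == 0.0

    def test_zero_threshold(self):
        assert w.fraction_above_threshold(self._records([0, 3]), k=0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            w.fraction_above_threshold([])


class TestManders:
    def test_identical_channels_full_overlap(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, (50, 50))
        mask = np.ones((50, 50), dtype=bool)
        m1, m2 = w.manders(img, img, mask, threshold_a=0.0, threshold_b=0.0)
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_signals_zero(self):
        a = np.zeros((40, 40))
        b = np.zeros((40, 40))
        a[:10, :10] = 100.0
        b[30:, 30:] = 100.0
        mask = np.ones((40, 40), dtype=bool)
        m1, m2 = w.manders(a + 1e-3, b + 1e-3, mask, threshold_a=50.0, threshold_b=50.0)
        assert m1 == pytest.approx(0.0, abs=1e-3)
        assert m2 == pytest.approx(0.0, abs=1e-3)

    def test_zero_channel_rejected(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(DegenerateInputError):
            w.manders(np.zeros((20, 20)), np.ones((20, 20)), mask)

    def test_partial_overlap_matches_ground_truth_share(self):
        """Measured M1 tracks an oracle computed from the planted spot
        assignments (same formula on the noiseless rendered channels)."""
        b = w.simulate_focus_image(
            shape=(300, 300), n_nuclei=4, foci_per_nucleus=10, focus_sigma=2.0,
            focus_intensity=120.0, noise_sd=4.0, overlap_fraction=0.5, seed=6,
            min_spot_separation=8.0,
        )
        clean = w.simulate_focus_image(
            shape=(300, 300), n_nuclei=4, foci_per_nucleus=10, focus_sigma=2.0,
            focus_intensity=120.0, noise_sd=0.0, overlap_fraction=0.5, seed=6,
            min_spot_separation=8.0,
        )
        for lab in range(1, 5):
            mask = b.nuclei_labels == lab
            m1_obs, _ = w.manders(b.channels["damage"], b.channels["marker"], mask)
            m1_oracle, _ = w.manders(
                clean.channels["damage"] + 1e-6, clean.channels["marker"] + 1e-6, mask
            )
            assert abs(m1_obs - m1_oracle) < 0.15

    def test_overlap_fraction_orders_m1(self):
        m1s = []
        for frac in (0.0, 0.5, 1.0):
            b = w.simulate_focus_image(
                shape=(260, 260), n_nuclei=3, foci_per_nucleus=10, focus_sigma=2.0,
                focus_intensity=120.0, noise_sd=4.0, overlap_fraction=frac, seed=8,
                min_spot_separation=8.0,
            )
            vals = [
                w.manders(b.channels["damage"], b.channels["marker"], b.nuclei_labels == lab)[0]
                for lab in range(1, 4)
            ]
            m1s.append(np.mean(vals))
        assert m1s[0] < m1s[1] < m1s[2]


class TestCostesRandomization:
    def test_identical_channels_minimal_p(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 100, (40, 40))
        mask = np.ones((40, 40), dtype=bool)
        result = w.costes_randomization_p(img, img, mask, n=1000, seed=0)
        assert result.p_value == pytest.approx(1 / 1001)

    def test_constant_channel_p_one(self):
        mask = np.ones((30, 30), dtype=bool)
        a = np.full((30, 30), 5.0)
        b = np.random.default_rng(5).uniform(0, 100, (30, 30))
        result = w.costes_randomization_p(a, b, mask, n=100, seed=0)
        assert result.p_value == 1.0

    def test_uniform_under_independence(self):
        """Under the permutation null, p-values are (conservatively)
        uniform: a KS test at alpha = 0.01 across 200 seeded replicates."""
        yy, xx = np.mgrid[0:40, 0:40]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 18**2
        p_values = []
        for seed in range(200):
            rng = np.random.default_rng(20_000 + seed)
            a = rng.normal(50, 10, (40, 40))
            b = rng.normal(50, 10, (40, 40))
            p_values.append(
                w.costes_randomization_p(a, b, mask, n=199, seed=seed).p_value
            )
        assert stats.kstest(p_values, "uniform").pvalue > 0.01

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 100, (30, 30))
        b = rng.uniform(0, 100, (30, 30))
        mask = np.ones((30, 30), dtype=bool)
        r1 = w.costes_randomization_p(a, b, mask, n=200, seed=9)
        r2 = w.costes_randomization_p(a, b, mask, n=200, seed=9)
        assert r1.p_value == r2.p_value


class TestQuantifyImage:
    def test_full_pipeline_counts_match_ground_truth(self):
        b = w.simulate_focus_image(
            shape=(300, 300), n_nuclei=4, foci_per_nucleus=10, focus_sigma=2.0,
            focus_intensity=80.0, noise_sd=8.0, seed=10, min_spot_separation=8.0,
        )
        nuclei, records = w.quantify_image(b.channels["dna"], b.channels["damage"])
        assert len(nuclei) == 4
        truth_total = sum(len(f) for f in b.damage_foci)
        found_total = sum(r.foci_count for r in records)
        assert abs(found_total - truth_total) <= max(2, 0.1 * truth_total)
        for r in records:
            assert r.damage_index == pytest.approx(
                r.coverage_percent * r.mean_positive_intensity
            )
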