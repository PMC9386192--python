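"""Quantization, entropy, mean temperature and GLCM texture."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermentropy.features import (
    extract_roi,
    frame_features,
    glcm_texture,
    mean_temperature,
    quantize,
    shannon_entropy,
)
from thermentropy.io import ROIMask, ThermalFrame


def brute_entropy(levels) -> float:
    """Independent oracle: direct evaluation of -sum p log2 p."""
    counts = Counter(levels)
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


class TestExtractRoi:
    def test_full_mask_returns_all_values(self, small_frame, full_mask):
        vals = extract_roi(small_frame, full_mask)
        assert sorted(vals) == sorted(small_frame.temperatures.ravel())

    def test_single_pixel(self, small_frame):
        m = np.zeros(small_frame.shape, dtype=bool)
        m[1, 2] = True
        vals = extract_roi(small_frame, ROIMask(mask=m, label="chest"))
        assert vals.tolist() == [30.3]

    def test_shape_mismatch(self, small_frame):
        bad = ROIMask(mask=np.ones((2, 2), dtype=bool), label="chest")
        with pytest.raises(ValueError, match="shape"):
            extract_roi(small_frame, bad)


class TestQuantize:
    @pytest.mark.parametrize(
        "temps, expected_levels",
        [
            ([30.04, 30.06, 30.14], [0, 1, 1]),
            ([20.0, 20.1, 20.2, 20.3], [0, 1, 2, 3]),
            ([31.2] * 100, [0] * 100),
            # documented tie rule: half rounds away from zero, so 30.05 -> 30.1
            ([30.0, 30.05], [0, 1]),
            ([30.04999, 30.0], [0, 0]),
        ],
    )
    def test_hand_traces(self, temps, expected_levels):
        q = quantize(temps)
        assert q.levels.tolist() == expected_levels
        assert q.levels.min() == 0

    def test_t_min_records_rounded_minimum(self):
        q = quantize([30.04, 30.06])
        assert q.t_min == pytest.approx(30.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            quantize([])
        with pytest.raises(ValueError, match="bin_width"):
            quantize([30.0], bin_width=0.0)

    def test_custom_bin_width(self):
        q = quantize([20.0, 20.5, 21.0], bin_width=0.5)
        assert q.levels.tolist() == [0, 1, 2]


class TestShannonEntropy:
    def test_single_level_is_zero(self):
        assert shannon_entropy(quantize([31.2] * 50)) == 0.0

    @pytest.mark.parametrize("m", [2, 4, 8])
    def test_equiprobable_levels(self, m):
        temps = np.repeat(20.0 + 0.1 * np.arange(m), 5)
        assert shannon_entropy(quantize(temps)) == pytest.approx(math.log2(m), abs=1e-12)

    def test_two_one_split(self):
        # direct hand evaluation: -(2/3)log2(2/3) - (1/3)log2(1/3)
        h = shannon_entropy(quantize([20.0, 20.0, 20.1]))
        assert h == pytest.approx(0.9182958340544896, abs=1e-12)

    def test_exhaustive_small_multisets_match_oracle_and_bound(self):
        """All level multisets with n <= 8 pixels and <= 4 levels: entropy
        equals the hand oracle and respects the log2(n_levels) bound, with
        equality iff the histogram is uniform."""
        for n in range(1, 9):
            for levels in itertools.combinations_with_replacement(range(4), n):
                temps = 20.0 + 0.1 * np.array(levels)
                q = quantize(temps)
                h = shannon_entropy(q)
                assert h == pytest.approx(brute_entropy(levels), abs=1e-12)
                k = len(set(levels))
                assert 0.0 <= h <= math.log2(k) + 1e-12 if k > 1 else h == 0.0
                counts = set(Counter(levels).values())
                if len(counts) == 1:
                    assert h == pytest.approx(math.log2(k), abs=1e-12)


class TestMeanTemperature:
    @pytest.mark.parametrize(
        "temps, expected",
        [([30.0, 31.0], 30.5), ([32.2] * 50, 32.2), ([29.95, 30.05, 30.00], 30.00)],
    )
    def test_hand_arithmetic(self, temps, expected):
        assert mean_temperature(temps) == pytest.approx(expected)

    def test_uses_raw_not_rounded_values(self):
        assert mean_temperature([30.04, 30.04]) == pytest.approx(30.04)


class TestGlcm:
    def _quantized_on(self, temps, mask):
        return quantize(np.asarray(temps, dtype=float)[mask.mask])

    def test_constant_region(self):
        mask = ROIMask(mask=np.ones((3, 3), dtype=bool), label="chest")
        q = quantize([30.0] * 9)
        tex = glcm_texture(q, mask)
        assert tex["contrast"] == 0.0
        assert tex["homogeneity"] == 1.0

    def test_two_pixel_region_hand_built(self):
        mask = ROIMask(mask=np.ones((1, 2), dtype=bool), label="chest")
        q = quantize([30.0, 30.1])
        tex = glcm_texture(q, mask, offsets=[(0, 1)])
        assert tex["contrast"] == pytest.approx(1.0)
        assert tex["homogeneity"] == pytest.approx(0.5)

    def test_checkerboard_contrast(self):
        temps = np.indices((4, 4)).sum(axis=0) % 2 * 0.1 + 30.0
        mask = ROIMask(mask=np.ones((4, 4), dtype=bool), label="chest")
        q = quantize(temps[mask.mask])
        tex = glcm_texture(q, mask, offsets=[(0, 1)])
        assert tex["contrast"] == pytest.approx(1.0)

    def test_no_valid_pair_is_error(self):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 0] = m[2, 2] = True  # no unit-offset pair inside the mask
        mask = ROIMask(mask=m, label="chest")
        with pytest.raises(ValueError, match="pair"):
            glcm_texture(quantize([30.0, 30.1]), mask, offsets=[(0, 1)])

    def test_matches_brute_force_pair_enumeration(self):
        """Random masks/levels: GLCM features equal an independent pairwise
        enumeration over every offset."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.random((5, 6)) < 0.7
            if m.sum() < 2:
                continue
            temps = 30.0 + 0.1 * rng.integers(0, 4, size=(5, 6))
            mask = ROIMask(mask=m, label="chest")
            q = quantize(temps[m])
            offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
            level_img = np.full(m.shape, -1)
            level_img[m] = q.levels
            counts = Counter()
            for r in range(5):
                for c in range(6):
                    for dr, dc in offsets:
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < 5 and 0 <= c2 < 6 and level_img[r, c] >= 0 and level_img[r2, c2] >= 0:
                            counts[(level_img[r, c], level_img[r2, c2])] += 1
                            counts[(level_img[r2, c2], level_img[r, c])] += 1
            if not counts:
                continue
            total = sum(counts.values())
            contrast = sum(v / total * (i - j) ** 2 for (i, j), v in counts.items())
            homog = sum(v / total / (1 + abs(i - j)) for (i, j), v in counts.items())
            tex = glcm_texture(q, mask, offsets=offsets)
            assert tex["contrast"] == pytest.approx(contrast, abs=1e-12)
            assert tex["homogeneity"] == pytest.approx(homog, abs=1e-12)


class TestInvariances:
    @given(
        st.lists(st.floats(min_value=20.0, max_value=40.0, allow_nan=False), min_size=2, max_size=40),
        st.integers(min_value=-30, max_value=30),
    )
    def test_lattice_translation_invariance(self, temps, k):
        """Adding a bin-lattice constant c = 0.1k leaves levels and entropy
        unchanged; the mean shifts by exactly c."""
        c = 0.1 * k
        q0, q1 = quantize(temps), quantize([t + c for t in temps])
        assert q0.levels.tolist() == q1.levels.tolist()
        assert shannon_entropy(q0) == pytest.approx(shannon_entropy(q1), abs=1e-12)

    @given(
        st.lists(st.floats(min_value=20.0, max_value=40.0, allow_nan=False), min_size=1, max_size=40),
        st.floats(min_value=-3.0, max_value=3.0, allow_nan=False),
    )
    def test_mean_shifts_by_any_constant(self, temps, c):
        assert mean_temperature([t + c for t in temps]) == pytest.approx(
            mean_temperature(temps) + c, abs=1e-9
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        temps = 30.0 + rng.random(60)
        shuffled = rng.permutation(temps)
        assert shannon_entropy(quantize(shuffled)) == pytest.approx(
            shannon_entropy(quantize(temps)), abs=1e-12
        )
        assert mean_temperature(shuffled) == pytest.approx(mean_temperature(temps))

    def test_refining_bins_never_decreases_entropy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            temps = 30.0 + rng.normal(0, 0.5, size=200)
            h_coarse = shannon_entropy(quantize(temps, 0.2))
            h_fine = shannon_entropy(quantize(temps, 0.1))
            assert h_fine >= h_coarse - 1e-12


class TestFrameFeatures:
    def test_constant_frame_full_mask(self):
        frame = ThermalFrame(np.full((4, 4), 33.0))
        mask = ROIMask(np.ones((4, 4), dtype=bool), label="chest")
        (rec,) = frame_features(frame, [mask])
        assert rec.entropy == 0.0
        assert rec.mean_temp == pytest.approx(33.0)
        assert rec.n_levels == 1

    def test_disjoint_masks_are_independent(self, small_frame):
        m1 = np.zeros(small_frame.shape, dtype=bool)
        m2 = np.zeros(small_frame.shape, dtype=bool)
        m1[:2], m2[2:] = True, True
        recs = frame_features(
            small_frame,
            [ROIMask(m1, "forehead"), ROIMask(m2, "abdomen")],
        )
        assert [r.label for r in recs] == ["forehead", "abdomen"]
        assert recs[0].mean_temp != recs[1].mean_temp

    def test_synthetic_frame_smoke(self):
        from thermentropy.synthetic import SubjectConfig, generate_subject

        s = generate_subject("s", SubjectConfig(seed=5))
        recs = frame_features(s.frames[0], list(s.masks.values()), with_glcm=True)
        for r in recs:
            assert np.isfinite([r.mean_temp, r.entropy, r.contrast, r.homogeneity]).all()
            assert 15.0 <= r.mean_temp <= 45.0
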