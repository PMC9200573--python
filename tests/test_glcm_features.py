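"""Co-occurrence matrix and the ten texture statistics, checked against
nested-loop oracles, hand-computable cases, analytic bounds, and an
independent library implementation."""

import numpy as np
import pytest

from thyrotex.glcm_features import (
    FEATURE_NAMES,
    CooccurrenceMatrix,
    OffsetSpec,
    compute_glcm,
    extract_fglcm,
    glcm_marginals,
    quantize,
    sweep_offsets,
    texture_features,
)

# ---------------------------------------------------------------------------
# oracles


def brute_force_glcm(data, levels, dr, dc):
    """Exhaustive pair scan straight from the definition."""
    counts = np.zeros((levels, levels), dtype=int)
    rows, cols = data.shape
    for e in range(rows):
        for g in range(cols):
            e2, g2 = e + dr, g + dc
            if 0 <= e2 < rows and 0 <= g2 < cols:
                counts[data[e, g], data[e2, g2]] += 1
    return counts


def brute_force_features(P):
    """All ten statistics by direct double-loop summation."""
    L = P.shape[0]
    mu_e = sum(q * P[q, z] for q in range(L) for z in range(L))
    mu_g = sum(z * P[q, z] for q in range(L) for z in range(L))
    var_e = sum((q - mu_e) ** 2 * P[q, z] for q in range(L) for z in range(L))
    var_g = sum((z - mu_g) ** 2 * P[q, z] for q in range(L) for z in range(L))
    se, sg = np.sqrt(var_e), np.sqrt(var_g)
    out = {}
    out["AC"] = sum(q * z * P[q, z] for q in range(L) for z in range(L))
    out["CT"] = sum((q - z) ** 2 * P[q, z] for q in range(L) for z in range(L))
    out["CR"] = (
        0.0
        if se * sg == 0
        else sum(
            (q - mu_e) * (z - mu_g) * P[q, z] for q in range(L) for z in range(L)
        )
        / (se * sg)
    )
    out["CP"] = sum(
        (q + z - mu_e - mu_g) ** 4 * P[q, z] for q in range(L) for z in range(L)
    )
    out["CS"] = sum(
        (q + z - mu_e - mu_g) ** 3 * P[q, z] for q in range(L) for z in range(L)
    )
    out["D"] = sum(abs(q - z) * P[q, z] for q in range(L) for z in range(L))
    out["EN"] = sum(P[q, z] ** 2 for q in range(L) for z in range(L))
    out["ET"] = -sum(
        P[q, z] * np.log2(P[q, z])
        for q in range(L)
        for z in range(L)
        if P[q, z] > 0
    )
    out["H"] = sum(
        P[q, z] / (1 + abs(q - z)) for q in range(L) for z in range(L)
    )
    out["MP"] = P.max()
    return out


def normalized_matrix(P, orientation=0):
    return CooccurrenceMatrix(
        counts=np.zeros_like(P, dtype=int),
        offset=OffsetSpec(orientation=orientation),
        normalized=True,
        probabilities=P,
    )


# ---------------------------------------------------------------------------
# quantize


class TestQuantize:
    def test_identity_mapping_256(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(img, 256)
        np.testing.assert_array_equal(q.data, np.arange(256).reshape(16, 16))

    def test_two_level_checkerboard(self):
        q = quantize(np.array([[0.0, 255.0], [255.0, 0.0]]), 2)
        np.testing.assert_array_equal(q.data, [[0, 1], [1, 0]])

    def test_matches_digitize_oracle(self, rng):
        img = rng.random((12, 12)) * 300 - 50
        L = 8
        q = quantize(img, L)
        lo, hi = img.min(), img.max()
        edges = lo + (hi - lo) * np.arange(1, L) / L
        oracle = np.digitize(img, edges)
        np.testing.assert_array_equal(q.data, oracle)
        assert q.data.min() >= 0 and q.data.max() <= L - 1

    def test_constant_image_maps_to_level_zero(self):
        q = quantize(np.full((4, 4), 9.0), 16)
        assert np.all(q.data == 0)

    def test_rejects_single_level(self):
        with pytest.raises(ValueError, match="levels"):
            quantize(np.zeros((4, 4)), 1)


# ---------------------------------------------------------------------------
# compute_glcm


class TestComputeGlcm:
    def test_hand_enumerated_two_by_two(self):
        q = quantize(np.array([[0.0, 0.0], [1.0, 1.0]]), 2)
        glcm = compute_glcm(q, OffsetSpec(delta=1, orientation=0), normalize=False)
        expected = np.array([[1, 0], [0, 1]])
        np.testing.assert_array_equal(glcm.counts, expected)

    def test_constant_image_single_cell(self):
        q = quantize(np.full((5, 7), 3.0), 4)
        for off in sweep_offsets(1):
            glcm = compute_glcm(q, off, normalize=False)
            dr, dc = off.displacement
            n_pairs = (5 - abs(dr)) * (7 - abs(dc))
            assert glcm.counts[0, 0] == n_pairs
            assert glcm.counts.sum() == n_pairs

    @pytest.mark.parametrize("orientation", [0, 45, 90, 135])
    def test_matches_nested_loop_oracle(self, rng, orientation):
        img = rng.integers(0, 6, size=(8, 8)).astype(float)
        q = quantize(img, 6)
        off = OffsetSpec(delta=1, orientation=orientation)
        glcm = compute_glcm(q, off, normalize=True)
        dr, dc = off.displacement
        oracle = brute_force_glcm(q.data, 6, dr, dc)
        np.testing.assert_array_equal(glcm.counts, oracle)
        assert abs(glcm.P.sum() - 1.0) < 1e-12

    def test_offset_exceeding_extent_rejected(self):
        q = quantize(np.zeros((4, 4)) + np.eye(4), 2)
        with pytest.raises(ValueError, match="exceeds"):
            compute_glcm(q, OffsetSpec(delta=4, orientation=0))

    def test_agrees_with_skimage(self, rng):
        """Independent cross-check of the 0-degree counts."""
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        img = rng.integers(0, 8, size=(10, 10))
        q = quantize(img.astype(float), 8)
        ours = compute_glcm(q, OffsetSpec(delta=1, orientation=0), normalize=False)
        theirs = graycomatrix(img.astype(np.uint8), [1], [0], levels=8)[:, :, 0, 0]
        np.testing.assert_array_equal(ours.counts, theirs)


# ---------------------------------------------------------------------------
# marginals and features


class TestMarginals:
    def test_symmetric_matrix_equal_marginals(self, rng):
        A = rng.random((5, 5))
        P = (A + A.T) / (A + A.T).sum()
        m = glcm_marginals(normalized_matrix(P))
        assert m.mu_e == pytest.approx(m.mu_g, abs=1e-12)
        assert m.sigma_e == pytest.approx(m.sigma_g, abs=1e-12)

    def test_single_cell(self):
        P = np.zeros((5, 5))
        P[2, 3] = 1.0
        m = glcm_marginals(normalized_matrix(P))
        assert (m.mu_e, m.mu_g, m.sigma_e, m.sigma_g) == (2.0, 3.0, 0.0, 0.0)

    def test_matches_direct_summation(self, rng):
        A = rng.random((4, 4))
        P = A / A.sum()
        m = glcm_marginals(normalized_matrix(P))
        mu_e = sum(q * P[q, z] for q in range(4) for z in range(4))
        assert m.mu_e == pytest.approx(mu_e, abs=1e-12)

    def test_unnormalized_rejected(self):
        glcm = CooccurrenceMatrix(
            counts=np.ones((2, 2), dtype=int),
            offset=OffsetSpec(),
            normalized=False,
        )
        with pytest.raises(ValueError, match="normalized"):
            glcm_marginals(glcm)


class TestTextureFeatures:
    def test_single_diagonal_cell(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = texture_features(normalized_matrix(P))
        assert (f.CT, f.D, f.ET) == (0.0, 0.0, 0.0)
        assert (f.H, f.EN, f.MP) == (1.0, 1.0, 1.0)
        assert f.degenerate_correlation

    def test_uniform_four_level(self):
        P = np.full((4, 4), 1 / 16)
        f = texture_features(normalized_matrix(P))
        assert f.ET == pytest.approx(4.0, abs=1e-12)  # log2(16) bits
        assert f.EN == pytest.approx(1 / 16, abs=1e-15)
        assert f.MP == pytest.approx(1 / 16, abs=1e-15)

    def test_all_ten_match_bruteforce(self, rng):
        A = rng.random((8, 8))
        P = A / A.sum()
        f = texture_features(normalized_matrix(P))
        oracle = brute_force_features(P)
        for name in FEATURE_NAMES:
            assert getattr(f, name) == pytest.approx(oracle[name], abs=1e-10), name

    def test_bounds(self, rng):
        for _ in range(10):
            A = rng.random((6, 6)) ** 3
            P = A / A.sum()
            f = texture_features(normalized_matrix(P))
            L = 6
            assert 0 < f.EN <= 1 and 0 < f.H <= 1 and 0 < f.MP <= 1
            assert 0 <= f.ET <= 2 * np.log2(L)
            assert 0 <= f.CT <= (L - 1) ** 2
            assert f.D >= 0 and f.CP >= 0

    def test_zero_contrast_iff_diagonal_mass(self, rng):
        diag = np.diag(rng.random(5))
        f = texture_features(normalized_matrix(diag / diag.sum()))
        assert f.CT == 0.0
        off = np.zeros((5, 5))
        off[0, 1] = 1.0
        assert texture_features(normalized_matrix(off)).CT > 0


# ---------------------------------------------------------------------------
# extract_fglcm


class TestExtractFglcm:
    def test_constant_image(self):
        f = extract_fglcm(np.full((10, 10), 5.0), levels=8)
        assert (f.CT, f.D, f.ET) == (0.0, 0.0, 0.0)
        assert (f.H, f.EN, f.MP) == (1.0, 1.0, 1.0)

    def test_checkerboard_has_higher_contrast(self):
        board = np.indices((10, 10)).sum(axis=0) % 2 * 255.0
        assert extract_fglcm(board, levels=8).CT > extract_fglcm(
            np.full((10, 10), 5.0), levels=8
        ).CT

    def test_rotation_invariance_of_sweep_average(self, rng):
        img = rng.random((9, 9)) * 100
        a = extract_fglcm(img, levels=8).as_array()
        b = extract_fglcm(np.rot90(img), levels=8).as_array()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_symmetric_mode_normalizes(self, rng):
        img = rng.random((8, 8))
        f = extract_fglcm(img, levels=4, symmetric=True)
        assert 0 < f.EN <= 1


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            (8, 8),
            elements=st.floats(0, 255, allow_nan=False, allow_infinity=False),
        ),
        st.integers(2, 16),
    )
    def test_normalization_and_bounds_hold_for_any_image(self, image, levels):
        """For arbitrary finite images: probabilities sum to one at every
        offset, and the bounded statistics stay in their analytic ranges."""
        q = quantize(image, levels)
        for off in sweep_offsets(1):
            glcm = compute_glcm(q, off, normalize=True)
            assert abs(glcm.P.sum() - 1.0) < 1e-12
        f = extract_fglcm(image, levels=levels)
        assert 0 < f.EN <= 1 and 0 < f.H <= 1 and 0 < f.MP <= 1
        assert 0 <= f.ET <= 2 * np.log2(levels) + 1e-12
        assert -1e-12 <= f.CT <= (levels - 1) ** 2
        assert f.D >= 0 and f.CP >= -1e-12
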