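"""Radiomic feature extraction: schema, first-order arithmetic, texture
matrices against brute-force enumeration oracles, and invariances."""

import numpy as np
import pytest

from mrfusion.io_formats import AnnotatedSlice
from mrfusion.radiomics import (
    CLASS_NAMES,
    DIRECTIONS_2D,
    FEATURE_NAMES,
    FeatureStandardizer,
    SchemaError,
    build_feature_matrix,
    canonical_feature_names,
    discretize,
    extract_sequence_features,
    first_order_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    log_filter,
    ngtdm_features,
    ngtdm_table,
)

from _oracles import (
    oracle_dependence,
    oracle_glcm,
    oracle_glcm_features,
    oracle_ngtdm,
    oracle_ngtdm_features,
    oracle_runs,
    oracle_sized_features,
    oracle_zones,
)


def const_slice(value=5.0, shape=(9, 9)):
    return AnnotatedSlice(np.full(shape, value), np.ones(shape, bool), (1.0, 1.0), "T2w")


# ---------------------------------------------------------------------------
# schema


def test_feature_registry_counts():
    """372 features: 4 filters x (18 + 24 + 16 + 16 + 14 + 5)."""
    assert len(FEATURE_NAMES) == 372
    per_class = {"firstorder": 18, "glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}
    for cls, n in per_class.items():
        assert len(CLASS_NAMES[cls]) == n
        for filt in ("original", "log-sigma-1", "log-sigma-2", "log-sigma-3"):
            assert sum(1 for f in FEATURE_NAMES if f.startswith(f"{filt}_{cls}_")) == n
    assert len(set(FEATURE_NAMES)) == 372


def test_extract_sequence_features_full_vector(phantom_slice):
    vec = extract_sequence_features(phantom_slice)
    assert len(vec.values) == 372
    assert vec.names == FEATURE_NAMES
    assert np.all(np.isfinite(vec.values))
    # deterministic: bitwise identical on a second run
    vec2 = extract_sequence_features(phantom_slice)
    assert np.array_equal(vec.values, vec2.values)


def test_extraction_translation_invariance(rng):
    img = rng.normal(50, 5, (64, 64))
    mask = np.zeros((64, 64), bool)
    mask[20:33, 18:30] = True
    sl = AnnotatedSlice(img, mask, (1.0, 1.0), "T1c")
    shifted = AnnotatedSlice(np.roll(img, (7, -5), (0, 1)), np.roll(mask, (7, -5), (0, 1)),
                             (1.0, 1.0), "T1c")
    v1 = extract_sequence_features(sl)
    v2 = extract_sequence_features(shifted)
    # LoG uses edge padding, so compare the original-image block exactly
    orig = [i for i, n in enumerate(FEATURE_NAMES) if n.startswith("original_")]
    np.testing.assert_allclose(v1.values[orig], v2.values[orig], rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# LoG and discretization


def test_log_filter_constant_and_ramp():
    resp = log_filter(const_slice(value=7.0, shape=(15, 15)), 1.0)
    assert np.all(np.abs(resp.pixels[3:-3, 3:-3]) < 1e-9)
    ramp = AnnotatedSlice(np.tile(np.arange(15.0), (15, 1)), np.ones((15, 15), bool),
                          (1.0, 1.0), "ADC")
    resp = log_filter(ramp, 1.0)
    assert np.all(np.abs(resp.pixels[4:-4, 4:-4]) < 1e-7)


def test_log_filter_bright_pixel_negative_center():
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    sl = AnnotatedSlice(img, np.ones((21, 21), bool), (1.0, 1.0), "T2w")
    resp = log_filter(sl, 1.5)
    assert resp.pixels[10, 10] < 0


def test_log_filter_rejects_bad_sigma(phantom_slice):
    with pytest.raises(ValueError):
        log_filter(phantom_slice, 0.0)


@pytest.mark.parametrize(
    "values,n_bins,expected_levels",
    [
        (np.arange(32.0), 32, np.arange(1, 33)),
        (np.array([0.0, 10.0]), 2, np.array([1, 2])),
    ],
)
def test_discretize_forced_mappings(values, n_bins, expected_levels):
    n = values.size
    sl = AnnotatedSlice(values.reshape(1, n), np.ones((1, n), bool), (1.0, 1.0), "T2w")
    d = discretize(sl, n_bins)
    np.testing.assert_array_equal(np.sort(d.roi_levels), expected_levels)


def test_discretize_constant_roi_single_level():
    d = discretize(const_slice(), 32)
    assert d.n_levels == 1
    assert np.all(d.roi_levels == 1)


# ---------------------------------------------------------------------------
# first order


def test_first_order_hand_arithmetic():
    sl = AnnotatedSlice(np.array([[1.0, 2.0], [3.0, 4.0]]), np.ones((2, 2), bool),
                        (1.0, 1.0), "T2w")
    f = first_order_features(sl)
    assert f["Mean"] == pytest.approx(2.5)
    assert f["Variance"] == pytest.approx(1.25)
    assert f["Range"] == pytest.approx(3.0)
    assert f["Energy"] == pytest.approx(30.0)
    assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
    assert f["TotalEnergy"] == pytest.approx(f["Energy"])


def test_first_order_constant_conventions():
    f = first_order_features(const_slice(value=3.0))
    assert f["Variance"] == 0.0
    assert f["Skewness"] == 0.0
    assert f["Kurtosis"] == 0.0
    assert f["Uniformity"] == pytest.approx(1.0)
    assert f["Entropy"] == pytest.approx(0.0)


def test_first_order_scaling_law(phantom_slice):
    f1 = first_order_features(phantom_slice)
    scaled = AnnotatedSlice(phantom_slice.pixels * 3.0, phantom_slice.mask,
                            (1.0, 1.0), "T2w")
    f3 = first_order_features(scaled)
    assert f3["Mean"] == pytest.approx(3 * f1["Mean"])
    assert f3["Variance"] == pytest.approx(9 * f1["Variance"])


def test_first_order_permutation_invariance(rng, phantom_slice):
    f1 = first_order_features(phantom_slice)
    vals = phantom_slice.pixels[phantom_slice.mask]
    perm = rng.permutation(vals)
    img = phantom_slice.pixels.copy()
    img[phantom_slice.mask] = perm
    f2 = first_order_features(AnnotatedSlice(img, phantom_slice.mask, (1.0, 1.0), "T2w"))
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], abs=1e-9), k


# ---------------------------------------------------------------------------
# GLCM specifics


def test_glcm_hand_counted_2x2():
    levels = np.array([[1, 1], [2, 2]])
    d_roi = discretize(
        AnnotatedSlice(levels.astype(float), np.ones((2, 2), bool), (1.0, 1.0), "T2w"), 2
    )
    P = glcm_matrix(d_roi, (0, 1))  # horizontal
    # pairs: (1,1) and (2,2), symmetrized -> diagonal 0.5/0.5
    np.testing.assert_allclose(P, np.array([[0.5, 0.0], [0.0, 0.5]]))


def test_glcm_checkerboard_horizontal_contrast():
    board = np.indices((6, 6)).sum(axis=0) % 2 + 1
    d_roi = discretize(
        AnnotatedSlice(board.astype(float), np.ones((6, 6), bool), (1.0, 1.0), "T2w"), 2
    )
    feats = glcm_features(d_roi, directions=((0, 1),))
    assert feats["Contrast"] == pytest.approx(1.0)


def test_glcm_constant_conventions():
    d_roi = discretize(const_slice(), 32)
    f = glcm_features(d_roi)
    assert f["Contrast"] == 0.0
    assert f["Correlation"] == 1.0
    assert f["JointEnergy"] == pytest.approx(1.0)
    assert f["MCC"] == 1.0


def test_glcm_matrix_is_symmetric_distribution(roi_factory):
    for _ in range(5):
        d = roi_factory()
        for off in DIRECTIONS_2D:
            P = glcm_matrix(d, off)
            assert P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(P, P.T, atol=1e-15)


# ---------------------------------------------------------------------------
# run/zone/dependence specifics


def test_glrlm_hand_counted_row():
    row = np.array([[1, 1, 1, 2]])
    d_roi = discretize(
        AnnotatedSlice(row.astype(float), np.ones((1, 4), bool), (1.0, 1.0), "T2w"), 2
    )
    R = glrlm_matrix(d_roi, (0, 1))
    assert R[0, 2] == 1  # level 1, length 3
    assert R[1, 0] == 1  # level 2, length 1
    assert R.sum() == 2


def test_glszm_single_zone_constant():
    d_roi = discretize(const_slice(shape=(3, 3)), 32)
    Z = glszm_matrix(d_roi)
    assert Z[0, 8] == 1
    assert Z.sum() == 1


def test_glszm_diagonal_pixels_merge_under_8_connectivity():
    img = np.zeros((4, 4))
    img[1, 1] = img[2, 2] = 5.0  # diagonal-adjacent same level
    sl = AnnotatedSlice(img, np.ones((4, 4), bool), (1.0, 1.0), "T2w")
    Z = glszm_matrix(discretize(sl, 2))
    assert Z[1, 1] == 1  # one zone of size 2 at the high level
    img2 = np.zeros((4, 4))
    img2[0, 0] = img2[2, 3] = 5.0  # not adjacent: two singleton zones
    Z2 = glszm_matrix(discretize(AnnotatedSlice(img2, np.ones((4, 4), bool),
                                                (1.0, 1.0), "T2w"), 2))
    assert Z2[1, 0] == 2


def test_ngtdm_constant_coarseness_capped():
    d_roi = discretize(const_slice(shape=(3, 3)), 32)
    f = ngtdm_features(d_roi)
    assert f["Coarseness"] == 1e6
    assert f["Contrast"] == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence (the load-bearing texture correctness test)


def test_texture_features_match_enumeration_oracles(roi_factory):
    """All five texture classes match brute-force enumeration to 1e-9 on
    random 8x8 ROIs (including ragged masks and unseen levels)."""
    for _ in range(8):
        d = roi_factory(size=8, ng=5)
        n_pix = int(d.mask.sum())

        per_dir = [oracle_glcm_features(oracle_glcm(d.levels, d.mask, d.n_levels, off),
                                        d.n_levels) for off in DIRECTIONS_2D]
        got = glcm_features(d)
        for k in got:
            want = np.mean([f[k] for f in per_dir])
            assert got[k] == pytest.approx(want, abs=1e-9), f"glcm {k}"

        keymap16 = ["Small", "Large", "GLN", "GLNN", "SN", "SNN", "Pct", "GLV", "SV",
                    "Entropy", "LGL", "HGL", "SmallLGL", "SmallHGL", "LargeLGL", "LargeHGL"]
        per_dir = [oracle_sized_features(oracle_runs(d.levels, d.mask, d.n_levels, off), n_pix)
                   for off in DIRECTIONS_2D]
        got = glrlm_features(d)
        for name, key in zip(got, keymap16):
            want = np.mean([f[key] for f in per_dir])
            assert got[name] == pytest.approx(want, abs=1e-9), f"glrlm {name}"

        got = glszm_features(d)
        want = oracle_sized_features(oracle_zones(d.levels, d.mask, d.n_levels), n_pix)
        for name, key in zip(got, keymap16):
            assert got[name] == pytest.approx(want[key], abs=1e-9), f"glszm {name}"

        keymap14 = ["Small", "Large", "GLN", "SN", "SNN", "GLV", "SV", "Entropy",
                    "LGL", "HGL", "SmallLGL", "SmallHGL", "LargeLGL", "LargeHGL"]
        got = gldm_features(d)
        want = oracle_sized_features(oracle_dependence(d.levels, d.mask, d.n_levels), n_pix)
        for name, key in zip(got, keymap14):
            assert got[name] == pytest.approx(want[key], abs=1e-9), f"gldm {name}"

        got = ngtdm_features(d)
        n_i, s_i = oracle_ngtdm(d.levels, d.mask, d.n_levels)
        want = oracle_ngtdm_features(n_i, s_i, d.n_levels)
        for k in got:
            assert got[k] == pytest.approx(want[k], abs=1e-9), f"ngtdm {k}"


def test_texture_not_permutation_invariant(rng):
    """Shuffling in-mask pixels changes texture (counterexample check)."""
    img = rng.normal(0, 1, (12, 12))
    img[3:9, 3:9] += np.linspace(0, 6, 6)[None, :]  # oriented structure
    mask = np.ones((12, 12), bool)
    sl = AnnotatedSlice(img, mask, (1.0, 1.0), "T2w")
    shuffled = img.copy()
    shuffled[mask] = rng.permutation(img[mask])
    sl2 = AnnotatedSlice(shuffled, mask, (1.0, 1.0), "T2w")
    f1 = glcm_features(discretize(sl, 8))
    f2 = glcm_features(discretize(sl2, 8))
    assert abs(f1["Contrast"] - f2["Contrast"]) > 1e-6


# ---------------------------------------------------------------------------
# feature matrix assembly


def test_build_feature_matrix_standardization(phantom_slice, rng):
    vecs = {}
    for seq in ("T2w", "T1c", "ADC"):
        sl = AnnotatedSlice(phantom_slice.pixels + rng.normal(0, 1, phantom_slice.pixels.shape),
                            phantom_slice.mask, (1.0, 1.0), seq)
        vecs[seq] = extract_sequence_features(sl)
    m_raw = build_feature_matrix(vecs)
    assert m_raw.values.shape == (3, 372)

    std = FeatureStandardizer().fit([m_raw])
    m_std = build_feature_matrix(vecs, standardizer=std)
    np.testing.assert_allclose(m_std.values.mean(axis=0), 0.0, atol=1e-9)


def test_build_feature_matrix_name_mismatch_rejected(phantom_slice):
    v = extract_sequence_features(phantom_slice)
    import dataclasses

    swapped = dataclasses.replace(v, names=tuple(reversed(v.names)))
    with pytest.raises(SchemaError):
        build_feature_matrix({"T2w": v, "T1c": swapped, "ADC": v})
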