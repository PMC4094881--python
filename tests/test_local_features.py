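"""Local pattern descriptors: brute-force oracle equivalence, mapping
tables, forced examples and invariances."""

import numpy as np
import pytest

from ihcloc.core import GrayImage
from ihcloc.local_features import (NeighborhoodConfig, clbp_codes,
                                   clbp_histogram, lbp_codes, lbp_histogram,
                                   ltrp_binary_codes, ltrp_histograms,
                                   riu2_table, to_gray_u8, u2_table)

from _oracles import (clbp_codes_bruteforce, lbp_codes_bruteforce,
                      ltrp_codes_bruteforce)
from conftest import random_gray_images


# ---------------------------------------------------------------------------
# pattern mapping tables
# ---------------------------------------------------------------------------

def test_riu2_table_enumeration():
    """riu2: uniform codes map to their bit count, 10 distinct bins."""
    m = riu2_table()
    assert m.table[0b00000000] == 0
    assert m.table[0b11111111] == 8
    assert m.table[0b01010101] == 9  # 8 transitions -> non-uniform bin
    assert len(set(m.table.tolist())) == 10
    # rotation invariance: circular shifts share a bin
    for code in range(256):
        rot = ((code << 1) | (code >> 7)) & 0xFF
        assert m.table[code] == m.table[rot]


def test_u2_table_enumeration():
    """u2: 58 uniform codes get their own bin + 1 shared bin = 59."""
    m = u2_table()
    assert len(set(m.table.tolist())) == 59
    assert set(m.table.tolist()) == set(range(59))  # surjection onto 0..58
    uniform = [c for c in range(256)
               if sum(((c >> k) & 1) != ((c >> ((k + 1) % 8)) & 1)
                      for k in range(8)) <= 2]
    assert len(uniform) == 58
    own_bins = [m.table[c] for c in uniform]
    assert len(set(own_bins)) == 58  # each uniform code has its own bin
    assert m.table[0b11111111] in own_bins


def test_mapping_tables_reject_unsupported_n():
    with pytest.raises(ValueError):
        riu2_table(N=16)
    with pytest.raises(ValueError):
        u2_table(N=4)


# ---------------------------------------------------------------------------
# per-pixel code oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_lbp_codes_match_bruteforce(seed):
    px = to_gray_u8(random_gray_images(1, seed=seed)[0])
    np.testing.assert_array_equal(lbp_codes(px), lbp_codes_bruteforce(px))


@pytest.mark.parametrize("seed", range(10))
def test_clbp_codes_match_bruteforce(seed):
    px = to_gray_u8(random_gray_images(1, seed=100 + seed)[0])
    s, m, c = clbp_codes(px)
    s_o, m_o, c_o = clbp_codes_bruteforce(px)
    np.testing.assert_array_equal(s, s_o)
    np.testing.assert_array_equal(m, m_o)
    np.testing.assert_array_equal(c, c_o)


@pytest.mark.parametrize("seed", range(10))
def test_ltrp_codes_match_bruteforce(seed):
    px = to_gray_u8(random_gray_images(1, shape=(7, 7), seed=200 + seed)[0])
    tetra, lp = ltrp_binary_codes(px)
    tetra_o, lp_o = ltrp_codes_bruteforce(px)
    np.testing.assert_array_equal(tetra, tetra_o)
    np.testing.assert_array_equal(lp, lp_o)


# ---------------------------------------------------------------------------
# forced examples
# ---------------------------------------------------------------------------

def test_lbp_constant_image_all_codes_255():
    """Ties code 1 (s(0)=1), so a flat image gives code 255 everywhere."""
    img = GrayImage(np.full((8, 8), 0.5))
    h = lbp_histogram(img)
    assert len(h) == 256
    assert h.values[255] == 1.0
    assert h.values.sum() == pytest.approx(1.0)


def test_clbp_constant_image_single_joint_bin():
    """Flat image: S=255 (riu2 bin 8), M=255 (tau=0, bin 8), C=1."""
    img = GrayImage(np.full((8, 8), 0.25))
    h = clbp_histogram(img)
    assert len(h) == 200
    assert h.values[8 * 20 + 8 * 2 + 1] == 1.0


def test_ltrp_monotone_ramp_concentrates_tetra_histograms():
    """On a ramp all directions are 1 so every tetra code is 0 and the 12
    tetra histograms put all mass on the u2 bin of code 0."""
    r, c = np.mgrid[0:10, 0:10]
    img = GrayImage((r + c) / 255.0)
    h = ltrp_histograms(img)
    assert len(h) == 767
    u2 = u2_table()
    zero_bin = u2.table[0]
    for p in range(12):
        sub = h.values[p * 59:(p + 1) * 59]
        assert sub[zero_bin] == 1.0


def test_small_image_rejected():
    with pytest.raises(ValueError):
        lbp_histogram(GrayImage(np.zeros((2, 2))))
    with pytest.raises(ValueError):
        ltrp_histograms(GrayImage(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("encoder", [lbp_histogram, clbp_histogram,
                                     ltrp_histograms])
def test_additive_intensity_invariance(encoder):
    """Adding a constant leaves differences, derivatives, tau and the
    centre-mean comparison unchanged, hence identical histograms."""
    base = random_gray_images(1, shape=(12, 12), seed=3, levels=200)[0]
    shifted = base + 40 / 255.0
    h0 = encoder(GrayImage(base)).values
    h1 = encoder(GrayImage(shifted)).values
    np.testing.assert_array_equal(h0, h1)


def test_clbp_rotation_invariance():
    """riu2-mapped joint histogram is invariant under 90-degree rotation
    (interior-only codes: the rotated interior is the interior)."""
    base = random_gray_images(1, shape=(16, 16), seed=9)[0]
    h0 = clbp_histogram(GrayImage(base)).values
    h90 = clbp_histogram(GrayImage(np.rot90(base))).values
    np.testing.assert_allclose(h0, h90, atol=1e-12)


@pytest.mark.parametrize("encoder,length", [
    (lbp_histogram, 256), (clbp_histogram, 200), (ltrp_histograms, 767),
])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_histograms_normalised_nonnegative(encoder, length, seed):
    img = GrayImage(random_gray_images(1, shape=(10, 10), seed=seed)[0])
    h = encoder(img)
    assert len(h) == length
    assert np.all(h.values >= 0)
    if encoder is ltrp_histograms:
        # 13 sub-histograms, each L1-normalised
        assert np.allclose(h.values.reshape(13, 59).sum(axis=1), 1.0,
                           atol=1e-9)
    else:
        assert h.values.sum() == pytest.approx(1.0, abs=1e-9)


def test_neighborhood_config_fixed():
    with pytest.raises(ValueError):
        NeighborhoodConfig(N=16, R=2)
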