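"""Synthetic IHC dataset generator: contracts, determinism, separability."""

import numpy as np
import pytest

from ihcloc.core import GrayImage, StainModel
from ihcloc.local_features import lbp_histogram
from ihcloc.synthetic import (MOTIFS, generate_dataset, nuclei_field,
                              read_dataset, render_densities, render_image,
                              write_dataset)


def test_six_proteins_zero_fraction_covers_every_class(small_dataset):
    """With n=6 and no multilabel proteins, coverage forces one single-label
    protein per class."""
    labels = [rec.label_set for rec in small_dataset.records]
    assert all(len(ls) == 1 for ls in labels)
    assert set().union(*labels) == {1, 2, 3, 4, 5, 6}


def test_multilabel_count_and_image_total():
    ds = generate_dataset(12, 3, 0.25, image_size=(64, 64), seed=7)
    n_multi = sum(len(r.label_set) >= 2 for r in ds.records)
    assert n_multi == 3
    assert ds.n_images == 36
    assert len({r.protein_id for r in ds.records}) == 12


@pytest.mark.parametrize("frac", [0.0, 0.3, 0.6])
def test_multilabel_fraction_within_rounding(frac):
    n = 20
    ds = generate_dataset(n, 1, frac, image_size=(32, 32), seed=3)
    got = sum(len(r.label_set) >= 2 for r in ds.records) / n
    assert abs(got - frac) <= 1.0 / n + 1e-12


def test_same_seed_bit_identical():
    a = generate_dataset(8, 2, 0.25, image_size=(48, 48), seed=7)
    b = generate_dataset(8, 2, 0.25, image_size=(48, 48), seed=7)
    for ra, rb in zip(a.records, b.records):
        assert ra.protein_id == rb.protein_id
        assert ra.label_set == rb.label_set
        for ia, ib in zip(ra.images, rb.images):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)


def test_different_seed_differs():
    a = generate_dataset(6, 1, 0.0, image_size=(48, 48), seed=1)
    b = generate_dataset(6, 1, 0.0, image_size=(48, 48), seed=2)
    assert not np.array_equal(a.records[0].images[0].pixels,
                              b.records[0].images[0].pixels)


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        generate_dataset(5, 1, 0.0)           # fewer proteins than classes
    with pytest.raises(ValueError):
        generate_dataset(6, 0, 0.0)           # no images
    with pytest.raises(ValueError):
        generate_dataset(6, 1, 0.0, image_size=(16, 16))  # motifs need room
    with pytest.raises(ValueError):
        render_densities(set(), np.random.default_rng(0), (48, 48))
    with pytest.raises(ValueError):
        render_densities({7}, np.random.default_rng(0), (48, 48))


def test_nuclear_motif_support_inside_dna_support():
    """The nucleus motif is the nuclei field modulated by a positive
    factor, so its support is contained in the DNA support."""
    rng = np.random.default_rng(4)
    protein, dna = render_densities({5}, rng, (64, 64))
    assert np.all((protein > 0) <= (dna > 0))


def test_two_label_superposition_is_pixelwise_max():
    """Re-drawing the same sub-streams shows the mixture rule."""
    seed_rng = np.random.default_rng(21)
    state = seed_rng.bit_generator.state
    protein, _ = render_densities({1, 6}, seed_rng, (48, 48))
    replay = np.random.default_rng(21)
    replay.bit_generator.state = state
    nuclei = nuclei_field(replay, (48, 48))
    m1 = MOTIFS[0](replay, (48, 48), nuclei)
    m6 = MOTIFS[5](replay, (48, 48), nuclei)
    np.testing.assert_array_equal(protein, np.maximum(m1, m6))


def test_rendered_pixels_clamped_to_unit_interval():
    sm = StainModel(noise_sd=0.1)
    img = render_image({1, 5}, sm, (48, 48), np.random.default_rng(0))
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0


def chi_square(h1, h2):
    denom = h1 + h2
    mask = denom > 0
    return 0.5 * ((h1 - h2) ** 2)[mask].__truediv__(denom[mask]).sum()


def test_motif_lbp_histograms_pairwise_distinct():
    """Mean 256-bin LBP histograms over 20 renders per class are pairwise
    separated in chi-square distance — the texture signal the end-to-end
    classification relies on."""
    sm = StainModel()
    means = []
    for label in range(1, 7):
        hs = []
        for i in range(20):
            rng = np.random.default_rng(1000 * label + i)
            img = render_image({label}, sm, (64, 64), rng)
            # protein-channel proxy: luminance works for separability
            gray = img.pixels.mean(axis=2)
            hs.append(lbp_histogram(GrayImage(gray)).values)
        means.append(np.mean(hs, axis=0))
    for a in range(6):
        for b in range(a + 1, 6):
            assert chi_square(means[a], means[b]) > 0.01, (a + 1, b + 1)


def test_manifest_round_trip(tmp_path):
    ds = generate_dataset(6, 2, 0.0, image_size=(48, 48), seed=9)
    manifest = write_dataset(ds, tmp_path)
    assert manifest.exists()
    back = read_dataset(manifest)
    assert {r.protein_id for r in back.records} == \
           {r.protein_id for r in ds.records}
    orig = {r.protein_id: r.label_set for r in ds.records}
    for rec in back.records:
        assert rec.label_set == orig[rec.protein_id]
        assert len(rec.images) == 2
    # 8-bit round trip: pixels agree to within one quantisation step
    a = ds.records[0].images[0].pixels
    b = next(r for r in back.records
             if r.protein_id == ds.records[0].protein_id).images[0].pixels
    assert np.abs(a - b).max() <= 1.0 / 255.0 + 1e-12
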