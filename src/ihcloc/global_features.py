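"""Global subcellular-location features (SLFs).

Two blocks:

* ``haralick_block`` — 836 wavelet-domain texture features from the protein
  channel: 26 GLCM statistics (13 Haralick features x {mean, range} over the
  four unit-distance offsets) on each of 32 images — the protein channel
  itself, the deepest approximation band and the 30 detail subbands of a
  10-level Daubechies decomposition — plus 4 first-order intensity
  statistics (mean, variance, skewness, kurtosis).  26*32 + 4 = 836.
* ``dna_overlap_block`` — 4 features relating the protein distribution to
  the DNA (nuclear) channel.

GLCM construction goes through :func:`skimage.feature.graycomatrix`; the 13
classic Haralick statistics are computed here with explicit zero-variance
conventions so constant subbands never produce NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats as sstats
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu

from .core import ChannelPair, FeatureBlock, GrayImage

log = logging.getLogger(__name__)

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "diff_variance", "diff_entropy", "imc1", "imc2",
)


@dataclass(frozen=True)
class WaveletConfig:
    """Daubechies wavelet family member (db1..db10) and decomposition depth."""

    wavelet_name: str = "db6"
    levels: int = 10

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not self.wavelet_name.startswith("db"):
            raise ValueError("expected a Daubechies wavelet (db1..db10)")


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_13(glcm: np.ndarray) -> np.ndarray:
    """13 Haralick statistics of one normalised symmetric GLCM.

    Zero-variance conventions: correlation and both information measures of
    correlation are 0 when the relevant variance/entropy vanishes; an empty
    (all-zero) GLCM yields all-zero features.
    """
    L = glcm.shape[0]
    total = glcm.sum()
    if total == 0:
        return np.zeros(13)
    p = glcm / total
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()

    # p_{x+y} over 0..2L-2 and p_{x-y} over 0..L-1
    pxy_sum = np.zeros(2 * L - 1)
    np.add.at(pxy_sum, (ii + jj).ravel(), p.ravel())
    pxy_diff = np.zeros(L)
    np.add.at(pxy_diff, np.abs(ii - jj).ravel(), p.ravel())

    asm = (p**2).sum()
    contrast = (np.arange(L) ** 2 * pxy_diff).sum()
    if var_x > 0 and var_y > 0:
        correlation = (((ii - mu_x) * (jj - mu_y) * p).sum()
                       / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    k = np.arange(2 * L - 1)
    sum_average = (k * pxy_sum).sum()
    sum_variance = ((k - sum_average) ** 2 * pxy_sum).sum()
    sum_entropy = -_xlogx(pxy_sum).sum()
    entropy = -_xlogx(p).sum()
    d = np.arange(L)
    diff_mean = (d * pxy_diff).sum()
    diff_variance = ((d - diff_mean) ** 2 * pxy_diff).sum()
    diff_entropy = -_xlogx(pxy_diff).sum()

    hx = -_xlogx(px).sum()
    hy = -_xlogx(py).sum()
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = -(p[nz] * np.log2(outer[nz])).sum()
    nzo = outer > 0
    hxy2 = -(outer[nzo] * np.log2(outer[nzo])).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array([
        asm, contrast, correlation, variance, idm,
        sum_average, sum_variance, sum_entropy, entropy,
        diff_variance, diff_entropy, imc1, imc2,
    ])


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantise a float image to integer levels 0..levels-1."""
    img = np.asarray(img, float)
    lo, hi = img.min(), img.max()
    # dynamic range at roundoff scale is constant for texture purposes
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_stats(img: np.ndarray, glcm_levels: int = 32,
               glcm_distance: int = 1) -> np.ndarray:
    """Mean and range over the 4 offsets of the 13 Haralick features (26)."""
    q = _quantize(img, glcm_levels)
    if q.ndim != 2 or min(q.shape) < 1:
        return np.zeros(26)
    mats = graycomatrix(
        q, distances=[glcm_distance], angles=list(GLCM_ANGLES),
        levels=glcm_levels, symmetric=True, normed=False,
    )
    per_angle = np.stack(
        [haralick_13(mats[:, :, 0, a].astype(float))
         for a in range(len(GLCM_ANGLES))]
    )
    return np.concatenate([per_angle.mean(axis=0),
                           per_angle.max(axis=0) - per_angle.min(axis=0)])


def wavelet_subbands(px: np.ndarray, cfg: WaveletConfig) -> list[tuple[str, np.ndarray]]:
    """Deepest approximation plus all detail subbands, labelled by level.

    Symmetric boundary extension; the decomposition is run to ``cfg.levels``
    even past the nominal maximum useful level (subbands stop shrinking at
    the filter length), matching a fixed-depth multiresolution protocol.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(px, cfg.wavelet_name, mode="symmetric",
                               level=cfg.levels)
    out = [(f"a{cfg.levels}", coeffs[0])]
    # coeffs[1] holds level `levels`, coeffs[-1] holds level 1
    for idx, (ch, cv, cd) in enumerate(coeffs[1:]):
        level = cfg.levels - idx
        out.extend([(f"h{level}", ch), (f"v{level}", cv), (f"d{level}", cd)])
    return out


def haralick_block(protein: GrayImage, cfg: WaveletConfig = WaveletConfig(),
                   glcm_levels: int = 32, glcm_distance: int = 1) -> FeatureBlock:
    """836-dimensional wavelet-Haralick feature block of the protein channel."""
    px = protein.pixels
    images = [("orig", px)] + wavelet_subbands(px, cfg)
    values, names = [], []
    for tag, img in images:
        stats26 = glcm_stats(img, glcm_levels, glcm_distance)
        values.append(stats26)
        names.extend(f"har_{tag}_{kind}_{f}"
                     for kind in ("mean", "range") for f in HARALICK_NAMES)
    flat = px.ravel()
    var = flat.var()
    degenerate = var <= 1e-20  # near-constant: higher moments undefined
    first_order = np.nan_to_num(np.array([
        flat.mean(),
        var,
        sstats.skew(flat) if not degenerate else 0.0,
        sstats.kurtosis(flat) if not degenerate else 0.0,
    ]))
    values.append(first_order)
    names.extend(["int_mean", "int_variance", "int_skewness", "int_kurtosis"])
    return FeatureBlock(np.concatenate(values), names, "HARALICK")


def _otsu_or_none(px: np.ndarray) -> float | None:
    try:
        return float(threshold_otsu(px))
    except ValueError:  # constant image
        return None


def dna_overlap_block(pair: ChannelPair, protein_threshold: float | None = None,
                      dna_threshold: float | None = None) -> FeatureBlock:
    """4 DNA-protein overlap features.

    1. fraction of above-threshold protein mass inside the DNA mask,
    2. fraction of above-threshold DNA mass inside the protein mask,
    3. Pearson correlation of the two channels,
    4. ratio of mean protein intensity inside vs outside the DNA mask.

    Thresholds default to per-channel Otsu.  Degenerate cases (empty masks,
    constant channels) yield 0 with a logged warning.
    """
    prot = pair.protein.pixels
    dna = pair.dna.pixels
    tp = protein_threshold if protein_threshold is not None else _otsu_or_none(prot)
    td = dna_threshold if dna_threshold is not None else _otsu_or_none(dna)
    prot_mask = prot > tp if tp is not None else np.zeros(prot.shape, bool)
    dna_mask = dna > td if td is not None else np.zeros(dna.shape, bool)

    prot_mass = (prot * prot_mask).sum()
    dna_mass = (dna * dna_mask).sum()
    if prot_mass > 0:
        f1 = (prot * prot_mask * dna_mask).sum() / prot_mass
    else:
        log.warning("dna_overlap: empty protein mask; feature 1 set to 0")
        f1 = 0.0
    if dna_mass > 0:
        f2 = (dna * dna_mask * prot_mask).sum() / dna_mass
    else:
        log.warning("dna_overlap: empty DNA mask; feature 2 set to 0")
        f2 = 0.0

    if prot.std() > 0 and dna.std() > 0:
        f3 = float(np.corrcoef(prot.ravel(), dna.ravel())[0, 1])
    else:
        f3 = 0.0

    inside = prot[dna_mask]
    outside = prot[~dna_mask]
    if inside.size and outside.size and outside.mean() > 0:
        f4 = float(inside.mean() / outside.mean())
    else:
        log.warning("dna_overlap: degenerate DNA mask; feature 4 set to 0")
        f4 = 0.0

    names = ["dna_prot_in_dna", "dna_dna_in_prot", "dna_corr", "dna_in_out_ratio"]
    return FeatureBlock(np.array([f1, f2, f3, f4]), names, "DNA")
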