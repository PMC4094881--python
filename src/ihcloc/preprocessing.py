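"""Image quality control and two-stain linear colour separation.

IHC-style images mix two chromogens: a brown protein stain and a purple
DNA (nuclear) stain.  ``hue_qc`` screens out badly stained images by their
mean hue in HSV space; ``linear_separation`` unmixes each pixel into
protein and DNA stain coefficients by least squares against a fixed
two-vector stain basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .core import ChannelPair, GrayImage, RgbImage, StainModel

DEFAULT_HUE_THRESHOLD = 13.0  # on the 0-255 integer hue scale


@dataclass(frozen=True)
class HueQcResult:
    passed: bool
    mean_hue: float  # 0-255 scale unless degrees=True was requested


def hue_qc(
    image: RgbImage,
    hue_threshold: float = DEFAULT_HUE_THRESHOLD,
    *,
    saturation_min: float = 0.05,
    include_achromatic: bool = True,
    fail_above: bool = True,
    degrees: bool = False,
) -> HueQcResult:
    """Mean-hue quality control.

    The statistic is the mean hue over the image on the 0-255 integer hue
    scale (0-360 if ``degrees``).  Hue is undefined at zero saturation, so
    near-achromatic pixels (saturation <= ``saturation_min``) contribute
    hue 0 by default — brown-stained images over a neutral background then
    score low while cyan-cast images score high, which is what the
    threshold targets.  Set ``include_achromatic=False`` to average over
    saturated pixels only.  ``fail_above`` sets the polarity: by default
    the image fails iff the statistic exceeds the threshold.

    The statistic is always returned for audit, pass or fail.
    """
    hsv = rgb2hsv(np.clip(image.pixels, 0.0, 1.0))
    hue = hsv[..., 0]  # [0, 1)
    sat = hsv[..., 1]
    chromatic = sat > saturation_min
    if include_achromatic:
        vals = np.where(chromatic, hue, 0.0).ravel()
    else:
        vals = hue[chromatic]
    mean01 = float(vals.mean()) if vals.size else 0.0
    scale = 360.0 if degrees else 255.0
    mean_hue = mean01 * scale
    exceeded = mean_hue > hue_threshold
    passed = not exceeded if fail_above else exceeded
    return HueQcResult(passed=passed, mean_hue=mean_hue)


def linear_separation(
    image: RgbImage,
    stain_model: StainModel,
    *,
    rescale_percentile: float = 99.0,
) -> ChannelPair:
    """Per-pixel least-squares unmixing into protein and DNA channels.

    Solves ``rgb - background ~= a * protein_basis + b * dna_basis`` for
    every pixel, clamps negative coefficients to zero, then rescales each
    coefficient map by its ``rescale_percentile`` value (robust to single
    hot pixels) and clamps to [0, 1].  Exact on noiseless two-stain
    mixtures.
    """
    basis = stain_model.basis_matrix()
    if np.linalg.matrix_rank(basis) < 2:
        raise ValueError("stain basis is degenerate (collinear vectors)")
    diff = image.pixels - stain_model.background_rgb  # (H, W, 3)
    coeffs = diff.reshape(-1, 3) @ np.linalg.pinv(basis).T  # (H*W, 2)
    coeffs = np.clip(coeffs, 0.0, None)
    maps = coeffs.reshape(image.pixels.shape[:2] + (2,))

    out = []
    for k in range(2):
        m = maps[..., k]
        ref = np.percentile(m, rescale_percentile)
        # a vanishing reference means the stain is absent: keep the
        # channel at zero instead of amplifying numerical residue
        if ref > 1e-9:
            m = m / ref
        else:
            m = np.zeros_like(m)
        out.append(GrayImage(np.clip(m, 0.0, 1.0), source_id=image.source_id))
    return ChannelPair(protein=out[0], dna=out[1])
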