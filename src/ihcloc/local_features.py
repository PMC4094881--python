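"""Local texture pattern descriptors: LBP, CLBP and LTrP.

All three encoders share the same neighbourhood: the 8 integer-grid
neighbours at radius 1, enumerated from the east neighbour counterclockwise
(E, NE, N, NW, W, SW, S, SE).  Images are quantised to 8-bit gray before
encoding so tie semantics (``s(0) = 1``) are exact, and codes are computed
only for pixels whose full neighbourhood (and, for LTrP, derivative
support) lies inside the image — no padding, no fabricated patterns.

Descriptor layouts
------------------
LBP    raw 256-bin histogram of the sign codes (no pattern mapping).
CLBP   joint 3-D histogram of the riu2-mapped sign and magnitude codes and
       the centre-pixel bit: 10 x 10 x 2 = 200 bins.
LTrP   second order: 12 binary tetra patterns (4 centre directions x 3
       off-directions) plus one derivative-magnitude pattern, each
       histogrammed under the u2 mapping: 13 x 59 = 767 features.

Every histogram is L1-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureBlock, GrayImage

# (row, col) offsets: east, then counterclockwise.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # E
    (-1, 1),   # NE
    (-1, 0),   # N
    (-1, -1),  # NW
    (0, -1),   # W
    (1, -1),   # SW
    (1, 0),    # S
    (1, 1),    # SE
)


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Ring configuration; this implementation fixes N=8, R=1."""

    N: int = 8
    R: int = 1

    def __post_init__(self) -> None:
        if self.N != 8 or self.R != 1:
            raise ValueError("only N=8, R=1 neighbourhoods are supported")


@dataclass
class PatternMapping:
    """Map from 8-bit codes to histogram bins."""

    kind: str            # "none" | "u2" | "riu2"
    table: np.ndarray    # length 256, int
    n_bins: int

    def __post_init__(self) -> None:
        expected = {"none": 256, "u2": 59, "riu2": 10}
        if self.kind not in expected:
            raise ValueError(f"unknown mapping kind {self.kind!r}")
        if self.n_bins != expected[self.kind]:
            raise ValueError(f"{self.kind} mapping must have {expected[self.kind]} bins")
        if len(self.table) != 256:
            raise ValueError("mapping table must cover all 256 codes")


def _transitions(code: int, n: int = 8) -> int:
    """Number of circular 0/1 transitions in an n-bit code."""
    bits = [(code >> k) & 1 for k in range(n)]
    return sum(bits[k] != bits[(k + 1) % n] for k in range(n))


def identity_table() -> PatternMapping:
    return PatternMapping("none", np.arange(256), 256)


def riu2_table(N: int = 8) -> PatternMapping:
    """Rotation-invariant uniform mapping: 10 bins for 8-bit codes.

    Uniform codes (<= 2 circular transitions) map to their set-bit count
    (0..8); all non-uniform codes share bin 9.
    """
    if N != 8:
        raise ValueError("riu2_table supports N=8 only")
    table = np.empty(256, dtype=int)
    for code in range(256):
        if _transitions(code) <= 2:
            table[code] = bin(code).count("1")
        else:
            table[code] = 9
    return PatternMapping("riu2", table, 10)


def u2_table(N: int = 8) -> PatternMapping:
    """Uniform mapping: each uniform code keeps its own bin, 59 bins total."""
    if N != 8:
        raise ValueError("u2_table supports N=8 only")
    table = np.empty(256, dtype=int)
    nxt = 0
    for code in range(256):
        if _transitions(code) <= 2:
            table[code] = nxt
            nxt += 1
        else:
            table[code] = 58
    assert nxt == 58  # 58 uniform codes for N=8
    return PatternMapping("u2", table, 59)


def to_gray_u8(image: GrayImage | np.ndarray) -> np.ndarray:
    """Quantise a [0,1] gray image to integer 0..255."""
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    return np.clip(np.rint(px * 255.0), 0, 255).astype(np.int64)


def _check_size(px: np.ndarray, min_side: int) -> None:
    if px.shape[0] < min_side or px.shape[1] < min_side:
        raise ValueError(f"image must be at least {min_side}x{min_side}")


def _neighbor_stack(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (center, neighbors) for interior pixels.

    center: (H-2, W-2); neighbors: (8, H-2, W-2) in NEIGHBOR_OFFSETS order.
    """
    c = px[1:-1, 1:-1]
    stacked = np.stack(
        [px[1 + dr : px.shape[0] - 1 + dr, 1 + dc : px.shape[1] - 1 + dc]
         for dr, dc in NEIGHBOR_OFFSETS]
    )
    return c, stacked


def _pack_bits(bits: np.ndarray) -> np.ndarray:
    """bits: (8, ...) 0/1 -> sum 2^k * bit_k."""
    weights = (1 << np.arange(8)).reshape((8,) + (1,) * (bits.ndim - 1))
    return (bits * weights).sum(axis=0)


def _hist(codes: np.ndarray, mapping: PatternMapping) -> np.ndarray:
    mapped = mapping.table[codes.ravel()]
    h = np.bincount(mapped, minlength=mapping.n_bins).astype(float)
    total = h.sum()
    return h / total if total > 0 else h


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def lbp_codes(px: np.ndarray) -> np.ndarray:
    """Per-pixel LBP codes on the interior of an integer gray image."""
    c, nb = _neighbor_stack(px)
    return _pack_bits((nb - c >= 0).astype(np.int64))


def lbp_histogram(
    image: GrayImage,
    cfg: NeighborhoodConfig = NeighborhoodConfig(),
    mapping: PatternMapping | None = None,
) -> FeatureBlock:
    """Standard LBP histogram; default is the unmapped 256-bin variant."""
    if mapping is None:
        mapping = identity_table()
    px = to_gray_u8(image)
    _check_size(px, 3)
    h = _hist(lbp_codes(px), mapping)
    names = [f"lbp_{mapping.kind}_{i}" for i in range(mapping.n_bins)]
    return FeatureBlock(h, names, "LBP")


# ---------------------------------------------------------------------------
# CLBP
# ---------------------------------------------------------------------------

def clbp_codes(px: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (S, M, C) codes on the interior of an integer gray image.

    S is the sign code (identical to LBP).  M thresholds the neighbour
    difference magnitudes m_k = |g_k - g_c| at tau, the image-wide mean of
    all m_k.  C compares the centre gray value with the image mean.
    """
    c, nb = _neighbor_stack(px)
    d = nb - c
    s_code = _pack_bits((d >= 0).astype(np.int64))
    m = np.abs(d)
    tau = m.mean()
    m_code = _pack_bits((m - tau >= 0).astype(np.int64))
    c_bit = (c - px.mean() >= 0).astype(np.int64)
    return s_code, m_code, c_bit


def clbp_histogram(
    image: GrayImage, cfg: NeighborhoodConfig = NeighborhoodConfig()
) -> FeatureBlock:
    """Joint (S_riu2, M_riu2, C) histogram, 10*10*2 = 200 bins.

    Flattening order: index = s_bin*20 + m_bin*2 + c_bit (C fastest).
    """
    px = to_gray_u8(image)
    _check_size(px, 3)
    riu2 = riu2_table()
    s_code, m_code, c_bit = clbp_codes(px)
    joint = (
        riu2.table[s_code.ravel()] * 20
        + riu2.table[m_code.ravel()] * 2
        + c_bit.ravel()
    )
    h = np.bincount(joint, minlength=200).astype(float)
    h /= h.sum()
    names = [
        f"clbp_s{s}_m{m}_c{c}"
        for s in range(10) for m in range(10) for c in range(2)
    ]
    return FeatureBlock(h, names, "CLBP")


# ---------------------------------------------------------------------------
# LTrP
# ---------------------------------------------------------------------------

def ltrp_direction_field(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-order derivative direction (1..4) and magnitude per pixel.

    Forward differences: dh = I(r, c+1) - I(r, c), dv = I(r+1, c) - I(r, c);
    defined on the (H-1, W-1) grid where both neighbours exist.  Direction
    quadrants: 1 (dh>=0, dv>=0), 2 (dh<0, dv>=0), 3 (dh<0, dv<0),
    4 (dh>=0, dv<0).
    """
    dh = (px[:-1, 1:] - px[:-1, :-1]).astype(float)
    dv = (px[1:, :-1] - px[:-1, :-1]).astype(float)
    direction = np.where(
        dh >= 0,
        np.where(dv >= 0, 1, 4),
        np.where(dv >= 0, 2, 3),
    )
    magnitude = np.sqrt(dh**2 + dv**2)
    return direction, magnitude


def ltrp_binary_codes(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel LTrP codes: (12, h, w) tetra binary codes and (h, w) LP.

    The 12 tetra code images are indexed by (centre direction d in 1..4,
    off-direction v != d in ascending order): for a centre pixel of
    direction d, tetra pattern (d, v) has bit k set iff neighbour k's
    direction is v; centre pixels of any other direction contribute the
    all-zero code to that pattern image.
    """
    direction, magnitude = ltrp_direction_field(px)
    dc, dn = _neighbor_stack(direction)
    mc, mn = _neighbor_stack(magnitude)

    tetra = []
    for d in (1, 2, 3, 4):
        center_is_d = dc == d
        for v in (x for x in (1, 2, 3, 4) if x != d):
            bits = (center_is_d & (dn == v)).astype(np.int64)
            tetra.append(_pack_bits(bits))
    lp = _pack_bits((mn - mc >= 0).astype(np.int64))
    return np.stack(tetra), lp


def ltrp_histograms(
    image: GrayImage, cfg: NeighborhoodConfig = NeighborhoodConfig()
) -> FeatureBlock:
    """Second-order LTrP feature vector: 13 u2 histograms, 767 features."""
    px = to_gray_u8(image)
    _check_size(px, 4)
    u2 = u2_table()
    tetra, lp = ltrp_binary_codes(px)
    parts, names = [], []
    pattern_ids = [
        f"d{d}v{v}" for d in (1, 2, 3, 4) for v in (1, 2, 3, 4) if v != d
    ] + ["lp"]
    for pid, codes in zip(pattern_ids, list(tetra) + [lp]):
        parts.append(_hist(codes, u2))
        names.extend(f"ltrp_{pid}_{i}" for i in range(u2.n_bins))
    return FeatureBlock(np.concatenate(parts), names, "LTRP")
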