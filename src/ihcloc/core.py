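"""Core containers shared across the pipeline.

Images are plain float arrays in [0, 1] wrapped with a source identifier;
feature vectors carry their names so every column of a feature matrix is
traceable to the descriptor that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six subcellular location classes, in canonical (1-based) label order.
CLASS_NAMES: tuple[str, ...] = (
    "cytoplasm",
    "er",
    "golgi",
    "mitochondria",
    "nucleus",
    "vesicles",
)

N_CLASSES = len(CLASS_NAMES)


@dataclass
class GrayImage:
    """Single-channel image with intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage expects a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RgbImage:
    """Three-channel image with intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RgbImage expects an (H, W, 3) array")
        if self.pixels.size == 0:
            raise ValueError("RgbImage is empty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RgbImage contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ChannelPair:
    """Separated protein (DAB-like) and DNA (hematoxylin-like) channels."""

    protein: GrayImage
    dna: GrayImage

    def __post_init__(self) -> None:
        if self.protein.shape != self.dna.shape:
            raise ValueError("protein and dna channels must share a shape")


@dataclass
class StainModel:
    """Linear two-stain colour model: pixel = background + a*protein + b*dna.

    The stain vectors are stored normalised to unit length; they must be
    linearly independent for the unmixing solve to be well posed.
    """

    protein_stain_rgb: np.ndarray = field(
        default_factory=lambda: np.array([0.65, 0.45, 0.25])
    )
    dna_stain_rgb: np.ndarray = field(
        default_factory=lambda: np.array([0.45, 0.35, 0.60])
    )
    background_rgb: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.10, 0.10])
    )
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        self.protein_stain_rgb = _unit(np.asarray(self.protein_stain_rgb, float))
        self.dna_stain_rgb = _unit(np.asarray(self.dna_stain_rgb, float))
        self.background_rgb = np.asarray(self.background_rgb, float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if np.linalg.matrix_rank(self.basis_matrix()) < 2:
            raise ValueError("stain basis vectors are collinear")

    def basis_matrix(self) -> np.ndarray:
        """3x2 matrix with the protein and DNA stain bases as columns."""
        return np.column_stack([self.protein_stain_rgb, self.dna_stain_rgb])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass
class FeatureBlock:
    """Named feature vector produced by one descriptor."""

    values: np.ndarray
    names: list[str]
    block_id: str

    VALID_IDS = ("HARALICK", "DNA", "LBP", "CLBP", "LTRP")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FeatureBlock values must be 1-D")
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if self.block_id not in self.VALID_IDS:
            raise ValueError(f"unknown block_id {self.block_id!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite features in block {self.block_id}")

    def __len__(self) -> int:
        return len(self.values)


def concat_blocks(blocks: list[FeatureBlock]) -> tuple[np.ndarray, list[str], list[str]]:
    """Concatenate feature blocks -> (values, names, per-feature block ids)."""
    values = np.concatenate([b.values for b in blocks])
    names = [n for b in blocks for n in b.names]
    ids = [b.block_id for b in blocks for _ in b.names]
    return values, names, ids


@dataclass
class ProteinRecord:
    """All images of one protein with its ground-truth label set."""

    protein_id: str
    label_set: frozenset[int]
    images: list[RgbImage]

    def __post_init__(self) -> None:
        self.label_set = frozenset(int(l) for l in self.label_set)
        if not self.label_set:
            raise ValueError("label_set must be nonempty")
        if not self.label_set <= set(range(1, N_CLASSES + 1)):
            raise ValueError("labels must be in 1..6")
        if len(self.label_set) > 3:
            raise ValueError("label_set has at most 3 labels")

    def label_vector(self) -> np.ndarray:
        """+/-1 vector of length 6 (1-based labels -> 0-based positions)."""
        y = -np.ones(N_CLASSES)
        for l in self.label_set:
            y[l - 1] = 1.0
        return y


@dataclass
class Dataset:
    """Protein-grouped image collection."""

    records: list[ProteinRecord]
    class_names: tuple[str, ...] = CLASS_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_names) != N_CLASSES:
            raise ValueError("exactly 6 classes required")
        ids = [r.protein_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("protein_ids must be unique")

    @property
    def n_images(self) -> int:
        return sum(len(r.images) for r in self.records)

    def iter_images(self):
        """Yield (protein_record, image) pairs in stored order."""
        for rec in self.records:
            for img in rec.images:
                yield rec, img
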