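"""Seeded synthetic IHC-like image generation.

Real IHC images of protein subcellular location are two-stain colour
mixtures: a brown chromogen marks the target protein and a purple nuclear
stain marks DNA.  This module emulates exactly the structure the analysis
pipeline relies on — a linear two-stain RGB mixture over a neutral
background, a nuclei blob field shared by all classes, and one
distinguishable protein texture motif per subcellular class:

=============  ==================================================
cytoplasm      diffuse low-frequency field filling the cell area
er             reticular web (thin lace of ridges)
golgi          compact perinuclear patches hugging each nucleus
mitochondria   elongated granules (anisotropic strands)
nucleus        blobs coinciding with the nuclei field
vesicles       many small punctate spots
=============  ==================================================

Multi-label proteins superpose motifs by pixelwise maximum, which keeps
each class's texture statistics recognisable in mixtures.  One top-level
integer seed drives everything through numpy ``SeedSequence`` spawning, so
an identical seed reproduces the dataset bit for bit.

The motifs are this package's own construction: they are calibrated for
texture separability, not for photorealism.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .core import CLASS_NAMES, Dataset, ProteinRecord, RgbImage, StainModel

MIN_IMAGE_SIDE = 32
#: Among multilabel proteins, probability of a 3-label (vs 2-label) set;
#: mirrors a 7:83 split of 3-label to 2-label multilabel proteins.
THREE_LABEL_SHARE = 7 / 90


# ---------------------------------------------------------------------------
# density fields
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)

def nuclei_field(rng: np.random.Generator, shape) -> np.ndarray:
    """Compactly supported nuclei blob field (the DNA density)."""
    h, w = shape
    density = np.zeros(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    n_nuclei = int(rng.integers(5, 9))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
        r = rng.uniform(0.06, 0.10) * min(h, w)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 < r * r
        profile = np.where(inside, 1.0 - 0.5 * d2 / (r * r), 0.0)
        density = np.maximum(density, profile)
    return density


def _motif_cytoplasm(rng, shape, nuclei):
    base = _smooth_noise(rng, shape, sigma=0.08 * min(shape))
    return np.clip(0.25 + 0.55 * base, 0, 1) * (1.0 - 0.6 * nuclei)


def _motif_er(rng, shape, nuclei):
    g = _smooth_noise(rng, shape, sigma=0.03 * min(shape))
    level = np.median(g)
    width = 0.035
    web = np.exp(-((g - level) ** 2) / (2 * width**2))
    return np.clip(web, 0, 1) * 0.9


def _motif_golgi(rng, shape, nuclei):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    density = np.zeros(shape)
    n_patches = int(rng.integers(4, 8))
    for _ in range(n_patches):
        cy, cx = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
        r = rng.uniform(0.07, 0.11) * min(h, w)
        theta = rng.uniform(0, 2 * np.pi)
        py, px = cy + 1.3 * r * np.sin(theta), cx + 1.3 * r * np.cos(theta)
        # elongated anisotropic Gaussian patch tangent to the nucleus rim
        dy, dx = yy - py, xx - px
        u = dy * np.cos(theta) - dx * np.sin(theta)   # tangential
        v = dy * np.sin(theta) + dx * np.cos(theta)   # radial
        patch = np.exp(-(u**2 / (2 * (0.8 * r) ** 2) + v**2 / (2 * (0.3 * r) ** 2)))
        density = np.maximum(density, patch)
    return np.clip(density, 0, 1)


def _motif_mitochondria(rng, shape, nuclei):
    sigma_long = 0.05 * min(shape)
    sig = (0.8, sigma_long) if rng.random() < 0.5 else (sigma_long, 0.8)
    f = gaussian_filter(rng.standard_normal(shape), sig, mode="reflect")
    thr = np.quantile(f, 0.80)
    strands = np.where(f > thr, (f - thr) / (f.max() - thr + 1e-12), 0.0)
    return np.clip(3.0 * strands, 0, 1)


def _motif_nucleus(rng, shape, nuclei):
    modulation = 0.6 + 0.4 * _smooth_noise(rng, shape, sigma=0.02 * min(shape))
    return nuclei * modulation  # support is exactly the nuclei support


def _motif_vesicles(rng, shape, nuclei):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    density = np.zeros(shape)
    n_dots = int(rng.integers(40, 80) * (h * w) / (96 * 96))
    for _ in range(max(n_dots, 20)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(1.0, 2.5)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        density = np.maximum(density, np.where(d2 < (2.5 * r) ** 2,
                                               np.exp(-d2 / (2 * r * r)), 0.0))
    return np.clip(density, 0, 1)


#: Motif renderers in label order 1..6 (cytoplasm .. vesicles).
MOTIFS = (
    _motif_cytoplasm,
    _motif_er,
    _motif_golgi,
    _motif_mitochondria,
    _motif_nucleus,
    _motif_vesicles,
)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_densities(
    label_set, rng: np.random.Generator, size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Protein and DNA density fields for one image (both in [0, 1])."""
    labels = sorted(int(l) for l in label_set)
    if not labels:
        raise ValueError("label_set must be nonempty")
    if any(l < 1 or l > 6 for l in labels):
        raise ValueError("labels must be in 1..6")
    nuclei = nuclei_field(rng, size)
    protein = np.zeros(size)
    for l in labels:
        protein = np.maximum(protein, MOTIFS[l - 1](rng, size, nuclei))
    return protein, nuclei


def render_image(
    label_set,
    stain_model: StainModel,
    size: tuple[int, int],
    rng: np.random.Generator,
    source_id: str = "",
) -> RgbImage:
    """Render one RGB image: background + stains + clipped Gaussian noise."""
    protein, dna = render_densities(label_set, rng, size)
    rgb = (
        stain_model.background_rgb
        + 0.85 * protein[..., None] * stain_model.protein_stain_rgb
        + 0.80 * dna[..., None] * stain_model.dna_stain_rgb
    )
    if stain_model.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, stain_model.noise_sd, rgb.shape)
    return RgbImage(np.clip(rgb, 0.0, 1.0), source_id=source_id)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _assign_label_sets(n_proteins: int, multilabel_fraction: float,
                       rng: np.random.Generator) -> list[frozenset[int]]:
    n_multi = int(round(multilabel_fraction * n_proteins))
    n_multi = min(n_multi, n_proteins - 6)  # keep the 6 coverage singles
    label_sets: list[frozenset[int]] = [
        frozenset({l}) for l in range(1, 7)  # one single-label protein per class
    ]
    for _ in range(n_proteins - 6 - n_multi):
        label_sets.append(frozenset({int(rng.integers(1, 7))}))
    for _ in range(n_multi):
        k = 3 if rng.random() < THREE_LABEL_SHARE else 2
        label_sets.append(frozenset(rng.choice(6, size=k, replace=False) + 1))
    return label_sets


def generate_dataset(
    n_proteins: int,
    images_per_protein: int,
    multilabel_fraction: float,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    stain_model: StainModel | None = None,
) -> Dataset:
    """Generate a protein-grouped synthetic IHC dataset.

    The first six proteins carry one single label each (one per class) so
    every class is always represented; the requested multilabel fraction is
    met to within 1/n_proteins by rounding.
    """
    if n_proteins < 6:
        raise ValueError("n_proteins must be >= 6 (one per class)")
    if images_per_protein < 1:
        raise ValueError("images_per_protein must be >= 1")
    if min(image_size) < MIN_IMAGE_SIDE:
        raise ValueError(f"image_size below {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} "
                         "cannot hold the texture motifs")
    if not 0.0 <= multilabel_fraction <= 1.0:
        raise ValueError("multilabel_fraction must be in [0, 1]")
    if stain_model is None:
        stain_model = StainModel()

    root = np.random.SeedSequence(seed)
    label_rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
    label_sets = _assign_label_sets(n_proteins, multilabel_fraction, label_rng)

    records = []
    protein_seeds = root.spawn(n_proteins + 1)[1:]
    for p, (label_set, pseq) in enumerate(zip(label_sets, protein_seeds)):
        pid = f"prot{p:03d}"
        images = []
        for i, iseq in enumerate(pseq.spawn(images_per_protein)):
            rng = np.random.Generator(np.random.PCG64(iseq))
            images.append(render_image(label_set, stain_model, image_size,
                                       rng, source_id=f"{pid}_img{i:02d}"))
        records.append(ProteinRecord(pid, label_set, images))
    return Dataset(records=records, seed=seed)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, outdir: str | Path) -> Path:
    """Write 8-bit PNG images and a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        for img in rec.images:
            u8 = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.uint8)
            path = outdir / f"{img.source_id}.png"
            Image.fromarray(u8).save(path)
            labels = ";".join(str(l) for l in sorted(rec.label_set))
            rows.append((rec.protein_id, path.name, labels))
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "image_path", "labels"])
        writer.writerows(rows)
    return manifest


def read_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from a manifest CSV and its PNG images."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    groups: dict[str, tuple[frozenset[int], list[RgbImage]]] = {}
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["protein_id"]
            labels = frozenset(int(x) for x in row["labels"].split(";"))
            arr = np.asarray(Image.open(root / row["image_path"]), dtype=float) / 255.0
            img = RgbImage(arr, source_id=Path(row["image_path"]).stem)
            if pid not in groups:
                groups[pid] = (labels, [])
            groups[pid][1].append(img)
    records = [ProteinRecord(pid, labels, imgs)
               for pid, (labels, imgs) in groups.items()]
    return Dataset(records=records)
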