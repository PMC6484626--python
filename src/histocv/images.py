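"""Toy histology patch rendering and handcrafted feature extraction.

These rasters are deliberately cartoonish stand-ins for H&E-stained tissue:
an eosin-pink textured background with white elliptical "gland lumens"
whose count and size decrease monotonically with Gleason grade (benign
glands have many large lumens; grade 5 tissue has lost glandular structure
and gets none).  Patient- and core-level colour shifts added to the channel
means play the role of staining/sectioning batch effects — the image-space
version of the leakage mechanism.

Features extracted from a raster are 7 numbers: per-channel means,
per-channel variances, and edge density.  They feed the same downstream
pipeline as directly simulated feature vectors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classes import CLASSES

#: (lumen count, mean lumen radius in px) per class; monotone in grade
LUMEN_SPEC: dict[str, tuple[int, float]] = {
    "benign": (8, 7.0),
    "G3": (5, 4.5),
    "G4": (2, 3.0),
    "G5": (0, 0.0),
}

#: eosin-pink background mean (R, G, B), 8-bit scale
_BACKGROUND = np.array([195.0, 130.0, 170.0])
_LUMEN_COLOR = np.array([242.0, 238.0, 242.0])
_TEXTURE_SD = 8.0

#: gradient-magnitude threshold (on the [0, 1] intensity scale) above which
#: a pixel counts as an edge pixel
EDGE_THRESHOLD = 0.08

FEATURE_NAMES = (
    "mean_r", "mean_g", "mean_b",
    "var_r", "var_g", "var_b",
    "edge_density",
)


def render_patch_image(
    true_class: str,
    patient_shift,
    core_shift,
    seed: int,
    size: int = 64,
) -> np.ndarray:
    """Render a ``size x size x 3`` uint8 toy histology patch.

    ``patient_shift`` and ``core_shift`` are 3-vectors added to the mean
    channel intensities (8-bit scale) after the morphology is drawn;
    deterministic given all arguments.
    """
    if true_class not in CLASSES:
        raise ValueError(f"unknown class: {true_class!r}")
    patient_shift = np.asarray(patient_shift, dtype=float)
    core_shift = np.asarray(core_shift, dtype=float)
    if patient_shift.shape != (3,) or core_shift.shape != (3,):
        raise ValueError("shifts must be 3-vectors")

    rng = np.random.default_rng(int(seed))
    img = _BACKGROUND + rng.normal(0.0, _TEXTURE_SD, size=(size, size, 3))

    n_lumens, radius = LUMEN_SPEC[true_class]
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_lumens):
        cy, cx = rng.uniform(radius, size - radius, size=2)
        ry = radius * rng.uniform(0.7, 1.3)
        rx = radius * rng.uniform(0.7, 1.3)
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[mask] = _LUMEN_COLOR + rng.normal(0.0, 2.0, size=3)

    img = img + patient_shift + core_shift
    return np.clip(img, 0, 255).astype(np.uint8)


def extract_features(image: np.ndarray) -> np.ndarray:
    """7-vector of image descriptors: 3 channel means, 3 channel variances,
    and the fraction of pixels whose gradient magnitude (grayscale, [0, 1]
    scale) exceeds :data:`EDGE_THRESHOLD`."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) raster")
    x = image.astype(float) / 255.0
    means = x.mean(axis=(0, 1))
    variances = x.var(axis=(0, 1))
    gray = x.mean(axis=2)
    gy, gx = np.gradient(gray)
    magnitude = np.hypot(gx, gy)
    edge_density = float((magnitude > EDGE_THRESHOLD).mean())
    return np.concatenate([means, variances, [edge_density]])


def save_patch_images(images: dict[str, np.ndarray], directory: str | Path) -> None:
    """Write each raster as ``<patch_id>.png`` into ``directory``."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for patch_id, raster in images.items():
        Image.fromarray(raster).save(directory / f"{patch_id}.png")
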