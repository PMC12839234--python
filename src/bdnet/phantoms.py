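"""Synthetic fluorescence-like phantoms, image I/O, and dataset handling.

Real training data for this kind of denoiser are micrographs of labelled
cells (confocal / two-photon / wide-field), whose defining features are a
dim background, smooth intra-cellular intensity gradients, and thin bright
membranes — the sharp edges a gradient-aware loss is designed to protect.
``generate_phantom`` emulates exactly those features: elliptical cell
bodies with a smooth interior profile and a 1–2 px bright rim over a low
uniform background.

Image convention throughout the package: a single-channel 2D float array
with every value in [0, 1]; files on disk are 8-bit PNG/TIFF or 16-bit
TIFF, linearly scaled by the format's full-scale maximum (255 or 65535).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

BACKGROUND_LEVEL = 0.08


@dataclass(frozen=True)
class PairedSample:
    """One supervised training pair: a noisy observation and its clean
    reference, tagged with the acquisition noise level (frames averaged)
    and an imaging-modality label used for stratification."""

    noisy: np.ndarray
    clean: np.ndarray
    level: int = 1
    modality_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean images must share H×W")
        if self.level < 1:
            raise ValueError("level must be a positive integer")


def check_image(image: np.ndarray) -> np.ndarray:
    """Validate the [0, 1] single-channel image contract."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got shape {image.shape}")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("images must be at least 8×8")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return image


def generate_phantom(
    height: int,
    width: int,
    n_cells: int = 12,
    membrane_contrast: float = 0.6,
    seed: int = 0,
) -> np.ndarray:
    """Clean cell-like phantom: elliptical bodies with bright rims.

    Parameters
    ----------
    height, width:
        Output size in pixels, each at least 32.
    n_cells:
        Number of elliptical cell bodies; 0 gives the bare background.
    membrane_contrast:
        Brightness of the 1–2 px membrane rim relative to full scale,
        in [0, 1].
    seed:
        Seeds all random placement; identical seeds give identical images.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom dimensions must be at least 32×32")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if not 0.0 <= membrane_contrast <= 1.0:
        raise ValueError("membrane_contrast must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), BACKGROUND_LEVEL, dtype=np.float64)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(n_cells):
        cy = rng.uniform(0.1 * height, 0.9 * height)
        cx = rng.uniform(0.1 * width, 0.9 * width)
        a = rng.uniform(0.06, 0.16) * min(height, width)  # semi-axes in px
        b = rng.uniform(0.6, 1.0) * a
        theta = rng.uniform(0.0, np.pi)
        peak = rng.uniform(0.35, 0.65)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1.0 on the membrane
        interior = rho < 1.0
        # smooth interior gradient: brightest at the centre, dimming outwards
        img[interior] = np.maximum(
            img[interior], BACKGROUND_LEVEL + peak * (1.0 - 0.6 * rho[interior] ** 2)
        )
        # membrane: a thin rim ~1.5 px wide in pixel units
        rim_width = 1.5 / min(a, b)
        rim = np.abs(rho - 1.0) < rim_width
        img[rim] = np.maximum(img[rim], BACKGROUND_LEVEL + membrane_contrast)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# image files
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a grayscale PNG (8-bit) or TIFF (8/16-bit) as a [0, 1] image.

    Integer intensities are divided by the format's full-scale maximum, so
    the on-disk and in-memory scales are related by a fixed linear map.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name}: multi-channel image with shape {arr.shape}; "
            "split channels upstream, this pipeline is single-channel"
        )
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    return arr.astype(np.float64) / scale


def write_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale.

    Quantization uses round-half-even (numpy's rounding), so a read-back
    reproduces the image within half a quantization step.
    """
    image = check_image(image)
    if bit_depth == 8:
        arr = np.round(image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(image * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bit_depth == 16:
            raise ValueError("16-bit output requires a TIFF path")
        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(
    samples: list[PairedSample],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list[PairedSample], list[PairedSample], list[PairedSample]]:
    """Train/validation/test partition, stratified by (modality, level).

    Within every stratum the per-part counts are floor(fraction·n) with the
    leftovers assigned by largest fractional remainder (ties favouring the
    earlier part), so a 10-sample stratum under (0.7, 0.1, 0.2) yields
    exactly (7, 1, 2).  Strata with fewer than 3 samples go entirely to the
    training part (with a warning).
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, int], list[PairedSample]] = {}
    for s in samples:
        strata.setdefault((s.modality_tag, s.level), []).append(s)
    parts: tuple[list, list, list] = ([], [], [])
    for key in sorted(strata):
        members = strata[key]
        n = len(members)
        if n < 3:
            warnings.warn(
                f"stratum {key} has only {n} sample(s); assigning all to the training part",
                stacklevel=2,
            )
            parts[0].extend(members)
            continue
        order = rng.permutation(n)
        ideal = [f * n for f in fractions]
        counts = [int(np.floor(v)) for v in ideal]
        remainders = [v - c for v, c in zip(ideal, counts)]
        for _ in range(n - sum(counts)):
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1.0
        start = 0
        for part, count in zip(parts, counts):
            part.extend(members[i] for i in order[start : start + count])
            start += count
    return parts


def augment(pair: PairedSample, seed: int = 0) -> PairedSample:
    """Apply one of {identity, h-flip, v-flip, both}, uniformly at random,
    identically to the noisy and clean images (flips only, preserving the
    original morphology)."""
    rng = np.random.default_rng(seed)
    variant = int(rng.integers(0, 4))
    return apply_flip(pair, variant)


def apply_flip(pair: PairedSample, variant: int) -> PairedSample:
    """variant: 0 = identity, 1 = horizontal, 2 = vertical, 3 = both."""
    if variant == 0:
        return pair
    axes = {1: (1,), 2: (0,), 3: (0, 1)}[variant]
    return replace(
        pair,
        noisy=np.flip(pair.noisy, axis=axes).copy(),
        clean=np.flip(pair.clean, axis=axes).copy(),
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(rows: list[dict], path) -> None:
    """Plain CSV manifest: noisy_path, clean_path, level, modality_tag."""
    with open(path, "w") as fh:
        fh.write("noisy_path,clean_path,level,modality_tag\n")
        for r in rows:
            fh.write(f"{r['noisy_path']},{r['clean_path']},{r['level']},{r['modality_tag']}\n")


def read_manifest(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        expected = ["noisy_path", "clean_path", "level", "modality_tag"]
        if header != expected:
            raise ValueError(f"manifest header must be {','.join(expected)}")
        for line in fh:
            if not line.strip():
                continue
            noisy, clean, level, tag = line.strip().split(",")
            rows.append(
                {"noisy_path": noisy, "clean_path": clean, "level": int(level), "modality_tag": tag}
            )
    return rows


def load_pairs(manifest_path) -> list[PairedSample]:
    base = Path(manifest_path).parent
    pairs = []
    for row in read_manifest(manifest_path):
        noisy = read_image(base / row["noisy_path"])
        clean = read_image(base / row["clean_path"])
        pairs.append(PairedSample(noisy, clean, row["level"], row["modality_tag"]))
    return pairs
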