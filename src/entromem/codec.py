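"""Analysis/synthesis codecs: images to real feature vectors and back.

The memory proper never sees pixels; it stores discrete functions
derived from an *analysis* (encoder) step, and a *synthesis* (decoder)
step renders retrieved functions back into images.  Any encoder/decoder
pair can plug in through :class:`CodecSpec`.  The shipped
:func:`toy_encode`/:func:`toy_decode` pair is a deterministic block-mean
codec — no training — so the full pipeline runs end-to-end out of the
box: a 28×28 grayscale image is pooled to an 8×8 grid of block means
(64 features), and decoding paints each feature back over its block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from PIL import Image

IMAGE_SIZE = 28
GRID = 8
N_FEATURES = GRID * GRID

__all__ = [
    "CodecSpec",
    "toy_codec",
    "toy_encode",
    "toy_decode",
    "load_image_png",
    "save_image_png",
    "load_image_csv",
    "save_image_csv",
]


@dataclass(frozen=True)
class CodecSpec:
    """A pluggable analysis/synthesis pair.

    ``encode`` maps an H×W image with intensities in [0, 1] to an
    ``n``-feature real vector; ``decode`` maps such a vector back to an
    image.  Neural codecs attach here without touching the memory core.
    """

    encode: Callable[[np.ndarray], np.ndarray]
    decode: Callable[[np.ndarray], np.ndarray]
    n: int = N_FEATURES


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"expected a {IMAGE_SIZE}x{IMAGE_SIZE} image, got {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    return img


def _block_bounds(size: int = IMAGE_SIZE, parts: int = GRID) -> np.ndarray:
    # even partition of indices; 28 over 8 -> blocks of 4,4,4,4,3,3,3,3
    return np.array([len(a) for a in np.array_split(np.arange(size), parts)]).cumsum()


_BOUNDS = np.concatenate([[0], _block_bounds()])


def toy_encode(img: np.ndarray) -> np.ndarray:
    """8×8 block-mean pooling of a 28×28 image, flattened row-major."""
    img = _check_image(img)
    feats = np.empty(N_FEATURES)
    for r in range(GRID):
        for c in range(GRID):
            block = img[_BOUNDS[r]:_BOUNDS[r + 1], _BOUNDS[c]:_BOUNDS[c + 1]]
            feats[r * GRID + c] = block.mean()
    return feats


def toy_decode(features: np.ndarray) -> np.ndarray:
    """Nearest-neighbour upsampling of 64 features to a 28×28 image."""
    features = np.asarray(features, dtype=float)
    if features.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got shape {features.shape}")
    img = np.empty((IMAGE_SIZE, IMAGE_SIZE))
    for r in range(GRID):
        for c in range(GRID):
            img[_BOUNDS[r]:_BOUNDS[r + 1], _BOUNDS[c]:_BOUNDS[c + 1]] = features[
                r * GRID + c
            ]
    return np.clip(img, 0.0, 1.0)


toy_codec = CodecSpec(encode=toy_encode, decode=toy_decode, n=N_FEATURES)


# ----------------------------------------------------------------------
# image I/O: 8-bit grayscale PNG (intensity/255) and plain CSV matrices

def load_image_png(path: str) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return arr


def save_image_png(img: np.ndarray, path: str) -> None:
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(img * 255.0).astype(np.uint8), mode="L").save(path)


def load_image_csv(path: str) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=float)


def save_image_csv(img: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(img, dtype=float), delimiter=",", fmt="%.6f")
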