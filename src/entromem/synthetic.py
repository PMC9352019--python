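"""Seeded generators of class-structured corpora for the memory experiments.

Real deployments feed the memory with encoder outputs computed from
images of manuscript symbols; these generators emulate the statistical
structure that matters to the memory — ``c`` well-separated class
prototypes in feature space with bounded within-class dispersion —
without any external data or trained network.  Everything is
reproducible from the spec's seed.

Two generators ship:

* :func:`make_feature_corpus` — real-valued feature vectors per class
  (prototype plus clipped Gaussian noise), split into the train /
  remembered / test partitions the experiments expect (defaults
  57% / 33% / 10%),
* :func:`make_glyph_images` / :func:`make_glyph_corpus` — deterministic
  28×28 bar-motif glyphs, one base shape per class with small
  translation jitter, for the occlusion experiments.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .codec import IMAGE_SIZE

__all__ = [
    "FixtureSpec",
    "Partition",
    "Corpus",
    "make_feature_corpus",
    "make_glyph_images",
    "make_glyph_corpus",
    "default_glyph_spec",
    "save_corpus",
    "load_corpus",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic corpus.

    ``prototype_spread`` is the minimum mean absolute per-feature
    distance enforced between any two class prototypes (in levels);
    ``noise_sd`` the within-class standard deviation (levels).  Classes
    are separable by construction, so the spread must exceed the noise.
    """

    c: int = 36
    n: int = 64
    m: int = 64
    n_per_class: int = 300
    prototype_spread: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    fractions: tuple = (0.57, 0.33, 0.10)
    jitter: int = 2

    def __post_init__(self):
        if self.c < 1 or self.n < 1 or self.m < 1 or self.n_per_class < 1:
            raise ValueError("c, n, m and n_per_class must be positive")
        if self.prototype_spread <= self.noise_sd:
            raise ValueError("prototype_spread must exceed noise_sd")
        if len(self.fractions) != 3 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("partition fractions must be non-negative")


@dataclass(frozen=True)
class Partition:
    """One corpus partition: feature matrix (or image stack) plus labels."""

    X: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class Corpus:
    train: Partition
    remembered: Partition
    test: Partition
    spec: FixtureSpec = field(default_factory=FixtureSpec)


def _partition_sizes(n: int, fractions) -> tuple[int, int, int]:
    n_train = int(round(fractions[0] * n))
    n_rem = int(round(fractions[1] * n))
    n_test = n - n_train - n_rem
    if n_test < 0:
        n_rem += n_test
        n_test = 0
    return n_train, n_rem, n_test


def _draw_prototypes(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    protos = np.empty((spec.c, spec.n))
    for j in range(spec.c):
        for _ in range(1000):
            cand = rng.uniform(1.0, float(spec.m), size=spec.n)
            if j == 0:
                break
            sep = np.abs(protos[:j] - cand).mean(axis=1)
            if sep.min() >= spec.prototype_spread:
                break
        else:
            raise RuntimeError(
                "could not place separated prototypes; lower prototype_spread"
            )
        protos[j] = cand
    return protos


def make_feature_corpus(spec: FixtureSpec | None = None) -> Corpus:
    """Generate a labeled real-feature corpus split train/remembered/test.

    Per class, a prototype is drawn uniformly on ``[1, m]^n`` (redrawn
    until it sits at least ``prototype_spread`` mean-L1 levels from all
    earlier prototypes); each instance is the prototype plus zero-mean
    Gaussian noise of sd ``noise_sd``, clipped to ``[1, m]``.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    protos = _draw_prototypes(spec, rng)
    sizes = _partition_sizes(spec.n_per_class, spec.fractions)
    parts = {name: ([], []) for name in ("train", "remembered", "test")}
    for j in range(spec.c):
        X = protos[j][None, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_per_class, spec.n)
        )
        np.clip(X, 1.0, float(spec.m), out=X)
        order = rng.permutation(spec.n_per_class)
        start = 0
        for name, size in zip(("train", "remembered", "test"), sizes):
            idx = order[start : start + size]
            parts[name][0].append(X[idx])
            parts[name][1].append(np.full(size, j, dtype=np.int64))
            start += size
    built = {
        name: Partition(np.concatenate(xs), np.concatenate(ys))
        for name, (xs, ys) in parts.items()
    }
    return Corpus(built["train"], built["remembered"], built["test"], spec)


# ----------------------------------------------------------------------
# toy glyphs

def _base_glyph(class_id: int) -> np.ndarray:
    """Deterministic 28×28 bar motif for a class.

    Classes place a 4-px horizontal and a 4-px vertical bar on a 6×6
    position grid; classes beyond 36 additionally draw the main
    diagonal, so base glyphs stay pairwise distinct.
    """
    if class_id < 0:
        raise ValueError("class_id must be non-negative")
    img = np.zeros((IMAGE_SIZE, IMAGE_SIZE))
    r = 1 + 4 * (class_id % 6)
    c = 1 + 4 * ((class_id // 6) % 6)
    img[r : r + 4, :] = 1.0
    img[:, c : c + 4] = 1.0
    if class_id >= 36:
        for d in range(IMAGE_SIZE):
            img[d, max(0, d - 1) : d + 2] = 1.0
    return img


def _shift(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def make_glyph_images(
    spec: FixtureSpec,
    class_id: int,
    count: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Jittered instances of one class's base glyph, shape (count, 28, 28)."""
    if not (0 <= class_id < spec.c):
        raise ValueError(f"class_id must lie in [0, {spec.c})")
    count = spec.n_per_class if count is None else count
    rng = np.random.default_rng(spec.seed + class_id) if rng is None else rng
    base = _base_glyph(class_id)
    if spec.jitter == 0:
        return np.repeat(base[None, :, :], count, axis=0)
    shifts = rng.integers(-spec.jitter, spec.jitter + 1, size=(count, 2))
    return np.stack([_shift(base, int(dy), int(dx)) for dy, dx in shifts])


def default_glyph_spec(seed: int = 0) -> FixtureSpec:
    """The default glyph corpus: 36 classes, 30 images each, ±2 px jitter."""
    return FixtureSpec(c=36, n_per_class=30, seed=seed)


def make_glyph_corpus(spec: FixtureSpec | None = None) -> Corpus:
    """Glyph image corpus split train/remembered/test like the feature corpus."""
    spec = spec or default_glyph_spec()
    rng = np.random.default_rng(spec.seed)
    sizes = _partition_sizes(spec.n_per_class, spec.fractions)
    parts = {name: ([], []) for name in ("train", "remembered", "test")}
    for j in range(spec.c):
        imgs = make_glyph_images(spec, j, rng=rng)
        order = rng.permutation(spec.n_per_class)
        start = 0
        for name, size in zip(("train", "remembered", "test"), sizes):
            idx = order[start : start + size]
            parts[name][0].append(imgs[idx])
            parts[name][1].append(np.full(size, j, dtype=np.int64))
            start += size
    built = {
        name: Partition(np.concatenate(xs), np.concatenate(ys))
        for name, (xs, ys) in parts.items()
    }
    return Corpus(built["train"], built["remembered"], built["test"], spec)


# ----------------------------------------------------------------------
# persistence: CSV per partition (label, f1..fn) + JSON sidecar

def save_corpus(corpus: Corpus, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    n = corpus.train.X.shape[1]
    header = "label," + ",".join(f"f{i+1}" for i in range(n))
    for name in ("train", "remembered", "test"):
        part: Partition = getattr(corpus, name)
        data = np.column_stack([part.y.astype(float), part.X])
        np.savetxt(
            os.path.join(directory, f"{name}.csv"),
            data,
            delimiter=",",
            header=header,
            comments="",
            fmt="%.8g",
        )
    with open(os.path.join(directory, "fixture.json"), "w") as fh:
        json.dump(asdict(corpus.spec), fh, indent=1)


def load_corpus(directory: str) -> Corpus:
    with open(os.path.join(directory, "fixture.json")) as fh:
        raw = json.load(fh)
    raw["fractions"] = tuple(raw["fractions"])
    spec = FixtureSpec(**raw)
    parts = {}
    for name in ("train", "remembered", "test"):
        data = np.loadtxt(
            os.path.join(directory, f"{name}.csv"), delimiter=",", skiprows=1
        )
        data = np.atleast_2d(data)
        parts[name] = Partition(data[:, 1:], data[:, 0].astype(np.int64))
    return Corpus(parts["train"], parts["remembered"], parts["test"], spec)
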