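"""Synthetic prototype datasets, IDX (MNIST-format) I/O, and the three
corrupted-test-set generators: pattern completion, perceptual rivalry, and
distortion resistance, each at difficulty levels {0.2, 0.4, 0.6, 0.8, 1.0}.

All generators are pure functions of (inputs, difficulty, seed).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskPattern",
    "SyntheticSpec",
    "generate_synthetic_dataset",
    "make_completion_set",
    "make_rivalry_set",
    "make_distortion_set",
    "rival_index",
    "bar_width",
    "load_idx",
    "write_idx",
    "task_manifest",
]

DIFFICULTIES = (0.2, 0.4, 0.6, 0.8, 1.0)
POSITIONS = ("up", "down", "left", "right")
DISTORTION_KINDS = ("noise", "grid", "clutter", "deletion", "occlusion")

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


@dataclass
class TaskPattern:
    """One (possibly corrupted) image with its provenance metadata."""

    image: np.ndarray  # (H, W), values in [0, 1]
    label: int
    task: str = "clean"  # clean | completion | rivalry | distortion
    difficulty: float = 0.0
    geometry: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticSpec:
    """Prototype-structured binary dataset: K prototypes plus independent
    pixel-flip noise.  ``block_shape`` > (1, 1) makes prototypes constant on
    pixel blocks, giving spatially correlated pixel groups."""

    n_prototypes: int = 8
    image_shape: tuple[int, int] = (28, 28)
    flip_noise: float = 0.1
    n_per_class: int = 100
    seed: int = 0
    min_separation: float = 0.25  # pairwise Hamming distance / n_pixels
    block_shape: tuple[int, int] = (1, 1)


def _draw_prototypes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_shape
    bh, bw = spec.block_shape
    if h % bh or w % bw:
        raise ValueError(f"block_shape {spec.block_shape} must divide "
                         f"image_shape {spec.image_shape}")
    n_pix = h * w
    for _attempt in range(200):
        blocks = rng.integers(0, 2, size=(spec.n_prototypes, h // bh, w // bw))
        protos = np.repeat(np.repeat(blocks, bh, axis=1), bw, axis=2)
        flat = protos.reshape(spec.n_prototypes, n_pix)
        ok = True
        for a in range(spec.n_prototypes):
            for b in range(a + 1, spec.n_prototypes):
                if (flat[a] != flat[b]).mean() < spec.min_separation:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return protos.astype(float)
    raise RuntimeError(
        f"could not draw {spec.n_prototypes} prototypes with pairwise "
        f"separation >= {spec.min_separation} after 200 attempts"
    )


def generate_synthetic_dataset(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (images, labels, prototypes).

    Samples are ``prototype XOR Bernoulli(flip_noise)`` pixel flips; images
    have shape (n, H, W) with values in {0, 1}; labels are prototype indices.
    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    protos = _draw_prototypes(spec, rng)
    n = spec.n_prototypes * spec.n_per_class
    labels = np.repeat(np.arange(spec.n_prototypes), spec.n_per_class)
    flips = rng.random((n, *spec.image_shape)) < spec.flip_noise
    images = np.abs(protos[labels] - flips.astype(float))
    # interleave classes so contiguous subsets stay balanced
    order = np.argsort(np.tile(np.arange(spec.n_per_class), spec.n_prototypes),
                       kind="stable")
    return images[order], labels[order].copy(), protos


def bar_width(difficulty: float, image_height: int = 28) -> int:
    """Bar width in pixels: ``round(D * H/2)`` with round-half-up (14 px at
    D = 1.0 on a 28-pixel image)."""
    return int(np.floor(difficulty * (image_height / 2) + 0.5))


def _bar_slices(position: str, width: int, h: int, w: int):
    if position == "up":
        return slice(0, width), slice(None)
    if position == "down":
        return slice(h - width, h), slice(None)
    if position == "left":
        return slice(None), slice(0, width)
    if position == "right":
        return slice(None), slice(w - width, w)
    raise ValueError(f"unknown bar position {position!r}")


def _check_difficulty(d: float) -> None:
    if not any(np.isclose(d, lv) for lv in DIFFICULTIES):
        raise ValueError(f"difficulty {d} not in {DIFFICULTIES}")


def _position_blocks(n: int, positions, block_size: int) -> np.ndarray:
    if n % block_size:
        raise ValueError(f"set size {n} must be a multiple of block_size "
                         f"{block_size}")
    blocks = n // block_size
    return np.array([positions[b % len(positions)] for b in range(blocks)])


def make_completion_set(
    images: np.ndarray,
    labels: np.ndarray,
    difficulty: float,
    positions=POSITIONS,
    block_size: int = 250,
) -> list[TaskPattern]:
    """Occlude each image with a flush gray bar (intensity exactly 0.5).

    The bar width is ``round(D * H/2)`` pixels; its position cycles through
    ``positions`` per contiguous block of ``block_size`` images, so each
    position covers an equal share of the set.
    """
    _check_difficulty(difficulty)
    images = np.asarray(images, dtype=float)
    n, h, w = images.shape
    width = bar_width(difficulty, h)
    if width > min(h, w):
        raise ValueError(f"bar width {width} exceeds image size {h}x{w}")
    pos_of_block = _position_blocks(n, positions, block_size)
    out = []
    for i in range(n):
        pos = pos_of_block[i // block_size]
        img = images[i].copy()
        img[_bar_slices(pos, width, h, w)] = 0.5
        out.append(TaskPattern(
            image=img, label=int(labels[i]), task="completion",
            difficulty=difficulty,
            geometry={"position": pos, "width": width},
        ))
    return out


def rival_index(i: int, block_size: int = 250) -> int:
    """Rival of the ``i``-th image (1-based within its block): the
    ``(block_size - i)``-th image of the same block, progressing through the
    block in the reverse direction (8 -> 242 for blocks of 250).  The
    midpoint and the last image pair with themselves; a warning is issued."""
    if block_size < 2:
        raise ValueError("rivalry requires blocks of at least 2 images")
    if not 1 <= i <= block_size:
        raise ValueError(f"index {i} outside block of size {block_size}")
    j = (block_size - i) % block_size
    if j == 0:
        j = block_size
    if j == i:
        warnings.warn(f"image {i} is its own rival in a block of "
                      f"{block_size}", stacklevel=2)
    return j


def make_rivalry_set(
    images: np.ndarray,
    labels: np.ndarray,
    difficulty: float,
    positions=POSITIONS,
    block_size: int = 250,
) -> list[TaskPattern]:
    """Replace a flush bar of each image with the same pixels of its rival.

    The rival of the i-th image (1-based within its contiguous block) is the
    (block_size - i)-th image of that block.
    """
    _check_difficulty(difficulty)
    images = np.asarray(images, dtype=float)
    n, h, w = images.shape
    width = bar_width(difficulty, h)
    if width > min(h, w):
        raise ValueError(f"bar width {width} exceeds image size {h}x{w}")
    pos_of_block = _position_blocks(n, positions, block_size)
    out = []
    for i in range(n):
        block, offset = divmod(i, block_size)
        rival_1based = rival_index(offset + 1, block_size)
        rival = block * block_size + rival_1based - 1
        pos = pos_of_block[block]
        img = images[i].copy()
        sl = _bar_slices(pos, width, h, w)
        img[sl] = images[rival][sl]
        out.append(TaskPattern(
            image=img, label=int(labels[i]), task="rivalry",
            difficulty=difficulty,
            geometry={"position": pos, "width": width,
                      "rival": rival_1based,
                      "rival_label": int(labels[rival])},
        ))
    return out


def _distort(img: np.ndarray, kind: str, d: float,
             rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    h, w = img.shape
    out = img.copy()
    geom: dict = {"kind": kind}
    if kind == "noise":
        p = 0.1 * d
        mask = rng.random(img.shape) < p
        out[mask] = 1.0 - out[mask]
        geom["flip_prob"] = p
    elif kind == "grid":
        spacing = int(np.ceil(7 / d))
        out[::spacing, :] = 0.5
        out[:, ::spacing] = 0.5
        geom["spacing"] = spacing
    elif kind in ("clutter", "deletion"):
        value = 1.0 if kind == "clutter" else 0.0
        n_lines = int(np.ceil(10 * d))
        lines = []
        for _ in range(n_lines):
            if rng.random() < 0.5:
                r = int(rng.integers(h))
                out[r, :] = value
                lines.append(("h", r))
            else:
                c = int(rng.integers(w))
                out[:, c] = value
                lines.append(("v", c))
        geom["lines"] = lines
    elif kind == "occlusion":
        side = bar_width(d, h)
        r = int(rng.integers(h - side + 1))
        c = int(rng.integers(w - side + 1))
        out[r:r + side, c:c + side] = 0.5
        geom.update(side=side, row=r, col=c)
    else:
        raise ValueError(f"unknown distortion kind {kind!r}")
    return out, geom


def make_distortion_set(
    images: np.ndarray,
    labels: np.ndarray,
    difficulty: float,
    seed: int = 0,
    kinds=DISTORTION_KINDS,
) -> list[TaskPattern]:
    """Split the set into five equal contiguous parts and apply one
    distortion kind to each: pixel flips (noise), regular gray lines (grid),
    random black lines (clutter), random white lines (deletion), or a gray
    square occluder.  Deterministic per seed."""
    _check_difficulty(difficulty)
    images = np.asarray(images, dtype=float)
    n = images.shape[0]
    if n % len(kinds):
        raise ValueError(f"set size {n} must be a multiple of {len(kinds)}")
    part = n // len(kinds)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        kind = kinds[i // part]
        img, geom = _distort(images[i], kind, difficulty, rng)
        out.append(TaskPattern(image=img, label=int(labels[i]),
                               task="distortion", difficulty=difficulty,
                               geometry=geom))
    return out


# ---------------------------------------------------------------------------
# IDX (MNIST) format
# ---------------------------------------------------------------------------

def load_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label file pair.

    Returns (images, labels) with intensities scaled to [0, 1].  Headers are
    big-endian; magic numbers and payload sizes are validated and errors name
    the expected vs actual byte counts.
    """
    with open(images_path, "rb") as f:
        head = f.read(16)
        if len(head) < 16:
            raise ValueError(f"{images_path}: truncated header "
                             f"({len(head)} of 16 bytes)")
        magic, n, rows, cols = struct.unpack(">IIII", head)
        if magic != _IDX_IMAGES_MAGIC:
            raise ValueError(f"{images_path}: bad magic 0x{magic:08x}, "
                             f"expected 0x{_IDX_IMAGES_MAGIC:08x}")
        payload = f.read()
        expected = n * rows * cols
        if len(payload) != expected:
            raise ValueError(f"{images_path}: expected {expected} payload "
                             f"bytes at offset 16, got {len(payload)}")
        images = np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)
    with open(labels_path, "rb") as f:
        head = f.read(8)
        if len(head) < 8:
            raise ValueError(f"{labels_path}: truncated header "
                             f"({len(head)} of 8 bytes)")
        magic, n_lab = struct.unpack(">II", head)
        if magic != _IDX_LABELS_MAGIC:
            raise ValueError(f"{labels_path}: bad magic 0x{magic:08x}, "
                             f"expected 0x{_IDX_LABELS_MAGIC:08x}")
        payload = f.read()
        if len(payload) != n_lab:
            raise ValueError(f"{labels_path}: expected {n_lab} payload bytes "
                             f"at offset 8, got {len(payload)}")
        labels = np.frombuffer(payload, dtype=np.uint8)
    if n != n_lab:
        raise ValueError(f"image count {n} != label count {n_lab}")
    return images.astype(float) / 255.0, labels.astype(int)


def write_idx(images: np.ndarray, labels: np.ndarray,
              images_path, labels_path) -> None:
    """Write (images in [0, 1], labels) as an IDX file pair."""
    images = np.asarray(images)
    n, rows, cols = images.shape
    raw = np.clip(np.round(images * 255.0), 0, 255).astype(np.uint8)
    with open(images_path, "wb") as f:
        f.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        f.write(raw.tobytes())
    with open(labels_path, "wb") as f:
        f.write(struct.pack(">II", _IDX_LABELS_MAGIC, n))
        f.write(np.asarray(labels, dtype=np.uint8).tobytes())


def task_manifest(patterns: list[TaskPattern]) -> pd.DataFrame:
    """Tabular manifest: pattern id, task, difficulty, geometry, label."""
    return pd.DataFrame([
        {"id": i, "task": p.task, "difficulty": p.difficulty,
         "label": p.label, "geometry": repr(p.geometry)}
        for i, p in enumerate(patterns)
    ])


def patterns_to_array(patterns: list[TaskPattern]) -> tuple[np.ndarray, np.ndarray]:
    """Stack TaskPatterns into (images (n, H*W), labels)."""
    imgs = np.stack([p.image.reshape(-1) for p in patterns])
    labs = np.array([p.label for p in patterns])
    return imgs, labs
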