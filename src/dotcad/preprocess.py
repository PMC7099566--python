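"""From 3D absorption volumes to the normalized 2D slice dataset.

Each volume contributes the axial slices in a configured window (default
6-25, 1-based inclusive, 20 slices). Every slice is resized to 32 x 32
with corner-aligned bilinear interpolation and min-max normalized to
[0, 1] per image, which removes the arbitrary per-patient absorption
scale. The dataset is then split into stratified train/test partitions at
the image level, and the minority training class can be doubled by
left-right flip augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from dotcad.phantom import LABELS, Volume3D


@dataclass
class SliceImage:
    """One preprocessed 2D slice: 32x32 pixels in [0,1] plus provenance."""

    pixels: np.ndarray
    label: str
    patient_id: str
    z_index: int  # 1-based index in the source volume


@dataclass
class DatasetSplit:
    train: list[SliceImage]
    test: list[SliceImage]
    seed: int
    fraction_train: float


def slice_volume(volume: Volume3D, z_lo: int, z_hi: int) -> list[SliceImage]:
    """Extract raw axial planes z_lo..z_hi (1-based, inclusive).

    Returns un-resized, un-normalized planes in ascending z order, each
    carrying the volume's label and patient id.
    """
    depth = volume.voxels.shape[2]
    if not (1 <= z_lo <= z_hi <= depth):
        raise ValueError(f"z range {z_lo}..{z_hi} outside volume depth 1..{depth}")
    return [
        SliceImage(
            pixels=np.asarray(volume.voxels[:, :, z - 1], dtype=float),
            label=volume.label,
            patient_id=volume.patient_id,
            z_index=z,
        )
        for z in range(z_lo, z_hi + 1)
    ]


def resize_bilinear(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Corner-aligned bilinear resize of a 2D grid.

    Output pixel (i, j) samples source coordinates
    ``i * (H-1)/(out_h-1), j * (W-1)/(out_w-1)`` (0 when the target axis
    has a single pixel), interpolating the four nearest neighbours. Every
    output value is a convex combination of input values, so the output
    range is bounded by the input range; resizing to the same shape is the
    identity.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2D grid, got shape {image.shape}")
    if out_h < 1 or out_w < 1:
        raise ValueError(f"target dimensions must be positive, got {out_h}x{out_w}")
    in_h, in_w = image.shape

    def _coords(n_out: int, n_in: int) -> np.ndarray:
        if n_out == 1 or n_in == 1:
            return np.zeros(n_out)
        return np.arange(n_out) * (n_in - 1) / (n_out - 1)

    r = _coords(out_h, in_h)
    c = _coords(out_w, in_w)
    r0 = np.minimum(np.floor(r).astype(int), in_h - 1)
    c0 = np.minimum(np.floor(c).astype(int), in_w - 1)
    r1 = np.minimum(r0 + 1, in_h - 1)
    c1 = np.minimum(c0 + 1, in_w - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    top = image[np.ix_(r0, c0)] * (1 - fc) + image[np.ix_(r0, c1)] * fc
    bot = image[np.ix_(r1, c0)] * (1 - fc) + image[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Min-max scale a 2D grid to [0, 1]; a constant grid maps to zeros."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("normalize_minmax requires finite input")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def build_dataset(
    volumes: Sequence[Volume3D],
    z_lo: int = 6,
    z_hi: int = 25,
    out_size: int = 32,
) -> list[SliceImage]:
    """Slice, resize and normalize a cohort into network-ready images.

    ``len(volumes) * (z_hi - z_lo + 1)`` images result; 63 volumes with
    the default 6..25 window yield 1260.
    """
    if len(volumes) == 0:
        raise ValueError("build_dataset requires at least one volume")
    dataset: list[SliceImage] = []
    for vol in volumes:
        for sl in slice_volume(vol, z_lo, z_hi):
            pixels = normalize_minmax(resize_bilinear(sl.pixels, out_size, out_size))
            dataset.append(
                SliceImage(pixels=pixels, label=sl.label, patient_id=sl.patient_id, z_index=sl.z_index)
            )
    return dataset


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratified_split(
    dataset: Sequence[SliceImage],
    fraction_train: float = 0.75,
    seed: int = 0,
    by_patient: bool = False,
) -> DatasetSplit:
    """Class-stratified random split.

    Within each class the images (default) or patients (``by_patient``)
    are shuffled with the given seed and the first
    round(fraction_train x n) go to training, so per-class counts are
    deterministic regardless of seed. Image-level splitting reproduces
    the canonical 645/300 train, 215/100 test partition of a 1260-image
    cohort at fraction 0.75, at the cost of mixing one patient's slices
    across partitions; patient-level splitting avoids that leakage but
    only approximates the per-image counts.
    """
    if not (0 < fraction_train < 1):
        raise ValueError(f"fraction_train must be in (0, 1), got {fraction_train}")
    rng = np.random.default_rng(seed)
    train: list[SliceImage] = []
    test: list[SliceImage] = []
    for label in LABELS:
        members = [img for img in dataset if img.label == label]
        if not members:
            continue
        if by_patient:
            patients = sorted({img.patient_id for img in members})
            order = rng.permutation(len(patients))
            n_train = _round_half_away(fraction_train * len(patients))
            train_patients = {patients[i] for i in order[:n_train]}
            train.extend(img for img in members if img.patient_id in train_patients)
            test.extend(img for img in members if img.patient_id not in train_patients)
        else:
            order = rng.permutation(len(members))
            n_train = _round_half_away(fraction_train * len(members))
            train.extend(members[i] for i in order[:n_train])
            test.extend(members[i] for i in order[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed, fraction_train=fraction_train)


def augment_flip_minority(split: DatasetSplit, target_class: str = "malignant") -> DatasetSplit:
    """Double the target class in the training set by left-right mirroring.

    Every training image of ``target_class`` gains one horizontally
    flipped duplicate; the test set is untouched. Flipping is an
    involution, so augmenting an already-symmetric image simply duplicates
    it.
    """
    targets = [img for img in split.train if img.label == target_class]
    if not targets:
        warnings.warn(
            f"augment_flip_minority: no {target_class!r} images in training set; no-op",
            stacklevel=2,
        )
        return DatasetSplit(
            train=list(split.train), test=list(split.test), seed=split.seed,
            fraction_train=split.fraction_train,
        )
    flipped = [
        SliceImage(
            pixels=np.fliplr(img.pixels).copy(),
            label=img.label,
            patient_id=img.patient_id,
            z_index=img.z_index,
        )
        for img in targets
    ]
    return DatasetSplit(
        train=list(split.train) + flipped,
        test=list(split.test),
        seed=split.seed,
        fraction_train=split.fraction_train,
    )


def class_counts(images: Sequence[SliceImage]) -> dict[str, int]:
    """Number of images per class label."""
    counts = {label: 0 for label in LABELS}
    for img in images:
        counts[img.label] = counts.get(img.label, 0) + 1
    return counts


def as_arrays(images: Sequence[SliceImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into (N, 1, H, W) pixels and an (N,) label array."""
    x = np.stack([img.pixels for img in images])[:, None, :, :]
    y = np.array([img.label for img in images])
    return x, y
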