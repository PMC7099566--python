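"""Synthetic diffuse-optical-tomography (DOT) breast phantoms.

Real DOT absorption volumes of tumor-bearing dense breasts are diffuse,
low-contrast 91 x 91 x 31 voxel grids in which the lesion appears as a
smooth blob of elevated absorption somewhere in axial slices 6-25. No such
cohort is publicly deposited, so this module generates statistically
similar volumes: a z-tapered elliptical breast support filled with a
spatially correlated background field, one absorbing inclusion per breast
(a single smooth ellipsoid for benign masses, a union of overlapping
lobulated ellipsoids for malignant ones), and a global Gaussian blur that
emulates the millimetre-scale diffuse resolution of reconstructed DOT.

Absorption is kept in arbitrary units with background 1.0: downstream
preprocessing min-max normalizes every slice, so only relative contrast
matters. Malignant inclusions draw their multiplicative contrast from a
higher range than benign ones; with the default (disjoint) ranges the two
classes are learnable but not trivially separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

#: Fraction of the transverse half-width occupied by the breast support.
_SUPPORT_FRACTION = 0.92
#: Taper strength of the support toward deep z (chest-wall side).
_SUPPORT_TAPER = 0.6
#: Lesion centers stay within this fraction of the local support radius.
_CENTER_MARGIN = 0.4


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters of the synthetic cohort.

    Lengths are physical: semi-axes in cm, blur in mm, pitch in mm per
    voxel. With the default 2.0 mm pitch the 91-voxel transverse extent is
    about 18 cm, a plausible compressed-breast scale, and a 1.5 cm tumor
    semi-axis spans 7.5 voxels.

    ``tumor_z_range`` is a 1-based inclusive axial index pair: the lesion
    center is drawn uniformly from it.
    """

    grid_shape: tuple[int, int, int] = (91, 91, 31)
    voxel_pitch_mm: float = 2.0
    background_mu: float = 1.0
    background_noise_sigma: float = 4.0  # voxels, correlation length
    background_noise_amp: float = 0.05  # fractional amplitude
    tumor_z_range: tuple[int, int] = (6, 25)
    contrast_benign: tuple[float, float] = (1.3, 1.8)
    contrast_malignant: tuple[float, float] = (2.0, 3.0)
    lobulation_count: int = 4
    psf_sigma_mm: float = 4.0
    # Fixed (axial, transverse, transverse) semi-axes in cm; None -> drawn
    # per volume from the ranges below.
    tumor_semiaxes_cm: Optional[tuple[float, float, float]] = None
    tumor_semiaxis_long_cm: tuple[float, float] = (1.0, 1.6)
    tumor_semiaxis_short_cm: tuple[float, float] = (0.5, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        z_lo, z_hi = self.tumor_z_range
        depth = self.grid_shape[2]
        if not (1 <= z_lo <= z_hi <= depth):
            raise ValueError(
                f"tumor_z_range {self.tumor_z_range} outside grid depth 1..{depth}"
            )
        for name in ("contrast_benign", "contrast_malignant"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.voxel_pitch_mm <= 0:
            raise ValueError("voxel_pitch_mm must be positive")
        if self.psf_sigma_mm < 0 or self.background_noise_sigma < 0:
            raise ValueError("blur widths must be non-negative")
        if self.lobulation_count < 1:
            raise ValueError("lobulation_count must be >= 1")


@dataclass
class Volume3D:
    """One absorption volume with its class label and cohort bookkeeping.

    ``voxels`` is indexed ``[x, y, z]``; the axial (z) axis is the slicing
    axis downstream. ``tumor_extent_cm`` records the full axis lengths
    (2 x semi-axes) of the main inclusion, ordered (axial, transverse,
    transverse) — metadata only, not used by the classifier.
    """

    voxels: np.ndarray
    label: str
    patient_id: str
    tumor_extent_cm: tuple[float, float, float]
    seed: Optional[int] = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


def breast_support_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean z-tapered elliptical support: True inside the breast."""
    nx, ny, nz = config.grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None, None] - cx
    y = np.arange(ny)[None, :, None] - cy
    zi = np.arange(nz)[None, None, :] / max(nz - 1, 1)
    taper = np.sqrt(1.0 - _SUPPORT_TAPER * zi**2)
    ax = _SUPPORT_FRACTION * (nx - 1) / 2.0 * taper
    ay = _SUPPORT_FRACTION * (ny - 1) / 2.0 * taper
    return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0


def _support_semiaxes_at(config: PhantomConfig, z_index: int) -> tuple[float, float]:
    nx, ny, nz = config.grid_shape
    taper = np.sqrt(1.0 - _SUPPORT_TAPER * (z_index / max(nz - 1, 1)) ** 2)
    return (
        _SUPPORT_FRACTION * (nx - 1) / 2.0 * taper,
        _SUPPORT_FRACTION * (ny - 1) / 2.0 * taper,
    )


def _ellipsoid_profile(
    shape: tuple[int, int, int],
    center: Sequence[float],
    semiaxes_vox: Sequence[float],
) -> np.ndarray:
    """Smooth unit-peak profile max(0, 1 - d^2) of a normalized ellipsoid."""
    nx, ny, nz = shape
    x = (np.arange(nx)[:, None, None] - center[0]) / semiaxes_vox[0]
    y = (np.arange(ny)[None, :, None] - center[1]) / semiaxes_vox[1]
    z = (np.arange(nz)[None, None, :] - center[2]) / semiaxes_vox[2]
    return np.clip(1.0 - (x**2 + y**2 + z**2), 0.0, None)


def generate_phantom(
    label: str,
    config: Optional[PhantomConfig] = None,
    seed: Optional[int] = None,
    patient_id: str = "P000",
) -> Volume3D:
    """Generate one synthetic absorption volume.

    Deterministic given ``(label, config, seed)``; ``seed`` defaults to
    ``config.seed``. Voxels outside the breast support are exactly zero.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    config = config if config is not None else PhantomConfig()
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    nx, ny, nz = config.grid_shape
    pitch = config.voxel_pitch_mm

    # Correlated background: smoothed white noise, unit-variance, scaled.
    noise = gaussian_filter(rng.standard_normal((nx, ny, nz)), config.background_noise_sigma)
    std = noise.std()
    if std > 0:
        noise /= std
    field = config.background_mu * (1.0 + config.background_noise_amp * noise)
    field = np.clip(field, 0.05 * config.background_mu, None)

    # Main inclusion geometry. Long semi-axis along the axial (z) axis so
    # the lesion intersects most of the slicing window.
    if config.tumor_semiaxes_cm is not None:
        semiaxes_cm = tuple(float(v) for v in config.tumor_semiaxes_cm)
    else:
        lo, hi = config.tumor_semiaxis_long_cm
        s_lo, s_hi = config.tumor_semiaxis_short_cm
        semiaxes_cm = (
            float(rng.uniform(lo, hi)),
            float(rng.uniform(s_lo, s_hi)),
            float(rng.uniform(s_lo, s_hi)),
        )
    # cm -> voxels; ordering (axial, transverse, transverse) -> (z, x, y)
    az, ax_t, ay_t = (10.0 * s / pitch for s in semiaxes_cm)
    z_lo, z_hi = config.tumor_z_range
    cz = int(rng.integers(z_lo - 1, z_hi))  # 0-based center index
    sup_ax, sup_ay = _support_semiaxes_at(config, cz)
    cx = (nx - 1) / 2.0 + rng.uniform(-_CENTER_MARGIN, _CENTER_MARGIN) * sup_ax
    cy = (ny - 1) / 2.0 + rng.uniform(-_CENTER_MARGIN, _CENTER_MARGIN) * sup_ay

    main_axes_vox = (ax_t, ay_t, az)  # (x, y, z) order for the grid
    profile = _ellipsoid_profile((nx, ny, nz), (cx, cy, cz), main_axes_vox)
    if label == MALIGNANT:
        # Lobulated mass: main ellipsoid plus smaller overlapping lobes.
        for _ in range(config.lobulation_count - 1):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            offset = 0.6 * direction * np.asarray(main_axes_vox)
            lobe_axes = tuple(0.5 * a for a in main_axes_vox)
            lobe = _ellipsoid_profile(
                (nx, ny, nz),
                (cx + offset[0], cy + offset[1], cz + offset[2]),
                lobe_axes,
            )
            profile = np.maximum(profile, lobe)
        contrast = float(rng.uniform(*config.contrast_malignant))
    else:
        contrast = float(rng.uniform(*config.contrast_benign))

    field *= 1.0 + (contrast - 1.0) * profile

    if config.psf_sigma_mm > 0:
        field = gaussian_filter(field, config.psf_sigma_mm / pitch)

    field *= breast_support_mask(config)

    extent_cm = tuple(round(2.0 * s, 6) for s in semiaxes_cm)
    return Volume3D(
        voxels=field,
        label=label,
        patient_id=patient_id,
        tumor_extent_cm=extent_cm,  # type: ignore[arg-type]
        seed=seed,
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    config: Optional[PhantomConfig] = None,
    seed: int = 0,
) -> list[Volume3D]:
    """Generate a labelled cohort: benign volumes first, then malignant.

    Per-volume seeds are derived deterministically from the cohort seed so
    the whole cohort is reproducible and individual volumes can be
    regenerated in isolation from the manifest.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("cohort counts must be non-negative")
    config = config if config is not None else PhantomConfig()
    n_total = n_benign + n_malignant
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(max(n_total, 1))
    ]
    volumes: list[Volume3D] = []
    for i in range(n_total):
        label = BENIGN if i < n_benign else MALIGNANT
        idx = i if i < n_benign else i - n_benign
        patient_id = f"{'B' if label == BENIGN else 'M'}{idx + 1:03d}"
        volumes.append(
            generate_phantom(label, config, seed=child_seeds[i], patient_id=patient_id)
        )
    return volumes


def with_overrides(config: PhantomConfig, **kwargs) -> PhantomConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
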