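"""Volumetric containers, NIfTI I/O and CT preprocessing.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(x, y, z)``; axis 2 is the craniocaudal axis with
  *increasing* index pointing superior (toward the head).  Readers must
  bring data into this orientation on load; only axis-aligned data are
  supported.
* Voxel indexing is 0-based.  All physical quantities (spacing, origin,
  distances) are in millimetres; voxel centres sit at ``index * spacing``
  relative to ``origin``.
* Level-coded labelmaps use the fixed code table ``0`` = background,
  ``1..12`` = T1..T12, ``13..17`` = L1..L5 (:data:`LEVEL_NAMES`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LEVEL_NAMES",
    "N_LEVELS",
    "VertebraLevel",
    "Volume",
    "LabelMap",
    "read_volume",
    "read_labelmap",
    "write_volume",
    "write_labelmap",
    "resample_isotropic",
    "normalize_intensity",
]

#: Anatomical level names in craniocaudal order; code i+1 names LEVEL_NAMES[i].
LEVEL_NAMES: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)
N_LEVELS = len(LEVEL_NAMES)  # 17

_NAME_TO_CODE = {name: i + 1 for i, name in enumerate(LEVEL_NAMES)}


@dataclass(frozen=True, order=True)
class VertebraLevel:
    """An anatomical vertebral level in the fixed order T1 < ... < T12 < L1 < ... < L5.

    ``code`` is the integer label used in level-coded labelmaps (1..17).
    """

    code: int

    def __post_init__(self) -> None:
        if not 1 <= self.code <= N_LEVELS:
            raise ValueError(f"level code must be in 1..{N_LEVELS}, got {self.code}")

    @property
    def name(self) -> str:
        return LEVEL_NAMES[self.code - 1]

    @classmethod
    def from_name(cls, name: str) -> "VertebraLevel":
        try:
            return cls(_NAME_TO_CODE[name.upper()])
        except KeyError:
            raise ValueError(f"unknown vertebral level {name!r}") from None

    def successor(self) -> "VertebraLevel":
        """The next level toward L5 (one vertebra inferior)."""
        if self.code == N_LEVELS:
            raise ValueError("L5 has no successor within the thoracolumbar spine")
        return VertebraLevel(self.code + 1)

    def predecessor(self) -> "VertebraLevel":
        """The previous level toward T1 (one vertebra superior)."""
        if self.code == 1:
            raise ValueError("T1 has no predecessor within the thoracolumbar spine")
        return VertebraLevel(self.code - 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _check_geometry(values: np.ndarray, spacing) -> tuple[float, float, float]:
    if values.ndim != 3 or min(values.shape) < 1:
        raise ValueError(f"expected a 3-D grid, got shape {values.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3-D scalar intensity grid (CT, Hounsfield-unit-like) with geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = _check_geometry(self.values, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


#: Allowed labelmap semantics.
_SEMANTICS = ("binary", "level", "instance")


@dataclass
class LabelMap:
    """A 3-D integer grid aligned to a :class:`Volume`.

    ``semantics`` distinguishes binary foreground maps (values in {0,1}),
    level-coded maps (values in 0..17 using the fixed code table) and
    instance-coded maps (0 = background, positive ids otherwise).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantics: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError(f"labelmap values must be integers, got {self.values.dtype}")
        self.spacing = _check_geometry(self.values, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.semantics not in _SEMANTICS:
            raise ValueError(f"semantics must be one of {_SEMANTICS}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("labelmap values must be non-negative")
        if self.semantics == "binary" and self.values.size and self.values.max() > 1:
            raise ValueError("binary labelmap contains values outside {0, 1}")
        if self.semantics == "level" and self.values.size and self.values.max() > N_LEVELS:
            raise ValueError(f"level-coded labelmap contains codes > {N_LEVELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def binarized(self) -> "LabelMap":
        """Foreground mask: any nonzero label becomes 1."""
        return LabelMap(
            (self.values > 0).astype(np.int16),
            spacing=self.spacing,
            origin=self.origin,
            semantics="binary",
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


_LEVEL_TABLE_DESC = "levels:0=bg,1-12=T1-T12,13-17=L1-L5"


def read_volume(path) -> Volume:
    """Read an intensity volume from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data, spacing=zooms, origin=origin)


def read_labelmap(path, semantics: str = "binary") -> LabelMap:
    """Read a labelmap from a NIfTI file.

    Float-typed data are accepted only when every value is integral (some
    writers store labels as floats); anything else raises ``ValueError``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(data, rounded):
            raise ValueError(f"{path}: labelmap contains non-integer values")
        data = rounded
    data = data.astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LabelMap(data, spacing=zooms, origin=origin, semantics=semantics)


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.values, dtype=np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_labelmap(m: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(m.values, dtype=np.int16), _affine(m.spacing, m.origin))
    img.header.set_zooms(m.spacing)
    if m.semantics == "level":
        img.header["descrip"] = _LEVEL_TABLE_DESC.encode()
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing


def resample_isotropic(obj, target_spacing_mm: float):
    """Resample a :class:`Volume` or :class:`LabelMap` to isotropic spacing.

    The output grid has shape ``ceil(shape * spacing / t)`` per axis and
    spacing ``(t, t, t)``.  Intensity volumes are linearly interpolated;
    labelmaps use nearest-neighbour sampling so label values are never
    blended.  An input already at the target spacing is returned as a copy
    with identical values.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    is_label = isinstance(obj, LabelMap)
    spacing = obj.spacing
    shape = obj.values.shape
    out_shape = tuple(int(math.ceil(n * s / t)) for n, s in zip(shape, spacing))

    if all(abs(s - t) < 1e-12 for s in spacing):
        out = obj.values.copy()
    else:
        # voxel-centre mapping: output index i lies at physical i*t, i.e. at
        # input index i*t/spacing along each axis
        grids = np.meshgrid(
            *[np.arange(n, dtype=np.float64) * t / s for n, s in zip(out_shape, spacing)],
            indexing="ij",
        )
        coords = np.stack(grids)
        order = 0 if is_label else 1
        out = ndimage.map_coordinates(
            obj.values.astype(np.float32 if not is_label else obj.values.dtype),
            coords,
            order=order,
            mode="nearest",
        )
    if is_label:
        return LabelMap(out.astype(obj.values.dtype), spacing=(t, t, t), origin=obj.origin,
                        semantics=obj.semantics)
    return Volume(out, spacing=(t, t, t), origin=obj.origin)


def normalize_intensity(v: Volume, window_low: float = -1000.0,
                        window_high: float = 1000.0) -> Volume:
    """Affinely map a CT window onto the range [-0.5, 1.5], clipping outside it.

    ``window_low`` maps to -0.5 and ``window_high`` to 1.5; values outside
    the window saturate at those bounds.  The default window (-1000, 1000) HU
    spans air to dense bone.
    """
    if not window_low < window_high:
        raise ValueError("window_low must be strictly below window_high")
    scaled = -0.5 + 2.0 * (v.values.astype(np.float64) - window_low) / (window_high - window_low)
    return Volume(np.clip(scaled, -0.5, 1.5).astype(np.float32),
                  spacing=v.spacing, origin=v.origin)
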