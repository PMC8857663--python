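"""Synthetic thoracolumbar spine phantoms and simulated network predictions.

The generator stands in for clinical CT plus a trained segmentation CNN: it
builds a craniocaudal stack of vertebral-body-like blobs (superellipsoids,
i.e. rounded boxes — vertebral bodies are squat cylinders, and watershed
behaviour depends on shape realism) separated by disc gaps, renders a
CT-like intensity volume (trabecular interior, brighter cortical shell,
Gaussian noise), and can corrupt the ground truth into the failure modes a
network exhibits: fusion of adjacent vertebrae, boundary erosion/dilation,
voxel dropout, spurious islands and per-vertebra level mislabeling.

All randomness flows from the single integer ``seed`` in each spec through
a named ``numpy.random.Generator``; identical spec + seed gives bit-identical
outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelMap, N_LEVELS, VertebraLevel, Volume

__all__ = ["PhantomSpec", "CorruptionSpec", "generate_phantom", "corrupt_prediction"]

log = logging.getLogger("spinepost.phantom")

# intensity model (Hounsfield-unit-like)
_HU_SOFT_TISSUE = 40.0
_HU_TRABECULAR = 250.0
_HU_CORTICAL = 700.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters for one spine phantom.

    Defaults emulate the imaging regime the pipeline targets: 1 mm isotropic
    voxels and at least five thoracolumbar vertebrae in view.  ``volume_shape``
    may be left ``None`` to size the grid to the stack plus margins.
    """

    n_vertebrae: int = 5
    first_level: str = "T10"
    body_radius_mm: tuple[float, float, float] = (16.0, 14.0, 11.0)
    disc_gap_mm: float = 4.0
    volume_shape: tuple[int, int, int] | None = None
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    partial_at_edges: bool = False
    noise_sigma_hu: float = 20.0
    cortical_thickness_mm: float = 2.0
    lateral_margin_mm: float = 12.0
    axial_margin_mm: float = 8.0
    seed: int = 0

    @property
    def first_level_code(self) -> int:
        return VertebraLevel.from_name(self.first_level).code

    @property
    def pitch_mm(self) -> float:
        """Centre-to-centre craniocaudal distance between adjacent bodies."""
        return 2.0 * self.body_radius_mm[2] + self.disc_gap_mm

    def validate(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        if self.first_level_code + self.n_vertebrae - 1 > N_LEVELS:
            raise ValueError(
                f"{self.n_vertebrae} vertebrae starting at {self.first_level} "
                "run past L5"
            )
        if self.disc_gap_mm <= 0:
            raise ValueError("disc gap must be positive")
        if any(r <= 0 for r in self.body_radius_mm):
            raise ValueError("body radii must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class CorruptionSpec:
    """Failure modes applied to a ground-truth segmentation.

    ``fuse_pairs`` lists adjacent instance-id pairs to connect with a
    cylindrical bone bridge across the disc gap; ``mislabel_map`` maps an
    instance id to ``(substitute_level_code, mixing_fraction)``, flipping
    that fraction of the instance's voxels to the substitute level in the
    level-coded output only.
    """

    fuse_pairs: tuple[tuple[int, int], ...] = ()
    bridge_radius_mm: float = 3.0
    boundary_noise_mm: float = 0.0
    mislabel_map: dict[int, tuple[int, float]] = field(default_factory=dict)
    n_spurious_islands: int = 0
    island_radius_mm: tuple[float, float] = (3.0, 8.0)
    dropout_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for a, b in self.fuse_pairs:
            if abs(a - b) != 1:
                raise ValueError(f"can only fuse adjacent instances, got ({a}, {b})")
        for inst, (code, frac) in self.mislabel_map.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"mixing fraction for instance {inst} not in [0,1]")
            if not 1 <= code <= N_LEVELS:
                raise ValueError(f"substitute level code {code} out of range")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.boundary_noise_mm < 0:
            raise ValueError("boundary noise must be non-negative")


def _superellipsoid_field(shape, spacing, center_mm, radii_mm, power=4):
    """Evaluate s = sum(|x-c|/r)^p on the voxel grid inside a clipped bbox.

    Returns (slices, s) where s <= 1 is the interior.  Only the bounding box
    of the body (clipped to the volume) is evaluated.
    """
    slices = []
    axes = []
    for ax in range(3):
        lo = int(math.floor((center_mm[ax] - radii_mm[ax]) / spacing[ax]))
        hi = int(math.ceil((center_mm[ax] + radii_mm[ax]) / spacing[ax])) + 1
        lo = max(lo, 0)
        hi = min(hi, shape[ax])
        if hi <= lo:
            return None, None
        slices.append(slice(lo, hi))
        coords = (np.arange(lo, hi) * spacing[ax] - center_mm[ax]) / radii_mm[ax]
        axes.append(np.abs(coords) ** power)
    s = (
        axes[0][:, None, None]
        + axes[1][None, :, None]
        + axes[2][None, None, :]
    )
    return tuple(slices), s


def generate_phantom(spec: PhantomSpec):
    """Build a spine phantom.

    Returns ``(volume, gt_instances, table)`` where ``gt_instances`` is an
    instance-coded :class:`LabelMap` (ids 1..n in craniocaudal order, id 1
    most superior) and ``table`` a DataFrame with columns ``instance_id``,
    ``level_code``, ``level_name``, ``edge_contact``, ``n_voxels``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing_mm
    rx, ry, rz = spec.body_radius_mm
    pitch = spec.pitch_mm
    n = spec.n_vertebrae

    if spec.volume_shape is None:
        lat_x = 2 * (rx + spec.lateral_margin_mm)
        lat_y = 2 * (ry + spec.lateral_margin_mm)
        if spec.partial_at_edges:
            # cut roughly half of the topmost and bottommost bodies
            z_extent = (n - 1) * pitch + rz
        else:
            z_extent = (n - 1) * pitch + 2 * (rz + spec.axial_margin_mm)
        shape = tuple(
            int(math.ceil(e / s)) for e, s in zip((lat_x, lat_y, z_extent), sp)
        )
    else:
        shape = tuple(int(x) for x in spec.volume_shape)

    extent_mm = tuple(ns * s for ns, s in zip(shape, sp))
    cx, cy = extent_mm[0] / 2.0, extent_mm[1] / 2.0
    if spec.partial_at_edges:
        top_center = extent_mm[2] - rz * 0.5
    else:
        top_center = extent_mm[2] - spec.axial_margin_mm - rz
    if top_center - (n - 1) * pitch < -rz + sp[2]:
        raise ValueError("vertebral stack does not fit the requested volume")

    inst = np.zeros(shape, dtype=np.int32)
    shell_s = ((max(rx, ry, rz) - spec.cortical_thickness_mm) / max(rx, ry, rz)) ** 4
    intensity = np.full(shape, _HU_SOFT_TISSUE, dtype=np.float32)

    rows = []
    for i in range(n):
        cz = top_center - i * pitch
        slc, s = _superellipsoid_field(shape, sp, (cx, cy, cz), (rx, ry, rz))
        inside = None if s is None else s <= 1.0
        if inside is None or not inside.any():
            raise ValueError(f"vertebra {i + 1} falls entirely outside the volume")
        inst_id = i + 1
        region = inst[slc]
        region[inside] = inst_id
        vol_region = intensity[slc]
        vol_region[inside & (s > shell_s)] = _HU_CORTICAL
        vol_region[inside & (s <= shell_s)] = _HU_TRABECULAR
        rows.append(
            {
                "instance_id": inst_id,
                "level_code": spec.first_level_code + i,
                "level_name": VertebraLevel(spec.first_level_code + i).name,
            }
        )

    intensity += rng.normal(0.0, spec.noise_sigma_hu, size=shape).astype(np.float32)

    # edge contact from the realised masks
    objects = ndimage.find_objects(inst)
    for row in rows:
        bbox = objects[row["instance_id"] - 1]
        row["edge_contact"] = any(
            b.start == 0 or b.stop == shape[ax] for ax, b in enumerate(bbox)
        )
        row["n_voxels"] = int((inst == row["instance_id"]).sum())

    table = pd.DataFrame(rows)
    volume = Volume(intensity, spacing=sp)
    gt = LabelMap(inst, spacing=sp, semantics="instance")
    return volume, gt, table


# ---------------------------------------------------------------------------
# Corruption


def _ball(radius_vox: np.ndarray) -> np.ndarray:
    """Anisotropic ellipsoidal structuring element with per-axis voxel radii."""
    r = np.maximum(np.round(radius_vox).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-x, x + 1) for x in r], indexing="ij")
    s = sum((g / max(x, 1e-9)) ** 2 for g, x in zip(grids, r.astype(float)))
    return s <= 1.0


def corrupt_prediction(gt: LabelMap, levels: pd.DataFrame, c: CorruptionSpec):
    """Simulate network predictions from ground truth.

    Returns ``(binary_pred, level_pred)`` sharing one corrupted geometry:
    per-instance boundary noise (random erosion or dilation), voxel dropout,
    fusion bridges, spurious islands, and — in the level output only —
    mislabel mixing.
    """
    if gt.semantics != "instance":
        raise ValueError("ground truth must be an instance-coded labelmap")
    c.validate()
    rng = np.random.default_rng(c.seed)
    sp = np.asarray(gt.spacing)
    shape = gt.shape
    level_of = dict(zip(levels["instance_id"], levels["level_code"]))
    ids = sorted(level_of)
    for a, b in c.fuse_pairs:
        if a not in level_of or b not in level_of:
            raise ValueError(f"fuse pair ({a}, {b}) references a missing instance")

    # per-voxel level grid, geometry mutated in place
    lvl = np.zeros(shape, dtype=np.int16)
    for i in ids:
        lvl[gt.values == i] = level_of[i]

    if c.boundary_noise_mm > 0:
        pad = int(math.ceil(c.boundary_noise_mm / sp.min())) + 1
        for i in ids:
            mask = gt.values == i
            obj = ndimage.find_objects(mask.astype(np.int8))[0]
            slc = tuple(
                slice(max(s.start - pad, 0), min(s.stop + pad, shape[ax]))
                for ax, s in enumerate(obj)
            )
            sub = mask[slc]
            radius_mm = rng.uniform(0.0, c.boundary_noise_mm)
            radius_vox = radius_mm / sp
            if radius_vox.max() < 0.5:
                continue
            selem = _ball(radius_vox)
            if rng.random() < 0.5:
                new = ndimage.binary_erosion(sub, structure=selem)
                lvl[slc][sub & ~new] = 0
            else:
                new = ndimage.binary_dilation(sub, structure=selem)
                grown = new & (lvl[slc] == 0)
                lvl[slc][grown] = level_of[i]

    if c.dropout_fraction > 0:
        for i in ids:
            idx = np.flatnonzero((gt.values == i).ravel() & (lvl.ravel() > 0))
            k = int(round(c.dropout_fraction * idx.size))
            if k:
                drop = rng.choice(idx, size=k, replace=False)
                lvl.ravel()[drop] = 0

    # fusion bridges: cylinder along the centroid-connecting segment
    if c.fuse_pairs:
        centroids = ndimage.center_of_mass(
            np.ones(shape), gt.values, ids
        )
        centroids = {i: np.asarray(cm) * sp for i, cm in zip(ids, centroids)}
        for a, b in c.fuse_pairs:
            p, q = centroids[a], centroids[b]
            lo = np.maximum(np.floor((np.minimum(p, q) - c.bridge_radius_mm) / sp), 0).astype(int)
            hi = np.minimum(
                np.ceil((np.maximum(p, q) + c.bridge_radius_mm) / sp) + 1, shape
            ).astype(int)
            slc = tuple(slice(l, h) for l, h in zip(lo, hi))
            grids = np.meshgrid(
                *[np.arange(l, h) * s for l, h, s in zip(lo, hi, sp)], indexing="ij"
            )
            pts = np.stack([g.ravel() for g in grids], axis=1)
            d = q - p
            t = np.clip((pts - p) @ d / (d @ d), 0.0, 1.0)
            closest = p + t[:, None] * d
            dist = np.linalg.norm(pts - closest, axis=1).reshape(grids[0].shape)
            bridge = dist <= c.bridge_radius_mm
            sub = lvl[slc]
            new = bridge & (sub == 0)
            # split bridge levels at the segment midpoint
            sub[new & (t.reshape(bridge.shape) < 0.5)] = level_of[a]
            sub[new & (t.reshape(bridge.shape) >= 0.5)] = level_of[b]

    if c.n_spurious_islands:
        # islands model distant false positives (ribs, sternum): they are
        # placed clear of the spine so they never merge with a vertebra
        present = [level_of[i] for i in ids]
        extent = np.asarray(shape) * sp
        clearance = ndimage.binary_dilation(
            lvl > 0, ndimage.generate_binary_structure(3, 3), iterations=2)
        for _ in range(c.n_spurious_islands):
            for _attempt in range(20):
                r = rng.uniform(*c.island_radius_mm)
                center = rng.uniform(r, extent - r)
                slc, s = _superellipsoid_field(shape, sp, center, (r, r, r), power=2)
                if slc is None:
                    continue
                blob = s <= 1.0
                if not (blob & clearance[slc]).any():
                    lvl[slc][blob] = int(rng.choice(present))
                    break

    # mislabel mixing: level output only, geometry untouched
    gt_fg = gt.values
    for inst_id, (code, frac) in c.mislabel_map.items():
        idx = np.flatnonzero((gt_fg.ravel() == inst_id) & (lvl.ravel() > 0))
        k = int(round(frac * idx.size))
        if k:
            flip = rng.choice(idx, size=k, replace=False)
            lvl.ravel()[flip] = code

    binary = LabelMap((lvl > 0).astype(np.int16), spacing=gt.spacing,
                      origin=gt.origin, semantics="binary")
    level = LabelMap(lvl, spacing=gt.spacing, origin=gt.origin, semantics="level")
    return binary, level
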