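"""Refinement of binary vertebra segmentations into separated instances.

Pipeline: connected-component extraction, candidate filtering on size and
distance to a fitted craniocaudal spine axis, and marker-controlled
watershed splitting of suspected fusions on the negated interior distance
transform.  Composed by :func:`refine_binary` as
extract → filter → split → filter; the output foreground is always a subset
of the input foreground, and every destructive action (removal, split) is
recorded in the segmentation's provenance for auditability — in clinical
use, post-processing that silently rewrites labels is the dominant failure
mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.segmentation import watershed

from .volumes import LabelMap

__all__ = [
    "RefineConfig",
    "InstanceSegmentation",
    "extract_components",
    "filter_candidates",
    "split_fused",
    "refine_binary",
]

log = logging.getLogger("spinepost.refine")

_STRUCTS = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class RefineConfig:
    """Tunables of the refinement pipeline.

    Sizes are volumes in mm³; the candidate window [5, 120] cm³ brackets a
    thoracolumbar vertebral body with wide margins.  Edge-contacting
    candidates are exempted down to ``edge_min_size_mm3`` because partially
    visible vertebrae at scan borders can be arbitrarily truncated.  An
    instance is a suspected fusion when its craniocaudal extent exceeds
    ``fusion_extent_factor × expected_height_mm``.
    """

    connectivity: int = 26
    min_size_mm3: float = 5_000.0
    max_size_mm3: float = 120_000.0
    edge_min_size_mm3: float = 1_000.0
    axis_distance_tolerance_mm: float = 25.0
    expected_height_mm: float = 28.0
    fusion_extent_factor: float = 1.6
    marker_separation_factor: float = 0.8
    split_enabled: bool = True

    def __post_init__(self) -> None:
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.min_size_mm3 < self.max_size_mm3:
            raise ValueError("need 0 < min_size < max_size")
        if self.expected_height_mm <= 0:
            raise ValueError("expected height must be positive")


@dataclass
class InstanceSegmentation:
    """Disjoint candidate-vertebra regions on a common grid.

    ``labels`` is an instance-coded grid; ids run 1..n in craniocaudal
    order (id 1 most superior, i.e. largest axis-2 centroid).  ``table``
    carries per-instance geometry: ``instance_id``, ``n_voxels``,
    ``volume_mm3``, ``centroid_x/y/z_mm``, ``edge_contact``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    table: pd.DataFrame
    provenance: list = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = []

    @property
    def n_instances(self) -> int:
        return len(self.table)

    def mask(self, instance_id: int) -> np.ndarray:
        return self.labels == instance_id

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def to_labelmap(self) -> LabelMap:
        return LabelMap(self.labels.astype(np.int32), spacing=self.spacing,
                        semantics="instance")


def _voxel_volume(spacing) -> float:
    return float(np.prod(spacing))


def _build_table(labels: np.ndarray, spacing) -> pd.DataFrame:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    if ids.size:
        counts = np.bincount(labels.ravel())
        centroids = ndimage.center_of_mass(np.ones(labels.shape), labels, ids)
        objects = ndimage.find_objects(labels)
        for i, cm in zip(ids, centroids):
            bbox = objects[i - 1]
            rows.append(
                {
                    "instance_id": int(i),
                    "n_voxels": int(counts[i]),
                    "volume_mm3": counts[i] * _voxel_volume(spacing),
                    "centroid_x_mm": cm[0] * spacing[0],
                    "centroid_y_mm": cm[1] * spacing[1],
                    "centroid_z_mm": cm[2] * spacing[2],
                    "edge_contact": any(
                        b.start == 0 or b.stop == labels.shape[ax]
                        for ax, b in enumerate(bbox)
                    ),
                }
            )
    cols = ["instance_id", "n_voxels", "volume_mm3", "centroid_x_mm",
            "centroid_y_mm", "centroid_z_mm", "edge_contact"]
    return pd.DataFrame(rows, columns=cols)


def _renumber_craniocaudal(raw_labels: np.ndarray, spacing) -> tuple[np.ndarray, pd.DataFrame]:
    """Relabel components 1..n by descending craniocaudal centroid (superior first)."""
    ids = np.unique(raw_labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return raw_labels.astype(np.int32), _build_table(raw_labels, spacing)
    centroids_z = ndimage.center_of_mass(np.ones(raw_labels.shape), raw_labels, ids)
    cz = np.array([c[2] for c in centroids_z])
    order = ids[np.argsort(-cz, kind="stable")]
    remap = np.zeros(int(raw_labels.max()) + 1, dtype=np.int32)
    for new_id, old_id in enumerate(order, start=1):
        remap[old_id] = new_id
    labels = remap[raw_labels]
    return labels, _build_table(labels, spacing)


def extract_components(binary: LabelMap, connectivity: int = 26) -> InstanceSegmentation:
    """Connected foreground components as candidate vertebrae.

    Components are renumbered deterministically in craniocaudal order.
    """
    if binary.semantics != "binary":
        raise ValueError("extract_components needs a binary labelmap")
    structure = ndimage.generate_binary_structure(3, _STRUCTS[connectivity])
    raw, _ = ndimage.label(binary.values > 0, structure=structure)
    labels, table = _renumber_craniocaudal(raw, binary.spacing)
    seg = InstanceSegmentation(labels, binary.spacing, table)
    seg.provenance.append({"step": "extract", "connectivity": connectivity,
                           "n_components": seg.n_instances})
    return seg


def _fit_spine_axis(table: pd.DataFrame):
    """Least-squares polynomial x(z), y(z) through candidate centroids.

    Degree 2 (or 1 for three points); ``None`` when fewer than three
    candidates are available, in which case the axis filter is skipped.
    """
    if len(table) < 3:
        return None
    z = table["centroid_z_mm"].to_numpy()
    deg = 2 if len(table) >= 4 else 1
    px = np.polynomial.Polynomial.fit(z, table["centroid_x_mm"].to_numpy(), deg)
    py = np.polynomial.Polynomial.fit(z, table["centroid_y_mm"].to_numpy(), deg)
    return px, py


def filter_candidates(seg: InstanceSegmentation, config: RefineConfig | None = None) -> InstanceSegmentation:
    """Keep instances that look like vertebrae by size and axis position.

    Size rule: volume in ``[min_size, max_size]`` mm³, or edge-contacting
    with volume ≥ ``edge_min_size_mm3`` (partial vertebrae at scan borders).
    Axis rule: lateral distance of the centroid from the fitted craniocaudal
    spine axis must not exceed the tolerance.  Removed voxels are dropped
    from the foreground.
    """
    config = config or RefineConfig()
    t = seg.table
    if t.empty:
        return InstanceSegmentation(seg.labels.copy(), seg.spacing, t.copy(),
                                    list(seg.provenance))
    vol = t["volume_mm3"]
    size_ok = (vol >= config.min_size_mm3) & (vol <= config.max_size_mm3)
    edge_ok = t["edge_contact"] & (vol >= config.edge_min_size_mm3) & (vol <= config.max_size_mm3)
    keep = (size_ok | edge_ok).to_numpy()
    reasons = {int(i): "size" for i in t.loc[~keep, "instance_id"]}

    axis = _fit_spine_axis(t[keep])
    if axis is not None:
        px, py = axis
        z = t["centroid_z_mm"].to_numpy()
        dx = t["centroid_x_mm"].to_numpy() - px(z)
        dy = t["centroid_y_mm"].to_numpy() - py(z)
        off_axis = np.hypot(dx, dy) > config.axis_distance_tolerance_mm
        for i in t.loc[keep & off_axis, "instance_id"]:
            reasons[int(i)] = "axis_distance"
        keep = keep & ~off_axis

    kept_ids = t.loc[keep, "instance_id"].to_numpy()
    mask = np.isin(seg.labels, kept_ids)
    labels, table = _renumber_craniocaudal(np.where(mask, seg.labels, 0), seg.spacing)
    out = InstanceSegmentation(labels, seg.spacing, table, list(seg.provenance))
    for inst_id, reason in reasons.items():
        n_vox = int(t.loc[t["instance_id"] == inst_id, "n_voxels"].iloc[0])
        log.info("removed candidate %d (%s, %d voxels)", inst_id, reason, n_vox)
        out.provenance.append({"step": "filter", "action": "remove",
                               "instance_id": inst_id, "reason": reason,
                               "n_voxels": n_vox})
    return out


def _split_markers(mask: np.ndarray, edt: np.ndarray, spacing, config: RefineConfig) -> np.ndarray:
    """Watershed markers: craniocaudal peaks of the interior distance transform.

    The per-slice maximum of the distance transform is scanned along the
    craniocaudal axis; peaks closer than
    ``marker_separation_factor × expected_height_mm`` are suppressed (the
    taller peak wins, ties to the lower craniocaudal index via find_peaks'
    deterministic ordering).  Each surviving peak contributes one marker at
    the slice's distance maximum, ties broken by lowest flat index.
    """
    profile = np.where(mask, edt, 0.0).max(axis=(0, 1))
    min_sep = max(int(math.ceil(config.marker_separation_factor
                                * config.expected_height_mm / spacing[2])), 1)
    peaks, _ = signal.find_peaks(profile, distance=min_sep)
    markers = np.zeros(mask.shape, dtype=np.int32)
    # marker ids in descending z so part ids follow craniocaudal order
    for mid, z in enumerate(sorted(peaks, reverse=True), start=1):
        plane = np.where(mask[:, :, z], edt[:, :, z], -np.inf)
        x, y = np.unravel_index(int(np.argmax(plane)), plane.shape)
        markers[x, y, z] = mid
    return markers


def split_fused(seg: InstanceSegmentation, config: RefineConfig | None = None) -> InstanceSegmentation:
    """Separate suspected fusions with a marker-controlled watershed.

    An instance whose craniocaudal extent exceeds
    ``fusion_extent_factor × expected_height_mm`` is partitioned by a
    watershed on the negated Euclidean interior distance transform; the
    parts form an exact partition of the original voxel set.  A suspect
    with a single distance peak is passed through unchanged with a warning.
    """
    config = config or RefineConfig()
    if seg.table.empty:
        return InstanceSegmentation(seg.labels.copy(), seg.spacing, seg.table.copy(),
                                    list(seg.provenance))
    threshold = config.fusion_extent_factor * config.expected_height_mm
    out_labels = np.zeros_like(seg.labels, dtype=np.int32)
    next_id = 1
    provenance = list(seg.provenance)
    objects = ndimage.find_objects(seg.labels)
    for inst_id in seg.table["instance_id"]:
        bbox = objects[inst_id - 1]
        pad = tuple(
            slice(max(b.start - 1, 0), min(b.stop + 1, seg.labels.shape[ax]))
            for ax, b in enumerate(bbox)
        )
        sub = seg.labels[pad] == inst_id
        extent_mm = (bbox[2].stop - bbox[2].start) * seg.spacing[2]
        parts = None
        if extent_mm > threshold:
            edt = ndimage.distance_transform_edt(sub, sampling=seg.spacing)
            markers = _split_markers(sub, edt, seg.spacing, config)
            n_markers = int(markers.max())
            if n_markers >= 2:
                # flood with the same connectivity used for components, or
                # diagonal-only necks would be left unlabeled
                struct = ndimage.generate_binary_structure(3, _STRUCTS[config.connectivity])
                parts = watershed(-edt, markers=markers, mask=sub, connectivity=struct)
            else:
                log.warning(
                    "instance %d suspected fused (extent %.1f mm) but has a "
                    "single distance peak; passed through", inst_id, extent_mm)
                provenance.append({"step": "split", "action": "unsplittable",
                                   "instance_id": int(inst_id),
                                   "extent_mm": float(extent_mm)})
        if parts is None:
            out_labels[pad][sub] = next_id
            next_id += 1
        else:
            n_parts = int(parts.max())
            assert np.array_equal(parts > 0, sub), "watershed must partition the instance"
            out_labels[pad][sub] = parts[sub] + (next_id - 1)
            provenance.append({"step": "split", "action": "split",
                               "instance_id": int(inst_id),
                               "n_parts": n_parts,
                               "n_voxels": int(sub.sum()),
                               "extent_mm": float(extent_mm)})
            log.info("split instance %d (extent %.1f mm) into %d parts",
                     inst_id, extent_mm, n_parts)
            next_id += n_parts
    labels, table = _renumber_craniocaudal(out_labels, seg.spacing)
    return InstanceSegmentation(labels, seg.spacing, table, provenance)


def refine_binary(binary: LabelMap, config: RefineConfig | None = None) -> InstanceSegmentation:
    """Full refinement: extract → filter → split → filter.

    Never adds foreground voxels; deterministic for a given input and
    config; idempotent on its own output.
    """
    config = config or RefineConfig()
    seg = extract_components(binary, connectivity=config.connectivity)
    seg = filter_candidates(seg, config)
    if config.split_enabled:
        seg = split_fused(seg, config)
        seg = filter_candidates(seg, config)
    return seg
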