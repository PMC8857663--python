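"""Vertebral-level assignment: consensus anchoring and label propagation.

Each refined instance votes on its level by voxel consensus against a
level-coded network prediction; instances whose modal level covers at least
the anchor threshold (default 95%) of their predicted voxels are *anchors*
and considered true.  One winning anchor — the most confident, ties going
to the most superior — fixes the global level sequence, and every instance
is labeled by counting positions from it along the craniocaudal ordering.
Counting from a single anchor is what makes the characteristic offset-by-one
failure possible: if two vertebrae were merged upstream, every vertebra on
the far side of the merge lands one level away from the truth, even where
its own consensus was perfect.  Overridden anchors are logged, never
silently discarded.

Two entry points mirror the two delineation strategies: the *sequential*
approach takes geometry from a binary segmentation and levels from a
separate level-coded prediction; the *combined* approach derives both from
a single level-coded prediction (binarize → refine → re-consult the
original levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refine import InstanceSegmentation, RefineConfig, refine_binary
from .volumes import LabelMap, N_LEVELS, VertebraLevel

__all__ = [
    "LabelingError",
    "LabeledInstanceSegmentation",
    "level_consensus",
    "propagate_labels",
    "sequential_approach",
    "combined_approach",
]

log = logging.getLogger("spinepost.labeling")

DEFAULT_ANCHOR_THRESHOLD = 0.95


class LabelingError(RuntimeError):
    """Raised when no trustworthy labeling exists (no anchors, or the
    propagated sequence runs past T1/L5)."""


@dataclass
class LabeledInstanceSegmentation(InstanceSegmentation):
    """An :class:`InstanceSegmentation` whose table additionally carries
    ``level_code``, ``level_name``, ``consensus_level_code``, ``confidence``
    and ``anchor`` per instance."""

    def to_level_labelmap(self) -> LabelMap:
        out = np.zeros(self.labels.shape, dtype=np.int16)
        for _, row in self.table.iterrows():
            out[self.labels == row["instance_id"]] = row["level_code"]
        return LabelMap(out, spacing=self.spacing, semantics="level")

    def assigned_levels(self) -> list[VertebraLevel]:
        return [VertebraLevel(int(c)) for c in self.table["level_code"]]


def level_consensus(instance_mask: np.ndarray, level_pred: LabelMap):
    """Modal nonzero level over an instance's voxels and its fraction.

    Returns ``(VertebraLevel | None, confidence)``; the confidence is the
    modal count divided by the instance voxels overlapping *any* nonzero
    level prediction.  ``(None, 0.0)`` when there is no overlap at all.
    """
    if instance_mask.shape != level_pred.shape:
        raise ValueError("instance mask and level prediction are misaligned")
    vals = level_pred.values[instance_mask]
    nz = vals[vals > 0]
    if nz.size == 0:
        return None, 0.0
    counts = np.bincount(nz)
    modal = int(np.argmax(counts))  # ties resolve to the smaller (more superior) code
    return VertebraLevel(modal), counts[modal] / nz.size


def propagate_labels(
    seg: InstanceSegmentation,
    consensus: list[tuple[VertebraLevel | None, float]],
    anchor_threshold: float = DEFAULT_ANCHOR_THRESHOLD,
) -> LabeledInstanceSegmentation:
    """Assign a level to every instance by counting from the winning anchor.

    ``consensus`` holds one ``(level, confidence)`` pair per instance in
    craniocaudal order.  Anchors are instances with confidence at or above
    the threshold; the winning anchor is the most confident (ties to the
    most superior) and fixes the sequence ``level_i = winner_level +
    (i - winner_index)``.  Raises :class:`LabelingError` when no anchor
    exists or the implied sequence leaves T1..L5.
    """
    if len(consensus) != seg.n_instances:
        raise ValueError("one consensus entry per instance required")
    if seg.n_instances == 0:
        raise LabelingError("cannot label an empty segmentation")
    anchors = [
        (i, lvl, conf)
        for i, (lvl, conf) in enumerate(consensus)
        if lvl is not None and conf >= anchor_threshold
    ]
    if not anchors:
        raise LabelingError(
            "no instance reaches the anchor threshold "
            f"({anchor_threshold:.2f}); refusing to guess levels"
        )
    # most confident wins; ties to the most superior (lowest index)
    win_idx, win_level, win_conf = max(anchors, key=lambda a: (a[2], -a[0]))
    offset = win_level.code - win_idx

    provenance = list(seg.provenance)
    provenance.append({"step": "propagate", "winning_anchor": int(win_idx) + 1,
                       "level": win_level.name, "confidence": float(win_conf)})
    rows = []
    for i, (lvl, conf) in enumerate(consensus):
        code = offset + i
        if not 1 <= code <= N_LEVELS:
            raise LabelingError(
                f"propagation assigns level code {code} to instance {i + 1}, "
                "outside T1..L5"
            )
        anchor = lvl is not None and conf >= anchor_threshold
        if anchor and lvl.code != code:
            log.warning(
                "anchor instance %d (consensus %s at %.2f) overridden to %s "
                "by winning anchor %d", i + 1, lvl.name, conf,
                VertebraLevel(code).name, win_idx + 1)
            provenance.append({"step": "propagate", "action": "override_anchor",
                               "instance_id": i + 1, "consensus": lvl.name,
                               "assigned": VertebraLevel(code).name,
                               "confidence": float(conf)})
        rows.append({
            "level_code": code,
            "level_name": VertebraLevel(code).name,
            "consensus_level_code": 0 if lvl is None else lvl.code,
            "confidence": float(conf),
            "anchor": bool(anchor),
        })
    table = seg.table.reset_index(drop=True).join(pd.DataFrame(rows))
    return LabeledInstanceSegmentation(seg.labels.copy(), seg.spacing, table, provenance)


def _label_refined(seg: InstanceSegmentation, level_pred: LabelMap,
                   anchor_threshold: float) -> LabeledInstanceSegmentation:
    consensus = [
        level_consensus(seg.mask(i), level_pred)
        for i in seg.table["instance_id"]
    ]
    return propagate_labels(seg, consensus, anchor_threshold)


def sequential_approach(
    binary_pred: LabelMap,
    level_pred: LabelMap,
    config: RefineConfig | None = None,
    anchor_threshold: float = DEFAULT_ANCHOR_THRESHOLD,
) -> LabeledInstanceSegmentation:
    """Geometry from the binary prediction, levels from the level prediction.

    The binary map is refined (components, filtering, watershed splitting),
    then each instance takes its consensus level from ``level_pred`` and
    levels are propagated from the winning anchor.
    """
    if binary_pred.shape != level_pred.shape:
        raise ValueError("binary and level predictions are misaligned")
    seg = refine_binary(binary_pred, config)
    return _label_refined(seg, level_pred, anchor_threshold)


def combined_approach(
    level_pred: LabelMap,
    config: RefineConfig | None = None,
    anchor_threshold: float = DEFAULT_ANCHOR_THRESHOLD,
) -> LabeledInstanceSegmentation:
    """Geometry *and* levels from a single level-coded prediction.

    The level map is binarized (any nonzero level → foreground), refined
    exactly as in the sequential approach, and the refined instances are
    labeled by consensus against the original level map.
    """
    if level_pred.semantics != "level":
        raise ValueError("combined approach needs a level-coded prediction")
    seg = refine_binary(level_pred.binarized(), config)
    return _label_refined(seg, level_pred, anchor_threshold)
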