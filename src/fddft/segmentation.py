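"""Aware feature map, candidate selection, connectivity filters, 3-D assembly.

The stabilized Lagrangian landscape is thresholded at its own final global
mean; the surviving superlevel set, partitioned into connected components
(subgraphs, in the graph-embedding view of the image), is the *aware
feature map*.  Components that touch the high-similarity mask become tumor
candidates; candidates then pass two connectivity filters before the image
is split into tumor and remaining-tissue subgraphs:

* an edge-count floor — a component must have more adjacency edges among
  its pixels than ``3 pi sqrt(||I||_0) / 2`` (strict) or
  ``pi sqrt(||I||_0)`` (relaxed), where ``||I||_0`` counts the nonzero
  pixels of the input image;
* a size cap — each side of the component's bounding box must be at most
  75 % of the corresponding side of the brain-level bounding box (this is
  what removes the skull rim, whose box spans the whole brain).

Slice masks are stacked into a volume, 3-D connected components are
ranked by (mean energy, voxel count), and the single top component is the
final whole-lesion segmentation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .io_preprocess import BoundingBox, ImageGrid, compute_bounding_box
from .stabilization import SimilarityMask

__all__ = [
    "Subgraph",
    "AwareFeatureMap",
    "SegmentationResult",
    "count_edges",
    "aware_feature_map",
    "select_candidates",
    "filter_components",
    "split_image",
    "reconstruct_3d",
]

_STRUCTURES_2D = {4: ndimage.generate_binary_structure(2, 1), 8: ndimage.generate_binary_structure(2, 2)}
_STRUCTURES_3D = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass(frozen=True, eq=False)
class Subgraph:
    """One connected component of the aware feature map."""

    label: int
    mask: np.ndarray
    edge_count: int
    bbox: BoundingBox
    mean_energy: float
    voxel_count: int


@dataclasses.dataclass(frozen=True, eq=False)
class AwareFeatureMap:
    """Superlevel set of the stabilized LDF, labeled into subgraphs."""

    labels: np.ndarray
    components: tuple[Subgraph, ...]
    threshold: float
    connectivity: int


@dataclasses.dataclass(frozen=True, eq=False)
class SegmentationResult:
    """Disjoint tumor/normal partition of the foreground support."""

    tumor_mask: np.ndarray
    normal_mask: np.ndarray


def count_edges(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of adjacency edges between member pixels of a binary mask.

    Under 4-connectivity an edge joins horizontal/vertical neighbours;
    8-connectivity adds the two diagonal directions.  Equals the edge count
    of the induced subgraph of the pixel grid graph.
    """
    m = np.asarray(mask, dtype=bool)
    edges = int((m[:-1, :] & m[1:, :]).sum() + (m[:, :-1] & m[:, 1:]).sum())
    if connectivity == 8:
        edges += int((m[:-1, :-1] & m[1:, 1:]).sum() + (m[:-1, 1:] & m[1:, :-1]).sum())
    elif connectivity != 4:
        raise ValueError(f"2-D connectivity must be 4 or 8, got {connectivity}")
    return edges


def aware_feature_map(
    L_star: np.ndarray, threshold: float, connectivity: int = 8
) -> AwareFeatureMap:
    """Label the superlevel set ``{L_star >= threshold}`` into subgraphs.

    ``threshold`` is the final ``<L>`` from geometric stability, which by
    construction inhibits all elements below the stabilized mean level.
    An empty superlevel set yields an empty map (a valid "no lesion"
    answer), not an error.
    """
    if connectivity not in _STRUCTURES_2D:
        raise ValueError(f"2-D connectivity must be 4 or 8, got {connectivity}")
    L_star = np.asarray(L_star, dtype=float)
    fg = L_star >= threshold
    labels, n = ndimage.label(fg, structure=_STRUCTURES_2D[connectivity])
    comps = []
    for i, slc in enumerate(ndimage.find_objects(labels), start=1):
        local = labels[slc] == i
        full = np.zeros_like(fg)
        full[slc] = local
        comps.append(
            Subgraph(
                label=i,
                mask=full,
                edge_count=count_edges(local, connectivity),
                bbox=BoundingBox(
                    slc[0].start, slc[0].stop - 1, slc[1].start, slc[1].stop - 1
                ),
                mean_energy=float(L_star[full].mean()),
                voxel_count=int(local.sum()),
            )
        )
    return AwareFeatureMap(
        labels=labels, components=tuple(comps), threshold=float(threshold), connectivity=connectivity
    )


def select_candidates(fmap: AwareFeatureMap, sim: SimilarityMask) -> list[Subgraph]:
    """Components whose pixels overlap the similarity mask at identical coordinates."""
    if fmap.labels.shape != sim.mask.shape:
        raise ShapeMismatchError(
            f"feature map {fmap.labels.shape} vs similarity mask {sim.mask.shape}"
        )
    hit = np.unique(fmap.labels[sim.mask.astype(bool)])
    hit = set(int(h) for h in hit if h > 0)
    return [c for c in fmap.components if c.label in hit]


def edge_threshold(l0_norm: int, mode: str = "strict") -> float:
    """Permissible smallest edge number for a retained subgraph."""
    if mode == "strict":
        return 1.5 * np.pi * np.sqrt(l0_norm)
    if mode == "relaxed":
        return np.pi * np.sqrt(l0_norm)
    raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")


def filter_components(
    cands: Sequence[Subgraph],
    img: ImageGrid | np.ndarray,
    mode: str = "strict",
    brain_bbox: BoundingBox | None = None,
    size_ratio: float = 0.75,
    count_mode: str = "edges",
) -> list[Subgraph]:
    """Apply the edge-count floor and the 75 % bounding-box cap.

    ``count_mode='pixels'`` substitutes the component's pixel count for its
    edge count in the floor comparison (fallback reading of "edge number").
    """
    values = img.values if isinstance(img, ImageGrid) else np.asarray(img)
    l0 = int(np.count_nonzero(values))
    if l0 == 0:
        return []
    floor = edge_threshold(l0, mode)
    if brain_bbox is None:
        brain_bbox = compute_bounding_box(values, 0.0)
    kept = []
    for c in cands:
        measure = c.edge_count if count_mode == "edges" else c.voxel_count
        if measure <= floor:
            continue
        if c.bbox.height > size_ratio * brain_bbox.height:
            continue
        if c.bbox.width > size_ratio * brain_bbox.width:
            continue
        kept.append(c)
    return kept


def split_image(img: ImageGrid | np.ndarray, selected: Sequence[Subgraph]) -> SegmentationResult:
    """Partition the foreground into tumor (selected subgraphs) and the rest."""
    values = img.values if isinstance(img, ImageGrid) else np.asarray(img)
    foreground = values > 0
    tumor = np.zeros_like(foreground)
    for c in selected:
        tumor |= c.mask
    tumor &= foreground
    return SegmentationResult(tumor_mask=tumor, normal_mask=foreground & ~tumor)


def reconstruct_3d(
    per_slice: Sequence[SegmentationResult],
    per_slice_energy: Sequence[np.ndarray],
    connectivity: int = 26,
) -> tuple[np.ndarray, list[dict]]:
    """Stack slice masks and keep the top-ranked 3-D connected component.

    Components are ranked by highest mean energy, then largest voxel
    count, then first occurrence in scan order; only the winner survives.
    Returns the (H, W, D) binary mask and a per-component statistics table
    (kept component first is not guaranteed; the table is in label order
    with a ``kept`` flag).
    """
    if connectivity not in _STRUCTURES_3D:
        raise ValueError(f"3-D connectivity must be 6, 18 or 26, got {connectivity}")
    if len(per_slice) == 0:
        return np.zeros((0, 0, 0), dtype=bool), []
    vol = np.stack([np.asarray(s.tumor_mask, dtype=bool) for s in per_slice], axis=-1)
    energy = np.stack([np.asarray(e, dtype=float) for e in per_slice_energy], axis=-1)
    if energy.shape != vol.shape:
        raise ShapeMismatchError(f"energy stack {energy.shape} vs mask stack {vol.shape}")
    labels, n = ndimage.label(vol, structure=_STRUCTURES_3D[connectivity])
    if n == 0:
        return np.zeros_like(vol), []
    stats = []
    for i in range(1, n + 1):
        member = labels == i
        stats.append(
            {
                "label": i,
                "voxel_count": int(member.sum()),
                "mean_energy": float(energy[member].mean()),
                "kept": False,
            }
        )
    best = max(stats, key=lambda s: (s["mean_energy"], s["voxel_count"], -s["label"]))
    best["kept"] = True
    return labels == best["label"], stats
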