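"""Skeleton-based measurement and classification of endoluminal structures.

A protruding structure (polyp or haustral fold) is measured on the axial
slice where its cross-section is largest:

1. :func:`skeletonize_region` - topology-preserving thinning of the
   structure mask to a 1-pixel skeleton;
2. :func:`extract_medial_axis` - skeleton points coincident with the colon
   boundary are removed; the remaining chain, rooted at the wall, is the
   structure's medial axis;
3. :func:`orthogonal_widths` - at each axis point a unit normal is built by
   Gram-Schmidt orthogonalization against the local tangent and the chord
   of the mask along it is measured by sub-voxel ray marching; the maximum
   chord is the width;
4. height = geodesic length of the axis from the wall-attachment root to
   the tip, extended by the inscribed radii at both ends (thinning insets
   the skeleton by half the local width; the medial-axis property recovers
   the full extent), in mm;
5. :func:`classify_structure` - height < 6 mm: polyp, otherwise haustral
   fold candidate; polyps are sessile when height > 1.5 x width, else
   flat; size categories are 1-5 mm, 6-9 mm and >= 10 mm by width.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skeletonize

log = logging.getLogger(__name__)

#: Height (mm) separating polyps from haustral-fold candidates.
FOLD_HEIGHT_MM = 6.0
#: Sessile/flat factor: sessile when height > factor * width.
SESSILE_FACTOR = 1.5

SIZE_1_5 = "1-5mm"
SIZE_6_9 = "6-9mm"
SIZE_GE_10 = ">=10mm"


@dataclass
class MedialAxis:
    """Ordered centerline of a structure on one slice, root (wall) to tip."""

    points: np.ndarray  # (n, 2) voxel (row, col), ordered
    tangents: np.ndarray  # (n, 2) unit tangents in mm space
    spacing: tuple[float, float]  # (row, col) mm
    slice_index: int | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def geodesic_length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        steps = np.diff(self.points.astype(float), axis=0) * np.asarray(self.spacing)
        return float(np.sqrt((steps**2).sum(1)).sum())


@dataclass
class PolypMeasurement:
    """Measured size and class of one endoluminal structure."""

    structure_id: int
    height_mm: float
    width_mm: float
    kind: str  # "polyp" | "fold_candidate"
    morphology: str  # "sessile" | "flat" | "fold_candidate"
    size_category: str
    medial_axis: MedialAxis | None = None
    width_endpoints_mm: tuple[tuple[float, float], tuple[float, float]] | None = None
    slice_index: int | None = None

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "height_mm": round(self.height_mm, 3),
            "width_mm": round(self.width_mm, 3),
            "size_mm": round(self.width_mm, 3),  # reported size = width
            "kind": self.kind,
            "morphology": self.morphology,
            "size_category": self.size_category,
            "slice_index": self.slice_index,
            "width_endpoints_mm": self.width_endpoints_mm,
        }


# --- skeleton ----------------------------------------------------------------

def skeletonize_region(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a binary structure to 1-pixel width.

    The skeleton is produced irrespective of the congruency of the shape.
    An empty mask raises.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    return _skeletonize(mask)


def extract_medial_axis(
    skeleton: np.ndarray,
    boundary: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    slice_index: int | None = None,
) -> MedialAxis:
    """Medial axis of a protrusion: skeleton minus colon-boundary points.

    Skeleton points coincident with the colon wall contour are removed
    (the negated intersection); the longest geodesic chain of what remains,
    rooted at the point nearest the wall, is the structure's axis.  A
    skeleton lying entirely on the boundary means there is no protrusion.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    boundary = np.asarray(boundary, dtype=bool)
    axis_mask = skeleton & ~boundary
    if not axis_mask.any():
        raise ValueError("skeleton lies entirely on the colon boundary: "
                         "no protruding structure")
    pts = np.argwhere(axis_mask)
    # root: axis point closest to the wall
    if boundary.any():
        dist_to_wall = ndimage.distance_transform_edt(~boundary, sampling=spacing)
        root_idx = int(np.argmin(dist_to_wall[pts[:, 0], pts[:, 1]]))
    else:
        root_idx = 0
    path = _longest_geodesic(pts, root_idx, spacing)
    points = pts[path]
    return MedialAxis(
        points=points,
        tangents=_tangents(points, spacing),
        spacing=tuple(spacing),  # type: ignore[arg-type]
        slice_index=slice_index,
    )


def _longest_geodesic(
    pts: np.ndarray, root_idx: int, spacing: tuple[float, float]
) -> list[int]:
    """Dijkstra over the 8-connected pixel graph: path root -> farthest point."""
    index = {tuple(p): i for i, p in enumerate(pts)}
    sp = np.asarray(spacing, dtype=float)
    dist = np.full(len(pts), np.inf)
    prev = np.full(len(pts), -1, dtype=int)
    dist[root_idx] = 0.0
    heap = [(0.0, root_idx)]
    while heap:
        d, i = heapq.heappop(heap)
        if d > dist[i]:
            continue
        r, c = pts[i]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is None:
                    continue
                step = float(np.hypot(dr * sp[0], dc * sp[1]))
                nd = d + step
                if nd < dist[j]:
                    dist[j] = nd
                    prev[j] = i
                    heapq.heappush(heap, (nd, j))
    reachable = np.where(np.isfinite(dist))[0]
    tip = int(reachable[np.argmax(dist[reachable])])
    path = [tip]
    while prev[path[-1]] != -1:
        path.append(int(prev[path[-1]]))
    path.reverse()
    if path[0] != root_idx:  # disconnected axis: keep the root component
        path = [root_idx]
    return path


def _tangents(points: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Unit tangents in mm space: central differences over +/-2 axis points,
    one-sided at the endpoints."""
    n = len(points)
    sp = np.asarray(spacing, dtype=float)
    phys = points.astype(float) * sp
    tangents = np.zeros((n, 2))
    for i in range(n):
        a, b = max(0, i - 2), min(n - 1, i + 2)
        v = phys[b] - phys[a]
        norm = np.linalg.norm(v)
        tangents[i] = v / norm if norm > 0 else np.array([0.0, 0.0])
    return tangents


# --- widths ------------------------------------------------------------------

def _gram_schmidt_normal(tangent: np.ndarray) -> np.ndarray:
    """Unit normal orthogonal to the tangent via Gram-Schmidt.

    The seed vector is the coordinate basis vector least aligned with the
    tangent; subtracting its projection onto the tangent and normalizing
    yields the orthonormal direction along which the chord is measured.
    """
    t = tangent / np.linalg.norm(tangent)
    seed = np.array([1.0, 0.0]) if abs(t[0]) <= abs(t[1]) else np.array([0.0, 1.0])
    n = seed - np.dot(seed, t) * t
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate tangent")
    return n / norm


def _chord_mm(
    point: np.ndarray,
    direction_mm: np.ndarray,
    mask: np.ndarray,
    spacing: np.ndarray,
    step_frac: float = 0.25,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Chord of the mask through ``point`` along a unit mm-space direction.

    Ray-marches both ways at ``step_frac`` of the smaller pixel pitch until
    exiting the mask; the chord is the distance between the two first-exit
    positions.  Returns (length_mm, (end_minus_mm, end_plus_mm))."""
    start = point.astype(float) * spacing
    step = step_frac * float(spacing.min())
    ends = []
    for sign in (1.0, -1.0):
        s = 0.0
        while True:
            s += step
            p = start + sign * s * direction_mm
            idx = np.floor(p / spacing + 0.5).astype(int)
            inside = (
                0 <= idx[0] < mask.shape[0]
                and 0 <= idx[1] < mask.shape[1]
                and mask[idx[0], idx[1]]
            )
            if not inside:
                ends.append((s, p))
                break
    # each pixel spans +/- half a pitch around its centre, so the first-exit
    # arclengths sum to the digitized extent (an isolated pixel reads ~1 px)
    length = ends[0][0] + ends[1][0]
    return length, (ends[1][1], ends[0][1])


def orthogonal_widths(
    axis: MedialAxis, mask: np.ndarray
) -> list[tuple[np.ndarray, float]]:
    """Local widths: mask chords along Gram-Schmidt normals of the axis.

    Returns ``(axis_point, width_mm)`` per axis point, ordered from the
    structure base; the maximum is the structure width.  A single-point
    axis has no tangent: all directions are scanned and the maximum chord
    taken.
    """
    if len(axis) == 0:
        raise ValueError("empty medial axis")
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(axis.spacing, dtype=float)
    results: list[tuple[np.ndarray, float]] = []
    for i, point in enumerate(axis.points):
        tangent = axis.tangents[i]
        if np.linalg.norm(tangent) == 0:
            width = max(
                _chord_mm(point, _unit(np.radians(a)), mask, spacing)[0]
                for a in range(0, 180, 5)
            )
        else:
            normal = _gram_schmidt_normal(tangent)
            width = _chord_mm(point, normal, mask, spacing)[0]
        results.append((point, width))
    return results


def _unit(angle_rad: float) -> np.ndarray:
    return np.array([np.sin(angle_rad), np.cos(angle_rad)])


# --- measurement + classification -------------------------------------------

def classify_structure(height_mm: float, width_mm: float) -> tuple[str, str, str]:
    """Classify by the height rule and the height-to-width ratio.

    A structure is a polyp when its height is under 6 mm, otherwise a
    haustral-fold candidate.  Polyps are sessile when height > 1.5 x width
    and flat otherwise.  Size categories (by width): 1-5 mm, 6-9 mm,
    >= 10 mm - a partition of all positive widths.
    """
    if height_mm <= 0 or width_mm <= 0:
        raise ValueError("height and width must be positive")
    if width_mm <= 5.0:
        category = SIZE_1_5
    elif width_mm < 10.0:
        category = SIZE_6_9
    else:
        category = SIZE_GE_10
    if height_mm < FOLD_HEIGHT_MM:
        kind = "polyp"
        morphology = "sessile" if height_mm > SESSILE_FACTOR * width_mm else "flat"
    else:
        kind = "fold_candidate"
        morphology = "fold_candidate"
    return kind, morphology, category


def measure_structure(
    mask: np.ndarray,
    boundary: np.ndarray,
    spacing: tuple[float, float, float] | tuple[float, float],
    structure_id: int = 0,
) -> PolypMeasurement:
    """Measure one wall-attached structure (2-D slice or 3-D mask).

    A 3-D mask is measured on the axial slice with the largest
    cross-section.  Height is the geodesic length of the medial axis from
    its wall root to its tip plus one pixel extent; width is the maximal
    Gram-Schmidt-orthogonal chord.  A mask detached from the boundary
    raises.
    """
    mask = np.asarray(mask, dtype=bool)
    boundary = np.asarray(boundary, dtype=bool)
    if mask.ndim == 3:
        areas = mask.sum(axis=(1, 2))
        s = int(np.argmax(areas))
        mask2d, boundary2d = mask[s], boundary[s]
        inplane = (float(spacing[0]), float(spacing[1]))
        slice_index: int | None = s
    else:
        mask2d, boundary2d = mask, boundary
        inplane = (float(spacing[0]), float(spacing[1]))
        slice_index = None
    if not mask2d.any():
        raise ValueError("empty structure mask")
    touching = ndimage.binary_dilation(mask2d, np.ones((3, 3), bool)) & boundary2d
    if boundary2d.any() and not touching.any():
        raise ValueError("structure mask is detached from the colon boundary")

    px = float(np.mean(inplane))
    if mask2d.sum() == 1:
        point = np.argwhere(mask2d)[0]
        axis = MedialAxis(
            points=point[None, :],
            tangents=np.zeros((1, 2)),
            spacing=inplane,
            slice_index=slice_index,
        )
        height = width = px
        endpoints = None
    else:
        skel = skeletonize_region(mask2d)
        axis = extract_medial_axis(skel, boundary2d, inplane, slice_index)
        # the thinned axis stops short of the structure's ends: extend the
        # root to the wall attachment (distance to the boundary contour)
        # and the tip by its inscribed radius, so the height spans wall to
        # apex (exact for a wall-attached rectangle)
        edt = ndimage.distance_transform_edt(mask2d, sampling=inplane)
        if boundary2d.any():
            wall_edt = ndimage.distance_transform_edt(~boundary2d, sampling=inplane)
            root_ext = float(wall_edt[tuple(axis.points[0])])
        else:
            root_ext = float(edt[tuple(axis.points[0])])
        tip_ext = float(edt[tuple(axis.points[-1])])
        height = axis.geodesic_length_mm + root_ext + tip_ext - px
        widths = orthogonal_widths(axis, mask2d)
        values = np.array([w for _, w in widths])
        best = int(np.argmax(values))  # ties: first along the order = nearest base
        width = float(values[best])
        spacing_arr = np.asarray(inplane, dtype=float)
        bp = axis.points[best]
        if np.linalg.norm(axis.tangents[best]) > 0:
            normal = _gram_schmidt_normal(axis.tangents[best])
            _, ends = _chord_mm(bp, normal, mask2d, spacing_arr)
            endpoints = (
                tuple(float(v) for v in ends[0]),
                tuple(float(v) for v in ends[1]),
            )
        else:
            endpoints = None
    kind, morphology, category = classify_structure(height, width)
    return PolypMeasurement(
        structure_id=structure_id,
        height_mm=height,
        width_mm=width,
        kind=kind,
        morphology=morphology,
        size_category=category,
        medial_axis=axis,
        width_endpoints_mm=endpoints,
        slice_index=slice_index,
    )


# --- structure finding (pipeline glue) ---------------------------------------

def find_structures(
    hu: np.ndarray,
    voi_mask: np.ndarray,
    contour_mask: np.ndarray,
    tissue_interval: tuple[float, float],
    min_voxels: int = 5,
) -> list[np.ndarray]:
    """Connected soft-tissue components protruding inside the colon VOI.

    Voxels inside the VOI whose HU lie in the soft-tissue interval, away
    from the wall contour, grouped 26-connected.  Used by the measurement
    CLI to turn a (cleansed) volume plus segmentation into structure masks.
    """
    lo, hi = tissue_interval
    near_contour = ndimage.binary_dilation(contour_mask, np.ones((1, 3, 3), bool))
    tissue = (hu >= lo) & (hu <= hi) & voi_mask & ~near_contour
    lbl, n = ndimage.label(tissue, structure=np.ones((3, 3, 3), bool))
    masks = []
    for i in range(1, n + 1):
        m = lbl == i
        if m.sum() >= min_voxels:
            masks.append(m)
    return masks
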