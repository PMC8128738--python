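"""Per-artery scoring territories and their rasterization to voxel masks.

Calcified lesions that cause origin stenoses concentrate around the
ostium where a mesenteric branch leaves the aorta.  The scoring
territory of an artery therefore combines:

* an *origin region* — all tissue within a distance of one origin
  diameter of the ostium centre (a 3D ball by default; an in-plane disc
  mode is available, see :func:`origin_region`), and
* a *distal region* — operator-supplied per-slice polygons following
  the vessel to its anatomical end point (CA: bifurcation, SMA: first
  large jejunal branch, IMA: left colic artery).

All geometry is stored in world millimetres so annotations survive
resampling; masks are rasterized against a specific volume grid on
demand.  Annotation sets round-trip through a versioned JSON schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely import contains_xy as _contains_xy

from .imaging_io import CTVolume

logger = logging.getLogger(__name__)

ARTERIES = ("CA", "SMA", "IMA")

ANNOTATION_SCHEMA_VERSION = 1


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation data."""


@dataclass
class SlicePolygon:
    """A closed in-plane polygon at a given axial position.

    ``z_mm`` is the world z of the slice the polygon was drawn on;
    ``vertices_mm`` is an (N, 2) array of ``(y, x)`` world-mm vertices.
    """

    z_mm: float
    vertices_mm: np.ndarray

    def __post_init__(self) -> None:
        self.vertices_mm = np.asarray(self.vertices_mm, dtype=float)
        if self.vertices_mm.ndim != 2 or self.vertices_mm.shape[1] != 2:
            raise AnnotationError("polygon vertices must be (N, 2)")
        if len(self.vertices_mm) < 3:
            raise AnnotationError("polygon needs at least 3 vertices")


@dataclass
class CircleROI:
    """A circular in-plane ROI (used for aortic contrast-density sampling)."""

    center_mm: tuple[float, float, float]  # (z, y, x)
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise AnnotationError("ROI radius must be positive")


@dataclass
class ScoringRegion:
    """One artery's scoring territory.

    The territory scored is exactly ``origin ∪ distal``; nothing outside
    this union contributes to the artery's calcium score.
    """

    artery: str
    ostium_center_mm: tuple[float, float, float]  # (z, y, x)
    origin_diameter_mm: float
    distal_polygons: list[SlicePolygon] = field(default_factory=list)
    aorta_roi: Optional[CircleROI] = None
    origin_mode: str = "ball"  # "ball" or "disc"

    def __post_init__(self) -> None:
        if self.artery not in ARTERIES:
            raise AnnotationError(f"unknown artery {self.artery!r}")
        if self.origin_diameter_mm <= 0:
            raise AnnotationError("origin diameter must be positive")
        if self.origin_mode not in ("ball", "disc"):
            raise AnnotationError(f"unknown origin mode {self.origin_mode!r}")


@dataclass
class AnnotationSet:
    """All scoring regions for one scan, by one observer."""

    volume_path: str
    volume_checksum: Optional[str]
    regions: list[ScoringRegion]
    observer_id: str = ""
    created: str = ""
    unresolved_volume: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for r in self.regions:
            if r.artery in seen:
                raise AnnotationError(f"duplicate region for artery {r.artery}")
            seen.add(r.artery)
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def region(self, artery: str) -> Optional[ScoringRegion]:
        for r in self.regions:
            if r.artery == artery:
                return r
        return None


# ---------------------------------------------------------------------------
# rasterization

def origin_region(
    ostium_center_mm: Sequence[float],
    origin_diameter_mm: float,
    volume: CTVolume,
    mode: str = "ball",
) -> np.ndarray:
    """Rasterize the origin territory around an ostium.

    A voxel belongs to the region when its centre lies within a distance
    of ``origin_diameter_mm`` (the radius equals one origin *diameter*)
    of the ostium centre.  ``mode="ball"`` applies the distance in 3D;
    ``mode="disc"`` restricts to in-plane distance on the slice(s) whose
    centres lie within half a slice spacing of the ostium (the 2D
    reading of the schematic circle).

    The mask is guaranteed non-empty: a degenerate diameter smaller than
    the voxel pitch still yields the voxel nearest the ostium.
    """
    if origin_diameter_mm <= 0:
        raise ValueError("origin diameter must be positive")
    if not volume.contains_point(ostium_center_mm):
        raise ValueError(f"ostium centre {tuple(ostium_center_mm)} outside volume grid")

    z, y, x = volume.axis_coords()
    dz = (z - ostium_center_mm[0])[:, None, None]
    dy = (y - ostium_center_mm[1])[None, :, None]
    dx = (x - ostium_center_mm[2])[None, None, :]
    r = origin_diameter_mm
    if mode == "ball":
        mask = dz ** 2 + dy ** 2 + dx ** 2 <= r ** 2
    elif mode == "disc":
        in_plane = (dy ** 2 + dx ** 2 <= r ** 2)
        on_slice = np.abs(dz) <= volume.slice_spacing / 2.0
        mask = in_plane & on_slice
    else:
        raise ValueError(f"unknown origin mode {mode!r}")

    if not mask.any():
        kji = np.round(volume.world_to_index(ostium_center_mm)).astype(int)
        kji = np.clip(kji, 0, np.array(volume.shape) - 1)
        mask[tuple(kji)] = True
    return mask


def _validate_simple(vertices_yx: np.ndarray) -> _ShapelyPolygon:
    poly = _ShapelyPolygon([(float(vx), float(vy)) for vy, vx in vertices_yx])
    if not poly.is_valid:
        raise AnnotationError("self-intersecting polygon")
    return poly


def rasterize_polygons(
    slice_polygons: Iterable[tuple[int, np.ndarray]],
    volume: CTVolume,
) -> np.ndarray:
    """Rasterize closed in-plane polygons to a voxel mask.

    ``slice_polygons`` is an iterable of ``(slice_index, vertices)``
    pairs with ``(y, x)`` world-mm vertex coordinates.  A pixel is
    included iff its centre lies inside the polygon; vertex orientation
    is irrelevant.  Self-intersecting polygons are rejected.
    """
    mask = np.zeros(volume.shape, dtype=bool)
    _, yc, xc = volume.axis_coords()
    for slice_index, vertices in slice_polygons:
        vertices = np.asarray(vertices, dtype=float)
        if not 0 <= slice_index < volume.shape[0]:
            raise AnnotationError(f"slice index {slice_index} outside volume")
        poly = _validate_simple(vertices)
        # restrict the point-in-polygon test to the bounding box
        minx, miny, maxx, maxy = poly.bounds
        jsel = np.nonzero((yc >= miny - 1e-9) & (yc <= maxy + 1e-9))[0]
        isel = np.nonzero((xc >= minx - 1e-9) & (xc <= maxx + 1e-9))[0]
        if len(jsel) == 0 or len(isel) == 0:
            continue
        gx, gy = np.meshgrid(xc[isel], yc[jsel])
        inside = _contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        sub = mask[slice_index]
        sub[np.ix_(jsel, isel)] |= inside
    return mask


def distal_region(region: ScoringRegion, volume: CTVolume) -> np.ndarray:
    """Rasterize a region's distal polygons against a volume grid."""
    pairs = []
    for sp in region.distal_polygons:
        k = int(round((sp.z_mm - volume.origin[0]) / volume.slice_spacing))
        if not 0 <= k < volume.shape[0]:
            raise AnnotationError(
                f"polygon at z={sp.z_mm} mm maps outside the volume"
            )
        pairs.append((k, sp.vertices_mm))
    return rasterize_polygons(pairs, volume)


def scoring_mask(region: ScoringRegion, volume: CTVolume) -> np.ndarray:
    """The full scored territory: origin region ∪ distal region."""
    mask = origin_region(
        region.ostium_center_mm,
        region.origin_diameter_mm,
        volume,
        mode=region.origin_mode,
    )
    if region.distal_polygons:
        mask = mask | distal_region(region, volume)
    return mask


def circle_roi_mask(roi: CircleROI, volume: CTVolume) -> np.ndarray:
    """In-plane disc mask on the slice nearest the ROI centre."""
    k = int(round((roi.center_mm[0] - volume.origin[0]) / volume.slice_spacing))
    if not 0 <= k < volume.shape[0]:
        raise ValueError("ROI centre outside volume")
    _, yc, xc = volume.axis_coords()
    dy = (yc - roi.center_mm[1])[:, None]
    dx = (xc - roi.center_mm[2])[None, :]
    mask = np.zeros(volume.shape, dtype=bool)
    mask[k] = dy ** 2 + dx ** 2 <= roi.radius_mm ** 2
    return mask


# ---------------------------------------------------------------------------
# serialization

def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _region_to_dict(r: ScoringRegion) -> dict:
    return {
        "artery": r.artery,
        "ostium_center_mm": list(r.ostium_center_mm),
        "origin_diameter_mm": r.origin_diameter_mm,
        "origin_mode": r.origin_mode,
        "distal_polygons": [
            {"z_mm": sp.z_mm, "vertices_mm": sp.vertices_mm.tolist()}
            for sp in r.distal_polygons
        ],
        "aorta_roi": (
            None
            if r.aorta_roi is None
            else {"center_mm": list(r.aorta_roi.center_mm),
                  "radius_mm": r.aorta_roi.radius_mm}
        ),
    }


def _region_from_dict(d: dict) -> ScoringRegion:
    roi = d.get("aorta_roi")
    return ScoringRegion(
        artery=d["artery"],
        ostium_center_mm=tuple(d["ostium_center_mm"]),
        origin_diameter_mm=float(d["origin_diameter_mm"]),
        origin_mode=d.get("origin_mode", "ball"),
        distal_polygons=[
            SlicePolygon(z_mm=float(p["z_mm"]),
                         vertices_mm=np.asarray(p["vertices_mm"], dtype=float))
            for p in d.get("distal_polygons", [])
        ],
        aorta_roi=(None if roi is None else
                   CircleROI(center_mm=tuple(roi["center_mm"]),
                             radius_mm=float(roi["radius_mm"]))),
    )


def save_annotations(annotations: AnnotationSet, path: str) -> None:
    payload = {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "volume_path": annotations.volume_path,
        "volume_checksum": annotations.volume_checksum,
        "observer_id": annotations.observer_id,
        "created": annotations.created,
        "regions": [_region_to_dict(r) for r in annotations.regions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_annotations(path: str) -> AnnotationSet:
    """Load an annotation set, verifying the referenced volume if present.

    A missing referenced volume is tolerated (``unresolved_volume`` is
    set); a checksum mismatch is logged as a warning — the annotation
    may have been drawn on a different reconstruction.
    """
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed annotation file {path!r}: {exc}") from exc
    version = payload.get("schema_version")
    if version != ANNOTATION_SCHEMA_VERSION:
        raise AnnotationError(f"unsupported annotation schema version {version!r}")

    volume_path = payload.get("volume_path", "")
    checksum = payload.get("volume_checksum")
    unresolved = False
    resolved = volume_path
    if volume_path and not os.path.isabs(volume_path):
        resolved = os.path.join(os.path.dirname(os.path.abspath(path)), volume_path)
    if not volume_path or not os.path.exists(resolved):
        unresolved = True
        if volume_path:
            logger.warning("referenced volume %r not found", volume_path)
    elif checksum is not None and os.path.isfile(resolved):
        actual = file_checksum(resolved)
        if actual != checksum:
            logger.warning(
                "checksum mismatch for %r: annotation was drawn on a "
                "different file", volume_path,
            )

    return AnnotationSet(
        volume_path=volume_path,
        volume_checksum=checksum,
        regions=[_region_from_dict(d) for d in payload.get("regions", [])],
        observer_id=payload.get("observer_id", ""),
        created=payload.get("created", ""),
        unresolved_volume=unresolved,
    )
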