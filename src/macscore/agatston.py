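"""Agatston-definition calcium scoring inside artery scoring regions.

The classic Agatston score works per axial slice: pixels at or above
130 HU are grouped into 8-connected lesions, each lesion contributes
``area (mm²) × density weight``, where the weight is 1–4 depending on
the lesion's peak HU (130–199 → 1, 200–299 → 2, 300–399 → 3, ≥400 → 4),
and the classic protocol assumes 3 mm slices.  This module generalises
the slice thickness with a ``thickness / 3 mm`` factor so that the score
equals the classic score on 3 mm reconstructions and stays proportional
to lesion volume on thinner ones.

The mesenteric artery calcium score (MACS) applies this definition
inside each artery's scoring territory; the combined scores are plain
sums: ``CA+SMA`` and ``total = CA + SMA + IMA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume
from .roi_model import CircleROI, ScoringRegion, circle_roi_mask, scoring_mask

logger = logging.getLogger(__name__)

#: Classic Agatston attenuation threshold (HU); inclusive.
DEFAULT_THRESHOLD_HU = 130.0

#: Classic minimum lesion footprint (mm²); smaller components are noise.
DEFAULT_MIN_AREA_MM2 = 1.0

#: Reference slice thickness of the classic protocol (mm).
REFERENCE_THICKNESS_MM = 3.0

#: 8-connectivity structuring element for in-plane component labelling.
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class Lesion:
    """One per-slice 8-connected calcified component."""

    slice_index: int
    pixels: frozenset  # of (row, col)
    area_mm2: float
    max_hu: float
    weight: int

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class ArteryScore:
    """Per-artery MACS with its contributing lesions."""

    artery: str
    macs: float
    lesions: list[Lesion] = field(default_factory=list)
    threshold_used: float = DEFAULT_THRESHOLD_HU

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


@dataclass
class MacsProfile:
    """Per-artery scores and their combined sums for one scan."""

    ca: ArteryScore
    sma: ArteryScore
    ima: ArteryScore

    def __post_init__(self) -> None:
        labels = (self.ca.artery, self.sma.artery, self.ima.artery)
        if labels != ("CA", "SMA", "IMA"):
            raise ValueError(f"artery labels must be (CA, SMA, IMA), got {labels}")

    @property
    def ca_plus_sma(self) -> float:
        return self.ca.macs + self.sma.macs

    @property
    def total(self) -> float:
        return self.ca.macs + self.sma.macs + self.ima.macs

    def score(self, field_name: str) -> float:
        """Look up a score by field name (ca, sma, ima, ca_sma, total)."""
        table = {
            "ca": self.ca.macs,
            "sma": self.sma.macs,
            "ima": self.ima.macs,
            "ca_sma": self.ca_plus_sma,
            "total": self.total,
        }
        try:
            return table[field_name.lower().replace("+", "_").replace("ca_plus_sma", "ca_sma")]
        except KeyError:
            raise ValueError(f"unknown score field {field_name!r}") from None


@dataclass
class ContrastDensity:
    """Aortic contrast-enhancement density: mean + 2·SD of lumen HU."""

    mean_hu: float
    sd_hu: float
    roi_voxel_count: int
    artery_level: str = ""

    @property
    def density(self) -> float:
        return self.mean_hu + 2.0 * self.sd_hu


def calcium_mask(
    volume: CTVolume, region_mask: np.ndarray, threshold: float = DEFAULT_THRESHOLD_HU
) -> np.ndarray:
    """Voxels inside the region at or above the attenuation threshold."""
    if threshold < DEFAULT_THRESHOLD_HU:
        raise ValueError(
            f"threshold {threshold} HU below the calcium floor of 130 HU"
        )
    if region_mask.shape != volume.shape:
        raise ValueError("region mask shape does not match volume")
    return region_mask & (volume.voxels >= threshold)


def density_weight(max_hu: float) -> int:
    """Agatston density weight from a lesion's peak attenuation."""
    if max_hu < 130:
        raise ValueError(f"peak HU {max_hu} below the 130 HU calcium threshold")
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


def extract_lesions(
    calc_mask: np.ndarray,
    volume: CTVolume,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> list[Lesion]:
    """Group calcium voxels into per-slice 8-connected lesions.

    Components whose in-plane area is below ``min_area_mm2`` are
    discarded as noise (the classic single-pixel speckle filter).
    """
    pixel_area = volume.pixel_area
    lesions: list[Lesion] = []
    for k in range(calc_mask.shape[0]):
        plane = calc_mask[k]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane, structure=_STRUCT_8)
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            area = len(rows) * pixel_area
            if area < min_area_mm2:
                continue
            max_hu = float(volume.voxels[k, rows, cols].max())
            lesions.append(
                Lesion(
                    slice_index=k,
                    pixels=frozenset(zip(rows.tolist(), cols.tolist())),
                    area_mm2=area,
                    max_hu=max_hu,
                    weight=density_weight(max_hu),
                )
            )
    return lesions


def lesion_score(lesion: Lesion, slice_thickness_mm: float) -> float:
    """Score of one lesion: area × weight × (thickness / 3 mm)."""
    return lesion.area_mm2 * lesion.weight * (slice_thickness_mm / REFERENCE_THICKNESS_MM)


def score_mask(
    volume: CTVolume,
    region_mask: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> tuple[float, list[Lesion]]:
    """Agatston score of an arbitrary voxel mask (lower-level entry point)."""
    cmask = calcium_mask(volume, region_mask, threshold)
    lesions = extract_lesions(cmask, volume, min_area_mm2)
    total = float(sum(lesion_score(l, volume.slice_thickness) for l in lesions))
    return total, lesions


def artery_macs(
    volume: CTVolume,
    region: ScoringRegion,
    threshold: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    adaptive_threshold: bool = False,
) -> ArteryScore:
    """Per-artery MACS inside the region's scoring territory.

    With ``adaptive_threshold`` the threshold is raised to the aortic
    contrast density (mean + 2·SD of lumen HU) when that exceeds 130 HU,
    to suppress contrast lumen leaking into the score; off by default —
    the hand-drawn region is normally responsible for excluding lumen.
    """
    effective = threshold
    if adaptive_threshold and region.aorta_roi is not None:
        cd = contrast_density(volume, region.aorta_roi, artery_level=region.artery)
        if cd.density > effective:
            logger.info(
                "%s: raising threshold from %.0f to aortic contrast density %.1f HU",
                region.artery, effective, cd.density,
            )
            effective = cd.density
    mask = scoring_mask(region, volume)
    macs, lesions = score_mask(volume, mask, effective, min_area_mm2)
    return ArteryScore(
        artery=region.artery, macs=macs, lesions=lesions, threshold_used=effective
    )


def macs_profile(ca: ArteryScore, sma: ArteryScore, ima: ArteryScore) -> MacsProfile:
    """Assemble the per-artery scores into a MACS profile (validates labels)."""
    return MacsProfile(ca=ca, sma=sma, ima=ima)


def contrast_density(
    volume: CTVolume,
    aorta_roi: CircleROI,
    artery_level: str = "",
) -> ContrastDensity:
    """Contrast-enhancement density in the aortic lumen.

    Computed as mean + 2 × sample standard deviation (n−1 denominator)
    of the HU values inside a circular ROI placed in the centre of the
    aorta at the level of the artery origin.
    """
    mask = circle_roi_mask(aorta_roi, volume)
    values = volume.voxels[mask]
    if values.size < 2:
        raise ValueError(
            f"aorta ROI contains {values.size} voxel(s); need at least 2"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ContrastDensity(
        mean_hu=mean, sd_hu=sd, roi_voxel_count=int(values.size),
        artery_level=artery_level,
    )


def score_annotated_volume(
    volume: CTVolume,
    regions: Sequence[ScoringRegion],
    threshold: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    adaptive_threshold: bool = False,
) -> MacsProfile:
    """Score all three arteries of an annotated scan.

    Arteries without an annotation contribute a zero score (the vessel
    was judged lesion-free or could not be identified).
    """
    by_artery: dict[str, Optional[ScoringRegion]] = {a: None for a in ("CA", "SMA", "IMA")}
    for r in regions:
        by_artery[r.artery] = r
    scores = {}
    for artery, region in by_artery.items():
        if region is None:
            scores[artery] = ArteryScore(artery=artery, macs=0.0, threshold_used=threshold)
        else:
            scores[artery] = artery_macs(
                volume, region, threshold, min_area_mm2, adaptive_threshold
            )
    return MacsProfile(ca=scores["CA"], sma=scores["SMA"], ima=scores["IMA"])
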