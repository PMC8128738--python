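"""Digital CT phantoms with analytically known calcium scores.

The generator builds small abdominal-style volumes — soft-tissue
background, a contrast-filled aorta, three mesenteric branch tubes
(CA, SMA, IMA) and uniform-HU calcified lesions — together with the
matching scoring annotations and an analytic ground-truth score, so
the whole scoring pipeline can be exercised without patient data.

Lesions are uniform-HU balls or boxes: keeping the attenuation uniform
keeps the ground truth analytic (cross-section area per slice is a
closed form), at the cost of realism (no texture, no blooming).

Two further simulators support the evaluation machinery:

* :func:`simulate_acquisition` — slab-average resampling to a thicker
  reconstruction plus Gaussian noise, a first-order model of the
  partial-volume effect that makes thick-slice and thin-slice scores of
  the same patient differ;
* :func:`make_cohort` — zero-inflated log-normal score cohorts whose
  default parameters approximate the published score distributions of
  CMI and non-CMI patients (calcium scores are non-negative, heavily
  zero-inflated in disease-free patients and strongly right-skewed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agatston import (
    DEFAULT_MIN_AREA_MM2,
    REFERENCE_THICKNESS_MM,
    ArteryScore,
    MacsProfile,
    density_weight,
)
from .cohort_stats import CohortRecord
from .imaging_io import CTVolume
from .roi_model import ARTERIES, AnnotationSet, CircleROI, ScoringRegion, SlicePolygon

logger = logging.getLogger(__name__)

SOFT_TISSUE_HU = -50.0


@dataclass
class LesionSpec:
    """A uniform-HU synthetic calcified lesion."""

    artery: str
    center_mm: tuple[float, float, float]  # (z, y, x)
    shape: str  # "ball" or "box"
    dimensions_mm: tuple  # ball: (diameter,); box: (dz, dy, dx)
    hu: float

    def __post_init__(self) -> None:
        if self.shape not in ("ball", "box"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        dims = np.atleast_1d(np.asarray(self.dimensions_mm, dtype=float))
        if (dims <= 0).any():
            raise ValueError("lesion dimensions must be positive")
        if self.shape == "ball" and dims.size != 1:
            raise ValueError("ball lesions take a single diameter")
        if self.shape == "box" and dims.size != 3:
            raise ValueError("box lesions take (dz, dy, dx)")
        self.dimensions_mm = tuple(dims.tolist())


@dataclass
class BranchSpec:
    """A branch-artery tube leaving the aorta."""

    ostium_mm: tuple[float, float, float]  # (z, y, x)
    diameter_mm: float
    direction: tuple[float, float, float]  # unit-free (z, y, x)
    length_mm: float
    hu: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic scan."""

    shape: tuple[int, int, int] = (40, 64, 64)  # (z, y, x) voxels
    pixel_spacing: tuple[float, float] = (0.7, 0.7)  # (dy, dx) mm
    slice_thickness: float = 0.8
    background_hu: float = SOFT_TISSUE_HU
    aorta_center_mm: tuple[float, float] = (22.4, 16.0)  # (y, x)
    aorta_radius_mm: float = 9.0
    aorta_hu: float = 100.0  # lumen enhancement kept below the 130 HU calcium floor
    branches: dict = field(default_factory=dict)  # artery -> BranchSpec
    lesions: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def grid(self) -> CTVolume:
        """An empty volume with this spec's geometry."""
        return CTVolume(
            voxels=np.zeros(self.shape),
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            slice_spacing=self.slice_thickness,
        )

    def extent_mm(self) -> tuple[float, float, float]:
        return (
            self.shape[0] * self.slice_thickness,
            self.shape[1] * self.pixel_spacing[0],
            self.shape[2] * self.pixel_spacing[1],
        )


def default_spec(seed: int = 0, noise_sd: float = 5.0) -> PhantomSpec:
    """A realistic small phantom: aorta with the three branch ostia and
    one calcified origin lesion per artery.

    Ostia are spaced 12 mm apart along z so that no artery's origin
    territory (radius = one origin diameter, at most 8 mm) reaches a
    neighbouring artery's lesion: each lesion is scored exactly once.
    """
    spec = PhantomSpec(shape=(48, 64, 64), seed=seed, noise_sd=noise_sd)
    zc = spec.shape[0] * spec.slice_thickness / 2.0
    ay, ax = spec.aorta_center_mm
    front = ay + spec.aorta_radius_mm  # branches leave the anterior wall
    spec.branches = {
        "CA": BranchSpec((zc - 12.0, front, ax), 7.0, (0.0, 1.0, 0.0), 12.0, 100.0),
        "SMA": BranchSpec((zc, front, ax), 8.0, (0.3, 1.0, 0.0), 14.0, 100.0),
        "IMA": BranchSpec((zc + 12.0, front, ax - 2.0), 3.5, (0.2, 1.0, -0.2), 10.0, 100.0),
    }
    spec.lesions = [
        LesionSpec("CA", (zc - 12.0, front + 2.0, ax + 2.5), "ball", (4.0,), 450.0),
        LesionSpec("SMA", (zc, front + 3.0, ax - 3.0), "ball", (5.0,), 700.0),
        LesionSpec("IMA", (zc + 12.0, front + 1.2, ax - 3.0), "ball", (2.5,), 250.0),
    ]
    return spec


@dataclass
class LesionTruth:
    artery: str
    hu: float
    weight: int
    slice_areas_mm2: list[float]
    score: float


@dataclass
class GroundTruth:
    """Analytic per-lesion and per-artery scores of a phantom."""

    lesions: list[LesionTruth]
    artery_macs: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.artery_macs.values())


# ---------------------------------------------------------------------------
# analytic scoring

def _ball_cross_section(radius: float, dz: float) -> float:
    h2 = radius ** 2 - dz ** 2
    return math.pi * h2 if h2 > 0 else 0.0


def analytic_score(
    spec: PhantomSpec, min_area_mm2: float = DEFAULT_MIN_AREA_MM2
) -> GroundTruth:
    """Continuous-geometry counterpart of the discrete score.

    Each lesion contributes, per slice whose centre plane intersects it,
    ``exact cross-section area × density weight × thickness / 3 mm``.
    Slices with cross-section below ``min_area_mm2`` are dropped, the
    same footprint filter the discrete scorer applies.  Lesions below
    130 HU score zero.
    """
    t = spec.slice_thickness
    nz = spec.shape[0]
    slice_z = (np.arange(nz)) * t  # slice-centre world z (origin at 0)
    truths: list[LesionTruth] = []
    artery_totals = {a: 0.0 for a in ARTERIES}
    for lesion in spec.lesions:
        if lesion.hu < 130:
            truths.append(LesionTruth(lesion.artery, lesion.hu, 0, [], 0.0))
            continue
        w = density_weight(lesion.hu)
        zc = lesion.center_mm[0]
        areas = []
        for z in slice_z:
            if lesion.shape == "ball":
                area = _ball_cross_section(lesion.dimensions_mm[0] / 2.0, z - zc)
            else:
                dz_half = lesion.dimensions_mm[0] / 2.0
                inside = abs(z - zc) <= dz_half
                area = lesion.dimensions_mm[1] * lesion.dimensions_mm[2] if inside else 0.0
            if area >= min_area_mm2:
                areas.append(float(area))
        score = sum(areas) * w * (t / REFERENCE_THICKNESS_MM)
        truths.append(LesionTruth(lesion.artery, lesion.hu, w, areas, score))
        artery_totals[lesion.artery] += score
    return GroundTruth(lesions=truths, artery_macs=artery_totals)


# ---------------------------------------------------------------------------
# voxelisation

def _lesion_mask(lesion: LesionSpec, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    dz = (z - lesion.center_mm[0])[:, None, None]
    dy = (y - lesion.center_mm[1])[None, :, None]
    dx = (x - lesion.center_mm[2])[None, None, :]
    if lesion.shape == "ball":
        r = lesion.dimensions_mm[0] / 2.0
        return dz ** 2 + dy ** 2 + dx ** 2 <= r ** 2
    hz, hy, hx = (d / 2.0 for d in lesion.dimensions_mm)
    return (np.abs(dz) <= hz) & (np.abs(dy) <= hy) & (np.abs(dx) <= hx)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, AnnotationSet, GroundTruth]:
    """Voxelise a phantom spec.

    Painting order: background → aorta → branch tubes → lesions, then
    additive Gaussian noise with the spec's seed.  Overlapping lesions
    of different HU are rejected because their ground truth would be
    ambiguous.  The annotation set places each artery's origin region
    (ball of radius = origin diameter) at its ostium, adds per-slice
    rectangle polygons covering the branch course, and an aortic ROI at
    the ostium level for contrast-density measurement.
    """
    vol = spec.grid()
    z, y, x = vol.axis_coords()
    voxels = np.full(spec.shape, spec.background_hu, dtype=float)

    # aorta: cylinder along z
    ay, ax = spec.aorta_center_mm
    in_aorta = ((y - ay)[None, :, None] ** 2 + (x - ax)[None, None, :] ** 2
                <= spec.aorta_radius_mm ** 2)
    voxels[np.broadcast_to(in_aorta, spec.shape)] = spec.aorta_hu

    # branch tubes: capsule around the segment ostium → ostium + L·dir
    for branch in spec.branches.values():
        p0 = np.asarray(branch.ostium_mm, dtype=float)
        d = np.asarray(branch.direction, dtype=float)
        d = d / np.linalg.norm(d)
        pts = np.stack(np.meshgrid(z, y, x, indexing="ij"), axis=-1)
        rel = pts - p0
        t_par = np.clip(rel @ d, 0.0, branch.length_mm)
        closest = p0 + t_par[..., None] * d
        dist2 = np.sum((pts - closest) ** 2, axis=-1)
        voxels[dist2 <= (branch.diameter_mm / 2.0) ** 2] = branch.hu

    # lesions (checked for ambiguous overlap first)
    masks = [_lesion_mask(l, z, y, x) for l in spec.lesions]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any() and spec.lesions[i].hu != spec.lesions[j].hu:
                raise ValueError(
                    f"lesions {i} and {j} overlap with different HU; "
                    "ground truth would be ambiguous"
                )
    for lesion, mask in zip(spec.lesions, masks):
        voxels[mask] = lesion.hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = CTVolume(
        voxels=voxels,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_spacing=spec.slice_thickness,
    )

    regions = []
    for artery, branch in spec.branches.items():
        regions.append(_branch_region(spec, artery, branch))
    annotations = AnnotationSet(
        volume_path="", volume_checksum=None, regions=regions,
        observer_id="phantom-generator",
    )
    return volume, annotations, analytic_score(spec)


def _branch_region(spec: PhantomSpec, artery: str, branch: BranchSpec) -> ScoringRegion:
    """Scoring region for one branch: origin ball + rectangles along the tube."""
    p0 = np.asarray(branch.ostium_mm, dtype=float)
    d = np.asarray(branch.direction, dtype=float)
    d = d / np.linalg.norm(d)
    p1 = p0 + branch.length_mm * d
    half = branch.diameter_mm  # generous in-plane half-width
    zmax = (spec.shape[0] - 1) * spec.slice_thickness
    extent = spec.extent_mm()

    polygons = []
    z_lo, z_hi = sorted((p0[0], p1[0]))
    k_lo = max(0, int(math.floor(z_lo / spec.slice_thickness)))
    k_hi = min(spec.shape[0] - 1, int(math.ceil(z_hi / spec.slice_thickness)))
    for k in range(k_lo, k_hi + 1):
        zk = k * spec.slice_thickness
        # interpolate the tube axis position at this slice
        if abs(p1[0] - p0[0]) > 1e-9:
            f = np.clip((zk - p0[0]) / (p1[0] - p0[0]), 0.0, 1.0)
        else:
            f = 0.5
        c = p0 + f * (p1 - p0)
        span = max(half, branch.length_mm / 2.0 + half)
        y0, y1 = c[1] - span, c[1] + span
        x0, x1 = c[2] - span, c[2] + span
        y0, y1 = max(y0, 0.0), min(y1, extent[1])
        x0, x1 = max(x0, 0.0), min(x1, extent[2])
        polygons.append(SlicePolygon(
            z_mm=min(zk, zmax),
            vertices_mm=np.array([[y0, x0], [y0, x1], [y1, x1], [y1, x0]]),
        ))

    aorta_roi = CircleROI(
        center_mm=(float(p0[0]), spec.aorta_center_mm[0], spec.aorta_center_mm[1]),
        radius_mm=spec.aorta_radius_mm / 2.0,
    )
    return ScoringRegion(
        artery=artery,
        ostium_center_mm=tuple(float(v) for v in p0),
        origin_diameter_mm=branch.diameter_mm,
        distal_polygons=polygons,
        aorta_roi=aorta_roi,
    )


# ---------------------------------------------------------------------------
# acquisition simulation

def simulate_acquisition(
    volume: CTVolume,
    new_thickness: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CTVolume:
    """Re-reconstruct a volume at a thicker slice by slab averaging.

    Consecutive native slices are grouped into slabs of
    ``round(new_thickness / native)`` slices and averaged — a
    first-order partial-volume model: small dense lesions are diluted
    with surrounding tissue, lowering both their peak HU and their
    above-threshold footprint.  A non-integer slab ratio falls back to
    the nearest integer slab (logged); trailing slices that do not fill
    a slab are dropped.  Gaussian noise of ``noise_sd`` HU is then added.
    """
    native = volume.slice_spacing
    if new_thickness < native - 1e-9:
        raise ValueError("new thickness must be at least the native thickness")
    ratio = new_thickness / native
    k = max(1, int(round(ratio)))
    if abs(ratio - k) > 1e-6:
        logger.info(
            "slab ratio %.3f is not integer; using nearest slab of %d slices "
            "(effective thickness %.3f mm)", ratio, k, k * native,
        )
    nz = volume.shape[0]
    n_out = nz // k
    if n_out * k != nz:
        logger.info("dropping %d trailing slice(s) not filling a slab", nz - n_out * k)
    data = volume.voxels[: n_out * k].reshape(n_out, k, *volume.shape[1:]).mean(axis=1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    new_z0 = volume.origin[0] + (k - 1) * native / 2.0
    return CTVolume(
        voxels=data,
        pixel_spacing=volume.pixel_spacing,
        slice_thickness=k * native,
        slice_spacing=k * native,
        origin=(new_z0, volume.origin[1], volume.origin[2]),
    )


# ---------------------------------------------------------------------------
# score-cohort simulation

#: Zero-inflated log-normal parameters (zero fraction, log-median,
#: log-sd) per group and artery.  Least-squares fits of the mixture
#: quantile function to published median/IQR score summaries: CMI
#: patients carry substantial calcium in CA and SMA, disease-free
#: patients have a score of 0 in the majority of vessels.
DEFAULT_COHORT_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "CMI": {
        "ca": (0.10, 5.42, 1.26),
        "sma": (0.24, 6.48, 1.92),
        "ima": (0.30, 3.74, 1.23),
    },
    "non-CMI": {
        "ca": (0.55, 5.12, 1.50),
        "sma": (0.55, 5.08, 1.50),
        "ima": (0.55, 3.15, 1.50),
    },
}


def make_cohort(
    n_cmi: int,
    n_non_cmi: int,
    params: Optional[dict] = None,
    seed: int = 0,
) -> list[CohortRecord]:
    """Draw a synthetic score cohort from zero-inflated log-normals.

    Each artery score is 0 with probability ``zero fraction`` and
    ``exp(Normal(log-median, log-sd))`` otherwise, independently per
    artery.  Defaults emulate the published CMI / non-CMI score
    distributions; pass ``params`` (same nested structure as
    :data:`DEFAULT_COHORT_PARAMS`) to override.
    """
    if n_cmi <= 0 or n_non_cmi <= 0:
        raise ValueError("both group sizes must be positive")
    params = params or DEFAULT_COHORT_PARAMS
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for group, n in (("CMI", n_cmi), ("non-CMI", n_non_cmi)):
        gp = params[group]
        for i in range(n):
            scores = {}
            for artery in ("ca", "sma", "ima"):
                p0, mu, sigma = gp[artery]
                if rng.random() < p0:
                    scores[artery] = 0.0
                else:
                    scores[artery] = float(np.exp(rng.normal(mu, sigma)))
            profile = MacsProfile(
                ca=ArteryScore("CA", scores["ca"]),
                sma=ArteryScore("SMA", scores["sma"]),
                ima=ArteryScore("IMA", scores["ima"]),
            )
            records.append(CohortRecord(
                patient_id=f"{group.replace('-', '')}-{i:04d}",
                group=group, profile=profile,
            ))
    return records


def make_paired_thickness_phantoms(
    n_pairs: int,
    thin_thickness: float = 0.8,
    thick_thickness: float = 3.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[CTVolume, CTVolume, AnnotationSet]]:
    """Phantom pairs mimicking two reconstructions of the same patient.

    Each pair shares one underlying phantom with sub-slice-scale lesions
    (1–2.5 mm, comparable to the thick-slice spacing), scanned once at
    the thin native thickness and once slab-averaged to the thick
    protocol.  The slab averaging dilutes small lesions — the simulated
    partial-volume effect — so thin- and thick-slice scores of the same
    anatomy systematically differ.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        spec = PhantomSpec(
            shape=(32, 48, 48),
            pixel_spacing=(0.7, 0.7),
            slice_thickness=thin_thickness,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            noise_sd=noise_sd,
        )
        zc = spec.shape[0] * thin_thickness / 2.0
        ay, ax = 16.8, 16.8
        spec.aorta_center_mm = (ay, ax)
        spec.aorta_radius_mm = 7.0
        front = ay + spec.aorta_radius_mm
        spec.branches = {
            "CA": BranchSpec((zc - 5.0, front, ax), 6.0, (0.0, 1.0, 0.0), 8.0, 100.0),
            "SMA": BranchSpec((zc, front, ax + 3.0), 7.0, (0.3, 1.0, 0.0), 8.0, 100.0),
            "IMA": BranchSpec((zc + 5.0, front, ax - 3.0), 3.0, (0.2, 1.0, 0.0), 6.0, 100.0),
        }
        spec.lesions = []
        placed: list[tuple[np.ndarray, float]] = []
        for artery, branch in spec.branches.items():
            n_lesions = int(rng.integers(1, 4))
            for m in range(n_lesions):
                diameter = float(rng.uniform(1.2, 2.5))  # sub-slice at 3 mm
                hu = float(rng.uniform(300.0, 900.0))
                # rejection-sample a centre that keeps lesions disjoint
                for _attempt in range(50):
                    offset = np.array([
                        rng.uniform(-2.0, 2.0),
                        rng.uniform(0.5, 3.0),
                        rng.uniform(-3.0, 3.0),
                    ])
                    center = np.asarray(branch.ostium_mm) + offset
                    if all(np.linalg.norm(center - c) > (diameter + d) / 2.0 + 0.3
                           for c, d in placed):
                        break
                else:
                    continue  # crowded neighbourhood: skip this lesion
                placed.append((center, diameter))
                spec.lesions.append(LesionSpec(
                    artery, tuple(center.tolist()), "ball", (diameter,), hu,
                ))
        thin, annotations, _ = generate_phantom(spec)
        thick = simulate_acquisition(
            thin, thick_thickness, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        pairs.append((thin, thick, annotations))
    return pairs
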