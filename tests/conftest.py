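import numpy as np
import pytest

from macscore.agatston import ArteryScore, MacsProfile
from macscore.cohort_stats import CohortRecord
from macscore.imaging_io import CTVolume


def reconstructed_cohort(tp=43, fn=6, fp=65, tn=70, cutoff=29.7, seed=1234):
    """A cohort whose combined CA+SMA score reproduces a given 2x2 table
    at the given cutoff (scores spread on both sides of it).

    The default counts are the unique confusion table consistent with
    the published group sizes (49 diseased, 135 disease-free) and the
    published sensitivity/specificity at the 29.7 combined-score cutoff.
    """
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for n, group, positive in ((tp, "CMI", True), (fn, "CMI", False),
                               (fp, "non-CMI", True), (tn, "non-CMI", False)):
        for _ in range(n):
            if positive:
                ca_sma = cutoff + float(rng.uniform(0.0, 1500.0))
            else:
                ca_sma = float(rng.uniform(0.0, cutoff - 1e-6))
            records.append(CohortRecord(
                patient_id=f"p{i:04d}", group=group,
                profile=MacsProfile(ArteryScore("CA", ca_sma / 2),
                                    ArteryScore("SMA", ca_sma / 2),
                                    ArteryScore("IMA", 0.0)),
            ))
            i += 1
    return records


def make_volume(
    voxels,
    pixel_spacing=(1.0, 1.0),
    slice_thickness=3.0,
    origin=(0.0, 0.0, 0.0),
) -> CTVolume:
    return CTVolume(
        voxels=np.asarray(voxels, dtype=float),
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
        slice_spacing=slice_thickness,
        origin=origin,
    )


@pytest.fixture
def uniform_volume():
    """A 10³ isotropic 1 mm volume of soft tissue (-50 HU)."""
    return make_volume(np.full((10, 10, 10), -50.0))
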