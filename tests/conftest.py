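import numpy as np
import pytest

from radsem.features import RadiomicFeatureExtractor
from radsem.semantic import SemanticRecord
from radsem.synthetic import make_cohort
from radsem.volume import RegionMask, VoxelVolume

COHORT_N = 200
COHORT_SEED = 7


def make_record(subject_id="S0", **overrides):
    """A mid-range semantic record with selective overrides."""
    base = dict(cavitation=0, air_bronchogram=0, calcification=0, texture=3,
                border_definition=2, contour=2, lobulation=2, spiculation=2,
                concavity=2)
    base.update(overrides)
    return SemanticRecord(subject_id=subject_id, **base)


@pytest.fixture(scope="session")
def phantom_cohort():
    """200 phantoms at 1 mm isotropic 64^3 grids, fixed seed, with the
    48-feature original-image table; shared by the slower statistical tests."""
    subjects = make_cohort(COHORT_N, seed=COHORT_SEED)
    extractor = RadiomicFeatureExtractor().fit()
    features = extractor.transform(subjects)
    semantic = {
        name: np.array([getattr(s.semantic, name) for s in subjects])
        for name in ("cavitation", "air_bronchogram", "calcification", "texture",
                     "border_definition", "contour", "lobulation", "spiculation",
                     "concavity")
    }
    records = [s.semantic for s in subjects]
    return features, semantic, records


@pytest.fixture()
def digital_ball():
    """Radius-20 mm ball on a 1 mm grid."""
    g = 48
    ax = np.arange(g) - (g - 1) / 2.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return RegionMask(x**2 + y**2 + z**2 <= 20.0**2, (1.0, 1.0, 1.0))


@pytest.fixture()
def noisy_region():
    """Small random HU region + mask for feature unit tests."""
    rng = np.random.default_rng(42)
    vol = VoxelVolume(rng.normal(-100, 120, size=(12, 11, 10)), (1.0, 1.0, 1.0))
    mask = np.zeros(vol.shape, dtype=bool)
    mask[2:10, 2:9, 2:8] = rng.random((8, 7, 6)) > 0.25
    return vol, RegionMask(mask, vol.spacing)
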