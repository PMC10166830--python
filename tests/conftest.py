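import numpy as np
import pytest

from embody.core import EMOTIONS, BodyMap, BodyMask, MapCollection, SubjectRecord
from embody.masks import make_body_mask


@pytest.fixture(scope="session")
def small_mask() -> BodyMask:
    return make_body_mask(0.15)


@pytest.fixture(scope="session")
def flat_mask() -> BodyMask:
    """40x40 mask with a large head region and minimal other ROIs.

    Convenient for hand-built pixel layouts: rows 0..35 are all label 1,
    row 38 carries one pixel of each remaining ROI.
    """
    grid = np.zeros((40, 40), dtype=np.int64)
    grid[:36, :] = 1
    grid[38, :4] = [2, 3, 4, 5]
    return BodyMask(grid)


@pytest.fixture
def map_factory(flat_mask):
    """Build a BodyMap on the flat mask from sparse pixel specs."""

    def build(pixels: dict[tuple[int, int], float], subject="s1",
              emotion="happiness", polarity="activation", mask=flat_mask):
        grid = np.zeros(mask.shape)
        for (r, c), v in pixels.items():
            grid[r, c] = v
        return BodyMap(subject, emotion, polarity, grid, mask)

    return build


@pytest.fixture
def empty_pair_collection(flat_mask):
    """Collection builder: subjects with all-empty maps except given pixels."""

    def build(painted: dict[tuple[str, str, str], dict[tuple[int, int], float]],
              subject_ids=("s1",)):
        subjects = [
            SubjectRecord(sid, "SPQ", {"interpersonal": 1.0,
                                       "cognitive_perceptual": 1.0,
                                       "disorganized": 1.0})
            for sid in subject_ids
        ]
        maps = {}
        for sid in subject_ids:
            for emotion in EMOTIONS:
                for polarity in ("activation", "deactivation"):
                    grid = np.zeros(flat_mask.shape)
                    for (r, c), v in painted.get((sid, emotion, polarity), {}).items():
                        grid[r, c] = v
                    maps[(sid, emotion, polarity)] = BodyMap(
                        sid, emotion, polarity, grid, flat_mask)
        return MapCollection(flat_mask, subjects, maps)

    return build
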