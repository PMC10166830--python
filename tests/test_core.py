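import numpy as np
import pandas as pd
import pytest

from embody.core import (
    EMOTIONS,
    BodyMask,
    SubjectRecord,
    arousal_class,
    harmonize_schizotypy,
    load_collection,
    load_mask,
    save_collection,
    save_mask,
)
from embody.masks import make_body_mask
from embody.synth import SynthConfig, generate_collection


def _labeled_grid(n_labeled=40):
    grid = np.zeros((10, 10), dtype=np.int64)
    flat = grid.ravel()
    flat[:n_labeled] = (np.arange(n_labeled) % 5) + 1
    return flat.reshape(10, 10)


class TestBodyMask:
    def test_counts_nonzero_labels(self):
        mask = BodyMask(_labeled_grid(40))
        assert mask.n_body_pixels == 40

    def test_rejects_illegal_label(self):
        grid = _labeled_grid(40)
        grid[9, 9] = 7
        with pytest.raises(ValueError, match="illegal ROI label"):
            BodyMask(grid)

    def test_rejects_empty_roi(self):
        grid = np.zeros((10, 10), dtype=np.int64)
        grid[0, :4] = [1, 2, 3, 4]  # no legs pixel
        with pytest.raises(ValueError, match="legs"):
            BodyMask(grid)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_mask(tmp_path / "nope.txt")

    def test_save_load_roundtrip(self, tmp_path):
        mask = make_body_mask(0.1)
        save_mask(mask, tmp_path / "mask.txt")
        again = load_mask(tmp_path / "mask.txt")
        assert np.array_equal(mask.grid, again.grid)
        assert again.n_body_pixels == mask.n_body_pixels


class TestCollectionIO:
    def test_roundtrip_exact_and_cardinality(self, tmp_path):
        coll = generate_collection(
            SynthConfig(n_subjects=2, seed=4), mask=make_body_mask(0.1))
        assert len(coll) == 2 * 12 * 2
        out = tmp_path / "data"
        manifest = save_collection(coll, out)
        again = load_collection(manifest, load_mask(out / "mask.txt"),
                                subjects_path=out / "subjects.csv")
        assert set(again.maps) == set(coll.maps)
        for key, m in coll.maps.items():
            assert np.array_equal(m.grid, again.maps[key].grid), key

    def test_rejects_out_of_range_intensity(self, tmp_path, flat_mask):
        grid = np.zeros(flat_mask.shape)
        grid[0, 0] = 101
        np.savetxt(tmp_path / "r.txt", grid)
        pd.DataFrame([{"subject_id": "s1", "emotion": "anger",
                       "polarity": "activation", "raster_path": "r.txt"}]
                     ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="intensity out of range"):
            load_collection(tmp_path / "m.csv", flat_mask)

    def test_rejects_paint_outside_silhouette(self, tmp_path, flat_mask):
        grid = np.zeros(flat_mask.shape)
        grid[39, 10] = 5.0  # background cell
        np.savetxt(tmp_path / "r.txt", grid)
        pd.DataFrame([{"subject_id": "s1", "emotion": "anger",
                       "polarity": "activation", "raster_path": "r.txt"}]
                     ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="1 pixel"):
            load_collection(tmp_path / "m.csv", flat_mask)

    def test_rejects_duplicate_keys(self, tmp_path, flat_mask):
        np.savetxt(tmp_path / "r.txt", np.zeros(flat_mask.shape))
        row = {"subject_id": "s1", "emotion": "anger",
               "polarity": "activation", "raster_path": "r.txt"}
        pd.DataFrame([row, row]).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_collection(tmp_path / "m.csv", flat_mask)


def _subjects(scores, instrument="SPQ"):
    return [
        SubjectRecord(f"s{i}", instrument,
                      {"interpersonal": v, "cognitive_perceptual": v,
                       "disorganized": v})
        for i, v in enumerate(scores)
    ]


class TestHarmonization:
    def test_three_point_subsample(self):
        out = harmonize_schizotypy(_subjects([1.0, 2.0, 3.0]))
        z = [s.z_factor_scores["interpersonal"] for s in out]
        assert z == pytest.approx([-1.0, 0.0, 1.0])

    def test_two_subsamples_standardized_independently(self):
        subs = _subjects([0.0, 10.0], "SPQ") + _subjects([0.0, 10.0], "SPQ-B")
        out = harmonize_schizotypy(subs)
        for s in out:
            expected = -0.707 if s.raw_factor_scores["interpersonal"] == 0 else 0.707
            assert s.z_factor_scores["interpersonal"] == pytest.approx(expected, abs=1e-3)

    def test_mixed_cohort_moments(self):
        rng = np.random.default_rng(0)
        subs = (_subjects(rng.gamma(2, 10, size=20), "SPQ")
                + _subjects(rng.gamma(3, 4, size=30), "SPQ-B"))
        out = harmonize_schizotypy(subs)
        for instrument in ("SPQ", "SPQ-B"):
            for factor in ("interpersonal", "cognitive_perceptual", "disorganized"):
                z = np.array([s.z_factor_scores[factor] for s in out
                              if s.instrument == instrument])
                assert z.mean() == pytest.approx(0.0, abs=1e-12)
                assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_names_factor_and_instrument(self):
        with pytest.raises(ValueError, match="interpersonal.*SPQ"):
            harmonize_schizotypy(_subjects([5.0, 5.0]))

    def test_idempotent_and_pure(self):
        subs = _subjects([1.0, 4.0, 9.0])
        once = harmonize_schizotypy(subs)
        assert all(s.z_factor_scores is None for s in subs)  # input untouched
        # re-harmonizing the z-scores themselves reproduces them
        rescored = [
            SubjectRecord(s.subject_id, s.instrument,
                          {k: v for k, v in s.z_factor_scores.items()})
            for s in once
        ]
        twice = harmonize_schizotypy(rescored)
        for a, b in zip(once, twice):
            for f, v in a.z_factor_scores.items():
                assert b.z_factor_scores[f] == pytest.approx(v, abs=1e-12)


def test_arousal_classification():
    assert arousal_class("sadness") == "low"
    assert arousal_class("pride") == "high"
    assert arousal_class("anxiety") == "excluded"
    assert arousal_class("neutral") == "neutral"
    assert len(EMOTIONS) == 12
    with pytest.raises(ValueError):
        arousal_class("boredom")
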