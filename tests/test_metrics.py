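import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from embody.metrics import (
    add_diffusion_z,
    congruency_scores,
    intensity_metric,
    mean_pairwise_manhattan,
    mixed_pixels,
    roi_diffusion,
    size_metric,
    subject_summary,
)
from embody.preprocess import smooth_map


class TestManhattanDiffusion:
    def test_two_pixels(self):
        assert mean_pairwise_manhattan(np.array([[0, 0], [3, 4]])) == 7.0

    def test_three_pixels(self):
        coords = np.array([[0, 0], [3, 4], [6, 0]])
        assert mean_pairwise_manhattan(coords) == pytest.approx((7 + 6 + 7) / 3)

    def test_degenerate_sets_score_zero(self):
        assert mean_pairwise_manhattan(np.empty((0, 2))) == 0.0
        assert mean_pairwise_manhattan(np.array([[5, 5]])) == 0.0

    @pytest.mark.parametrize("k", [10, 100, 500, 1000])
    def test_sorted_axis_equals_brute_force(self, k):
        rng = np.random.default_rng(k)
        coords = rng.integers(0, 200, size=(k, 2))
        fast = mean_pairwise_manhattan(coords)
        brute = pdist(coords.astype(float), metric="cityblock").mean()
        assert fast == pytest.approx(brute, abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=2, max_size=40, unique=True),
           st.tuples(st.integers(-30, 30), st.integers(-30, 30)))
    def test_translation_invariance(self, pts, offset):
        coords = np.array(pts)
        shifted = coords + np.array(offset)
        assert mean_pairwise_manhattan(coords) == pytest.approx(
            mean_pairwise_manhattan(shifted), abs=1e-9)

    def test_roi_diffusion_on_map(self, flat_mask, map_factory):
        bmap = map_factory({(0, 0): 50.0, (3, 4): 10.0})
        assert roi_diffusion(bmap, flat_mask, "head") == 7.0
        assert roi_diffusion(bmap, flat_mask, 1) == 7.0
        assert roi_diffusion(bmap, flat_mask, "legs") == 0.0
        with pytest.raises(ValueError, match="unknown ROI"):
            roi_diffusion(bmap, flat_mask, 9)


class TestDiffusionZ:
    def test_pooled_z_with_zeros(self):
        df = pd.DataFrame({"diffusion_raw": [0.0, 0.0, 6.0, 6.0]})
        z = add_diffusion_z(df)["diffusion_z"]
        assert z.tolist() == pytest.approx([-0.866, -0.866, 0.866, 0.866], abs=1e-3)

    def test_exclude_zeros_rescores_remainder(self):
        df = pd.DataFrame({"diffusion_raw": [0.0, 0.0, 6.0, 8.0]})
        z = add_diffusion_z(df, exclude_zeros=True)["diffusion_z"]
        assert z.tolist() == pytest.approx([-0.707, 0.707], abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            add_diffusion_z(pd.DataFrame({"diffusion_raw": [3.0, 3.0, 3.0]}))


class TestSizeIntensityMixed:
    def test_size_counts_either_polarity_binary(self, flat_mask, map_factory):
        act = map_factory({(0, 0): 1.0, (1, 1): 100.0}, polarity="activation")
        deact = map_factory({(1, 1): 40.0, (2, 2): 7.0}, polarity="deactivation")
        # 3 distinct colored pixels over the mask's own denominator
        expected = 3 / flat_mask.n_body_pixels
        assert size_metric(act, deact, flat_mask) == pytest.approx(expected)

    def test_size_empty_and_bounds(self, map_factory, flat_mask):
        empty = map_factory({})
        assert size_metric(empty, empty, flat_mask) == 0.0
        body = {(r, c): 9.0 for r, c in np.argwhere(flat_mask.body)}
        full = map_factory(body)
        assert size_metric(full, full, flat_mask) == 1.0

    def test_intensity_sums_both_polarities(self, map_factory):
        act = map_factory({(0, 0): 50.0, (0, 1): 100.0}, polarity="activation")
        deact = map_factory({(5, 5): 25.0}, polarity="deactivation")
        assert intensity_metric(act, deact) == 175.0
        empty = map_factory({})
        assert intensity_metric(empty, empty) == 0.0

    def test_overall_intensity_averages_across_emotions(self):
        metrics = pd.DataFrame({
            "subject_id": ["s1"] * 12,
            "emotion": [f"e{i}" for i in range(12)],
            "arousal_class": ["high"] * 12,
            "size": [0.0] * 12,
            "intensity": [175.0] + [0.0] * 11,
            "mixed_pixels": [0] * 12,
        })
        overall = subject_summary(metrics)
        assert overall.loc["s1", "intensity"] == pytest.approx(175 / 12, abs=1e-3)

    def test_mixed_pixel_intersection(self, map_factory):
        act = map_factory({(0, 0): 5.0, (1, 1): 5.0}, polarity="activation")
        deact = map_factory({(1, 1): 5.0, (2, 2): 5.0}, polarity="deactivation")
        assert mixed_pixels(act, deact) == 1
        disjoint = map_factory({(9, 9): 5.0}, polarity="deactivation")
        assert mixed_pixels(act, disjoint) == 0
        same = map_factory({(0, 0): 9.0, (1, 1): 1.0}, polarity="deactivation")
        assert mixed_pixels(act, same) == 2

    def test_mixed_bounded_by_painted_counts(self, map_factory):
        rng = np.random.default_rng(0)
        pa = {(int(r), int(c)): 5.0 for r, c in rng.integers(0, 30, size=(40, 2))}
        pd_ = {(int(r), int(c)): 5.0 for r, c in rng.integers(0, 30, size=(25, 2))}
        act = map_factory(pa, polarity="activation")
        deact = map_factory(pd_, polarity="deactivation")
        assert mixed_pixels(act, deact) <= min(act.painted.sum(), deact.painted.sum())

    def test_smoothing_approximately_preserves_intensity(self, map_factory):
        act = map_factory({(18, 18): 80.0, (20, 22): 60.0}, polarity="activation")
        deact = map_factory({}, polarity="deactivation")
        raw = intensity_metric(act, deact)
        sm = intensity_metric(smooth_map(act, sigma=2), smooth_map(deact, sigma=2))
        assert sm == pytest.approx(raw, rel=1e-6)


class TestCongruency:
    def test_pure_congruent_activation(self, empty_pair_collection):
        coll = empty_pair_collection({
            ("s1", "happiness", "activation"): {(0, 0): 100.0, (0, 1): 100.0, (0, 2): 100.0},
        })
        scores = congruency_scores(coll).loc["s1"]
        assert scores["congruent_high_act"] == 300.0
        assert scores["congruent_low_deact"] == 0.0
        assert scores["incongruent_high_deact"] == 0.0
        assert scores["incongruent_low_act"] == 0.0

    def test_incongruent_low_arousal_activation(self, empty_pair_collection):
        coll = empty_pair_collection({
            ("s1", "sadness", "activation"): {(0, 0): 70.0, (0, 1): 50.0},
        })
        scores = congruency_scores(coll).loc["s1"]
        assert scores["incongruent_low_act"] == 120.0
        assert scores[["congruent_high_act", "congruent_low_deact",
                       "incongruent_high_deact"]].sum() == 0.0

    def test_excluded_emotions_do_not_count(self, empty_pair_collection):
        painted = {}
        for emotion in ("anxiety", "disgust", "shame", "jealousy", "neutral"):
            painted[("s1", emotion, "activation")] = {(0, 0): 80.0}
            painted[("s1", emotion, "deactivation")] = {(1, 1): 80.0}
        coll = empty_pair_collection(painted)
        assert congruency_scores(coll).loc["s1"].sum() == 0.0

    def test_polarity_totals_are_partitioned(self, small_mask):
        """Congruency columns + excluded/neutral paint = total paint by polarity."""
        from embody.core import EMOTIONS, arousal_class
        from embody.synth import SynthConfig, generate_collection

        coll = generate_collection(SynthConfig(n_subjects=3, seed=2), mask=small_mask)
        scores = congruency_scores(coll)
        for sid in coll.subject_ids:
            act_total = sum(coll.get(sid, e, "activation").grid.sum() for e in EMOTIONS)
            deact_total = sum(coll.get(sid, e, "deactivation").grid.sum() for e in EMOTIONS)
            rest = [e for e in EMOTIONS if arousal_class(e) in ("excluded", "neutral")]
            act_rest = sum(coll.get(sid, e, "activation").grid.sum() for e in rest)
            deact_rest = sum(coll.get(sid, e, "deactivation").grid.sum() for e in rest)
            row = scores.loc[sid]
            assert (row["congruent_high_act"] + row["incongruent_low_act"] + act_rest
                    == pytest.approx(act_total, rel=1e-9))
            assert (row["congruent_low_deact"] + row["incongruent_high_deact"] + deact_rest
                    == pytest.approx(deact_total, rel=1e-9))
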