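"""Generator contracts: weight model, silhouette rendering, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from cowseg.morphometry import mask_area
from cowseg.synthetic_scenes import (
    MorphTruth,
    SceneParams,
    generate_dataset,
    generate_feature_table,
    render_pair,
    sample_morph,
    true_weight,
)


class TestTrueWeight:
    def test_unit_areas_age_zero(self):
        # 520 * 1 * 1 * g(0) with g(0) = 0.45
        assert true_weight(1.0, 1.0, 0.0) == pytest.approx(234.0)

    def test_closed_form_value(self):
        # independent evaluation of the stated formula
        expected = 520.0 * 1.2 ** 0.9 * 0.8 ** 0.45 * (0.45 + 0.55 * (1 - np.exp(-1.8)))
        got = true_weight(1.2, 0.8, 18.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(503.8, abs=0.5)

    def test_noiseless_deterministic(self):
        assert true_weight(1.1, 0.7, 9.0) == true_weight(1.1, 0.7, 9.0)

    @pytest.mark.parametrize("a_top,a_back,age", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_domain_errors(self, a_top, a_back, age):
        with pytest.raises(ValueError):
            true_weight(a_top, a_back, age)

    def test_strictly_increasing_in_each_argument(self):
        tops = np.linspace(0.7, 1.6, 7)
        backs = np.linspace(0.4, 1.1, 7)
        ages = np.linspace(0.0, 24.0, 7)
        w_top = [true_weight(a, 0.7, 12) for a in tops]
        w_back = [true_weight(1.0, a, 12) for a in backs]
        w_age = [true_weight(1.0, 0.7, t) for t in ages]
        for seq in (w_top, w_back, w_age):
            assert np.all(np.diff(seq) > 0)

    def test_noise_draw_recorded_in_morph(self, desk_scene_params, rng):
        m = sample_morph(desk_scene_params, rng)
        noiseless = true_weight(m.A_top_true, m.A_back_true, m.age)
        # noise sigma is 15 lb: the draw must be plausible, not absent
        assert abs(m.weight - noiseless) < 6 * 15.0


class TestRenderPair:
    def test_area_recovery_and_binary_mask(self, rng):
        params = SceneParams(image_size=(96, 160), clutter_level=0.0, seed=1)
        m = sample_morph(params, rng)
        top, back = render_pair(m, params, rng)
        a = mask_area(top.mask, 1, top.meta["pixel_scale_m"])
        assert a == pytest.approx(m.A_top_true, rel=0.03)
        assert set(np.unique(top.mask)) <= {0, 1}
        assert set(np.unique(back.mask)) <= {0, 1}
        assert top.image.shape == (96, 160, 3)

    def test_seeded_determinism(self, desk_scene_params):
        outs = []
        for _ in range(2):
            r = np.random.default_rng(5)
            m = sample_morph(desk_scene_params, r)
            outs.append(render_pair(m, desk_scene_params, r))
        np.testing.assert_array_equal(outs[0][0].image, outs[1][0].image)
        np.testing.assert_array_equal(outs[0][1].mask, outs[1][1].mask)

    def test_median_area_error_over_many_scenes(self, desk_scene_params):
        r = np.random.default_rng(2)
        errs = []
        for _ in range(100):
            m = sample_morph(desk_scene_params, r)
            top, back = render_pair(m, desk_scene_params, r)
            for s, truth in ((top, m.A_top_true), (back, m.A_back_true)):
                a = mask_area(s.mask, 1, s.meta["pixel_scale_m"])
                errs.append(abs(a - truth) / truth)
        assert np.median(errs) <= 0.03


class TestGenerateDataset:
    def test_manifest_counts_and_csv(self, mini_dataset):
        assert len(mini_dataset.by_view("top")) == 24
        assert len(mini_dataset.by_view("back")) == 24
        df = pd.read_csv(f"{mini_dataset.root}/metadata.csv")
        assert list(df.columns) == ["id", "view", "age_months", "cam_height_m",
                                    "cam_distance_m", "area_true_m2", "weight_lb"]
        assert (df.groupby("view").size() == 24).all()

    def test_regeneration_byte_identical(self, tmp_path):
        params = SceneParams(image_size=(48, 80), clutter_level=0.3, seed=13)
        generate_dataset(params, 3, tmp_path / "a")
        generate_dataset(params, 3, tmp_path / "b")
        for name in ("metadata.csv", "checksums.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_paper_scale_row_count(self, tmp_path):
        params = SceneParams(image_size=(48, 80), clutter_level=0.2, seed=3)
        man = generate_dataset(params, 550, tmp_path / "full")
        df = pd.read_csv(tmp_path / "full" / "metadata.csv")
        assert (df.groupby("view").size() == 550).all()
        assert len(man) == 1100


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(age_range=(10, 4))
        with pytest.raises(ValueError):
            SceneParams(clutter_level=1.5)
        with pytest.raises(ValueError):
            MorphTruth(A_top_true=-1, A_back_true=1, age=2, weight=300,
                       pixel_scale_top=0.01, pixel_scale_back=0.01)

    def test_feature_table_shape_and_determinism(self):
        params = SceneParams(seed=4)
        df1 = generate_feature_table(params, 50)
        df2 = generate_feature_table(params, 50)
        pd.testing.assert_frame_equal(df1, df2)
        assert list(df1.columns) == ["id", "A_t", "A_b", "H_t", "H_b", "age", "weight"]
        assert df1["weight"].between(100, 1000).all()
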