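import numpy as np
import pandas as pd
import pytest

from epikinet import (
    LabelAtlas,
    VOISelection,
    extract_static_ac,
    extract_voi_tacs,
    make_frame_schedule,
    pair_regions,
)
from epikinet.regions import AtlasConsistencyError
from epikinet.synthetic_cohort import make_synthetic_atlas, paint_dynamic_volume, paint_static_volume


@pytest.fixture()
def atlas():
    return make_synthetic_atlas(n_pairs=6, shape=(20, 20, 10))


@pytest.fixture()
def small_schedule():
    return make_frame_schedule([(5, 60)])


class TestLabelAtlas:
    def test_homolog_is_involution(self, atlas):
        for label_id in atlas.lut["label_id"]:
            assert atlas.homolog(atlas.homolog(int(label_id))) == int(label_id)

    def test_unknown_labels_rejected(self):
        labels = np.ones((4, 4, 4), dtype=np.int32) * 99
        lut = pd.DataFrame([{"label_id": 1, "name": "a", "hemisphere": "left",
                             "homolog_id": 1}])
        with pytest.raises(AtlasConsistencyError):
            LabelAtlas(labels=labels, lut=lut)

    def test_broken_involution_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 1
        lut = pd.DataFrame([
            {"label_id": 1, "name": "a", "hemisphere": "left", "homolog_id": 2},
            {"label_id": 2, "name": "b", "hemisphere": "right", "homolog_id": 1},
            {"label_id": 3, "name": "c", "hemisphere": "left", "homolog_id": 1},
        ])
        with pytest.raises(AtlasConsistencyError):
            LabelAtlas(labels=labels, lut=lut)

    def test_nifti_and_tsv_round_trip(self, atlas, tmp_path):
        nib = pytest.importorskip("nibabel")
        img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4))
        nib.save(img, tmp_path / "atlas.nii")
        atlas.lut.to_csv(tmp_path / "atlas.tsv", sep="\t", index=False)
        loaded = LabelAtlas.from_files(tmp_path / "atlas.nii", tmp_path / "atlas.tsv")
        np.testing.assert_array_equal(loaded.labels, atlas.labels)


class TestExtraction:
    def test_uniform_volume(self, atlas, small_schedule):
        vol = np.full(atlas.labels.shape + (5,), 3.25)
        tacs = extract_voi_tacs(vol, atlas, [1, 7], small_schedule)
        for tac in tacs.values():
            np.testing.assert_allclose(tac.values, 3.25)

    def test_painter_round_trip_is_exact(self, atlas, small_schedule):
        rng = np.random.default_rng(3)
        curves = {int(i): rng.uniform(0, 30, 5) for i in atlas.lut["label_id"]}
        vol = paint_dynamic_volume(atlas, curves)
        tacs = extract_voi_tacs(vol, atlas, list(curves), small_schedule)
        for label_id, curve in curves.items():
            # voxel means of identically painted values round only in the
            # last ulps of the accumulating sum
            np.testing.assert_allclose(tacs[str(label_id)].values, curve, rtol=1e-13)

    def test_region_mean_arithmetic(self, small_schedule):
        labels = np.zeros((3, 1, 1), dtype=np.int32)
        labels[:, 0, 0] = 5
        lut = pd.DataFrame([{"label_id": 5, "name": "r", "hemisphere": "left",
                             "homolog_id": 5}])
        atlas = LabelAtlas(labels=labels, lut=lut)
        vol = np.zeros((3, 1, 1, 1))
        vol[:, 0, 0, 0] = [1.0, 2.0, 3.0]
        sched = make_frame_schedule([(1, 60)])
        tacs = extract_voi_tacs(vol, atlas, [5], sched)
        assert tacs["5"].values[0] == 2.0

    def test_static_means(self, atlas):
        vol = paint_static_volume(atlas, {1: 5.0, 7: 9.0})
        out = extract_static_ac(vol, atlas, [1, 7])
        assert out == {"1": 5.0, "7": 9.0}

    def test_static_mean_of_three_voxels(self):
        labels = np.zeros((3, 1, 1), dtype=np.int32)
        labels[:, 0, 0] = 2
        lut = pd.DataFrame([{"label_id": 2, "name": "r", "hemisphere": "left",
                             "homolog_id": 2}])
        atlas = LabelAtlas(labels=labels, lut=lut)
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [2.0, 4.0, 9.0]
        assert extract_static_ac(vol, atlas, [2])["2"] == 5.0

    def test_merged_voi_pools_with_volume_weights(self, atlas, small_schedule):
        vol = paint_dynamic_volume(atlas, {1: np.full(5, 2.0), 2: np.full(5, 8.0)})
        n1 = (atlas.labels == 1).sum()
        n2 = (atlas.labels == 2).sum()
        pooled = extract_voi_tacs(vol, atlas, [(1, 2)], small_schedule)["1+2"]
        expected = (2.0 * n1 + 8.0 * n2) / (n1 + n2)
        np.testing.assert_allclose(pooled.values, expected)

    def test_linearity_in_intensity(self, atlas, small_schedule):
        rng = np.random.default_rng(5)
        vol = rng.uniform(0, 10, atlas.labels.shape + (5,))
        base = extract_voi_tacs(vol, atlas, [3], small_schedule)["3"].values
        scaled = extract_voi_tacs(2.5 * vol, atlas, [3], small_schedule)["3"].values
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-12)

    def test_grid_mismatch_and_empty_region_errors(self, atlas, small_schedule):
        with pytest.raises(ValueError):
            extract_voi_tacs(np.zeros((5, 5, 5, 5)), atlas, [1], small_schedule)
        vol = np.zeros(atlas.labels.shape + (5,))
        with pytest.raises(AtlasConsistencyError):
            extract_voi_tacs(vol, atlas, [999], small_schedule)


class TestPairing:
    def test_focus_side_pairs_with_homolog(self, atlas):
        sel = VOISelection(epileptogenic=(1,), reference=(2, 3), focus_side="left")
        pairs = pair_regions(atlas, sel)
        epi = [p for p in pairs if p["region_class"] == "epileptogenic"][0]
        assert (epi["ipsi"], epi["contra"]) == (1, 7)

    def test_six_region_selection_yields_distinct_pairs(self, atlas):
        sel = VOISelection(epileptogenic=(1,), reference=(2, 3, 4, 5, 6),
                           focus_side="right")
        pairs = pair_regions(atlas, sel)
        assert len(pairs) == 6
        assert len({(p["ipsi"], p["contra"]) for p in pairs}) == 6

    def test_mirrored_selection_gives_mirror_pairs(self, atlas):
        left = pair_regions(atlas, VOISelection(epileptogenic=(1,), reference=(),
                                                focus_side="left"))[0]
        right = pair_regions(atlas, VOISelection(epileptogenic=(7,), reference=(),
                                                 focus_side="right"))[0]
        assert (left["ipsi"], left["contra"]) == (right["contra"], right["ipsi"])

    def test_overlapping_selection_rejected(self):
        with pytest.raises(ValueError):
            VOISelection(epileptogenic=(1,), reference=(1, 2), focus_side="left")
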