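import numpy as np
import pandas as pd
import pytest

from papscreen import (CellClass, CellObject, ContractError, DataError,
                       GrayImage, binary_label, extract_features,
                       read_feature_table, write_feature_table)
from papscreen.cell_features import FEATURE_NAMES, feature_table
from papscreen.synthetic_data import (SceneRecipe, _ellipse_mask, ClassStats,
                                      herlev_class_stats, render_scene)


@pytest.fixture()
def circle_cell():
    """Uniform nucleus disk (r=10, intensity 60) centred in a cytoplasm disk
    (r=50, intensity 140)."""
    d = 110
    nuc = _ellipse_mask(d, d, d / 2, d / 2, 10, 10, 0)
    cyt = _ellipse_mask(d, d, d / 2, d / 2, 50, 50, 0) & ~nuc
    px = np.full((d, d), 200.0)
    px[cyt] = 140.0
    px[nuc] = 60.0
    obj = CellObject(object_id=0, nucleus_mask=nuc, cytoplasm_mask=cyt)
    return GrayImage(px), obj


def test_circle_nucleus_measurements(circle_cell):
    img, obj = circle_cell
    f = extract_features(img, obj)
    assert f["nucleus_area"] == pytest.approx(np.pi * 100, abs=4)
    assert f["nucleus_eccentricity"] <= 0.1
    assert f["nucleus_elongation"] >= 0.95
    assert f["nucleus_mean"] == 60.0
    assert f["nucleus_variance"] == 0.0
    assert f["nucleus_entropy"] == 0.0
    assert f["nucleus_energy"] == 1.0
    assert f["nucleus_relative_position"] == pytest.approx(0.0, abs=0.02)
    assert set(f) == set(FEATURE_NAMES)


def test_feature_invariants_on_circle(circle_cell):
    img, obj = circle_cell
    f = extract_features(img, obj)
    assert f["nucleus_shortest_diameter"] <= f["nucleus_longest_diameter"]
    assert f["cytoplasm_shortest_diameter"] <= f["cytoplasm_longest_diameter"]
    assert f["nucleus_roundness"] <= 1.0
    assert 0 < f["nucleus_solidity"] <= 1.0
    assert 0 <= f["nc_ratio"] <= 1.0


def test_histogram_features_are_permutation_invariant(rng, circle_cell):
    img, obj = circle_cell
    px = img.pixels.copy()
    vals = px[obj.nucleus_mask]
    px[obj.nucleus_mask] = vals + rng.normal(0, 10, len(vals))
    f1 = extract_features(GrayImage(px), obj)
    # shuffle intensities within the nucleus mask
    px2 = px.copy()
    px2[obj.nucleus_mask] = rng.permutation(px[obj.nucleus_mask])
    f2 = extract_features(GrayImage(px2), obj)
    for name in ("nucleus_mean", "nucleus_std", "nucleus_variance",
                 "nucleus_entropy", "nucleus_energy", "nucleus_smoothness"):
        assert f1[name] == pytest.approx(f2[name], rel=1e-9)


def test_missing_cytoplasm_sentinel_and_nc_ratio(circle_cell):
    img, obj = circle_cell
    lone = CellObject(object_id=1, nucleus_mask=obj.nucleus_mask)
    f = extract_features(img, lone)
    assert f["nc_ratio"] == 1.0
    assert np.isnan(f["cytoplasm_area"])
    assert np.isnan(f["nucleus_relative_position"])


def test_empty_nucleus_mask_rejected(circle_cell):
    img, _ = circle_cell
    empty = CellObject(object_id=2, nucleus_mask=np.zeros((5, 5), bool))
    with pytest.raises(ContractError):
        extract_features(img, empty)


def _render_single_cell(cls, seed=0):
    stats = herlev_class_stats()
    tight = ClassStats(
        stats={cls: {k: (v[0], v[1] / 4) for k, v in stats.stats[cls].items()}},
        texture_sigma={cls: stats.texture_sigma[cls]})
    scene = render_scene(SceneRecipe(cells_per_class={cls: 1}, debris={},
                                     scale=0.5, seed=seed), tight)
    rec = scene.cells()[0]
    obj = CellObject(object_id=0, nucleus_mask=rec.nucleus_mask,
                     cytoplasm_mask=rec.cytoplasm_mask, bbox=rec.bbox,
                     linear_scale=scene.linear_scale)
    from papscreen import rgb_to_gray
    return rgb_to_gray(scene.image), obj


def test_superficial_render_nc_ratio_in_reference_band():
    img, obj = _render_single_cell(CellClass.SUPERFICIAL)
    f = extract_features(img, obj)
    assert 0.0 <= f["nc_ratio"] <= 0.02


def test_nc_ratio_ordering_across_classes():
    """Extracted N/C means reproduce the reference ordering
    superficial < intermediate < columnar < carcinoma in situ."""
    means = []
    for cls in (CellClass.SUPERFICIAL, CellClass.INTERMEDIATE,
                CellClass.COLUMNAR, CellClass.CARCINOMA_IN_SITU):
        vals = [extract_features(*_render_single_cell(cls, seed=s))["nc_ratio"]
                for s in range(3)]
        means.append(np.mean(vals))
    assert means == sorted(means)


def test_binary_label_mapping_total():
    expected = {
        CellClass.SUPERFICIAL: "NORMAL", CellClass.INTERMEDIATE: "NORMAL",
        CellClass.COLUMNAR: "NORMAL", CellClass.MILD: "ABNORMAL",
        CellClass.MODERATE: "ABNORMAL", CellClass.SEVERE: "ABNORMAL",
        CellClass.CARCINOMA_IN_SITU: "ABNORMAL",
    }
    assert {c: binary_label(c) for c in CellClass} == expected


def test_feature_csv_round_trip(tmp_path, circle_cell):
    img, obj = circle_cell
    df = feature_table([extract_features(img, obj)], [CellClass.SUPERFICIAL])
    path = tmp_path / "cells.csv"
    write_feature_table(df, path)
    back = read_feature_table(path)
    pd.testing.assert_frame_equal(df, back)


def test_feature_csv_header_validated(tmp_path):
    bad = pd.DataFrame({"foo": [1.0], "bar": [2.0]})
    path = tmp_path / "bad.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(DataError):
        read_feature_table(path)
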