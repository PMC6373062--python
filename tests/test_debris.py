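import math

import numpy as np
import pytest

from papscreen import (CellObject, ContractError, DebrisConfig, GrayImage,
                       compactness, label_objects, reject_debris, shape_gate,
                       size_gate, texture_gate)
from papscreen.debris_rejection import (RejectionStage, mask_perimeter,
                                        otsu_split)
from papscreen.pixel_segmentation import LabelMap, SceneClass
from papscreen.synthetic_data import _ellipse_mask, debris_fixture_scene
from papscreen import rgb_to_gray


def one_hot_map(labels):
    probs = np.zeros(labels.shape + (4,))
    for c in range(4):
        probs[..., c] = labels == c
    return LabelMap(labels=labels.astype(int), probabilities=probs)


def obj_with(area=1000.0, perimeter=100.0, compactness_score=float("nan"),
             texture=float("nan")):
    o = CellObject(object_id=0, nucleus_mask=np.ones((3, 3), bool),
                   area=area, perimeter=perimeter)
    o.compactness_score = compactness_score
    o.texture_score = texture
    return o


# ---------------------------------------------------------------------------
# object labelling and geometry

def test_two_disjoint_nuclei_give_two_objects():
    lab = np.full((40, 40), int(SceneClass.BACKGROUND))
    lab[5:10, 5:10] = int(SceneClass.NUCLEUS)
    lab[25:32, 25:32] = int(SceneClass.NUCLEUS)
    objs = label_objects(one_hot_map(lab))
    assert len(objs) == 2


def test_all_background_gives_no_objects():
    lab = np.full((20, 20), int(SceneClass.BACKGROUND))
    assert label_objects(one_hot_map(lab)) == []


def test_square_area_and_perimeter():
    lab = np.full((20, 20), int(SceneClass.BACKGROUND))
    lab[4:14, 4:14] = int(SceneClass.NUCLEUS)
    obj, = label_objects(one_hot_map(lab))
    assert obj.area == 100
    assert 36 <= obj.perimeter <= 40


def test_cytoplasm_attachment_and_unit_scaling():
    lab = np.full((40, 40), int(SceneClass.BACKGROUND))
    lab[15:25, 15:25] = int(SceneClass.CYTOPLASM)
    lab[18:22, 18:22] = int(SceneClass.NUCLEUS)
    obj, = label_objects(one_hot_map(lab), linear_scale=2.0)
    assert obj.cytoplasm_mask is not None
    assert obj.area == 100 * 4          # 10x10 block, unit factor 2^2
    assert obj.nucleus_area == 16 * 4


# ---------------------------------------------------------------------------
# size gate (inclusive bounds)

@pytest.mark.parametrize("area, retained", [
    (624, False), (625, True), (40_000, True),
    (85_267, True), (85_268, False),
])
def test_size_gate_boundaries(area, retained):
    o = obj_with(area=area)
    assert size_gate(o, DebrisConfig()) is retained
    if not retained:
        assert o.rejection_stage == RejectionStage.SIZE


# ---------------------------------------------------------------------------
# shape gate and compactness

def test_compactness_of_ideal_circle_is_one():
    o = obj_with(area=math.pi * 100.0, perimeter=2 * math.pi * 10.0)
    assert compactness(o) == pytest.approx(1.0)
    assert o.p2a_raw == pytest.approx(4 * math.pi)


def test_compactness_of_continuous_square():
    o = obj_with(area=25.0, perimeter=20.0)
    assert compactness(o) == pytest.approx(math.pi / 4, rel=1e-6)


def test_thin_line_compactness_below_band():
    mask = np.zeros((5, 30), bool)
    mask[2, 2:27] = True
    p = mask_perimeter(mask)
    c = 4 * math.pi * 25 / p**2
    assert c < 0.15


def test_single_pixel_object_is_degenerate():
    o = obj_with(area=1.0, perimeter=0.0)
    with pytest.raises(ContractError):
        compactness(o)


@pytest.mark.parametrize("c, retained", [
    (0.98, False), (0.5, True), (0.14, False), (0.15, True), (0.97, True),
])
def test_shape_gate_band(c, retained):
    o = obj_with(compactness_score=c)
    assert shape_gate(o, DebrisConfig()) is retained
    if not retained:
        assert o.rejection_stage == RejectionStage.SHAPE


def test_compactness_scale_invariant_for_large_disks():
    values = []
    for r in (20, 40):
        d = 2 * r + 5
        mask = _ellipse_mask(d, d, d / 2, d / 2, r, r, 0.0)
        p = mask_perimeter(mask)
        values.append(4 * math.pi * mask.sum() / p**2)
    assert abs(values[1] - values[0]) / values[0] < 0.02


# ---------------------------------------------------------------------------
# texture gate

def test_texture_gate_fixed_infinite_threshold_retains_all():
    cfg = DebrisConfig(texture_threshold=float("inf"))
    objs = [obj_with(texture=t) for t in (0.5, 3.0, 100.0)]
    assert texture_gate(objs, cfg) == objs


def test_texture_gate_empty_list():
    assert texture_gate([], DebrisConfig()) == []


def test_texture_gate_auto_separates_outlier():
    objs = [obj_with(texture=t) for t in (1.0, 1.1, 0.9, 1.05, 9.0)]
    retained = texture_gate(objs, DebrisConfig())
    assert len(retained) == 4
    assert objs[-1].rejection_stage == RejectionStage.TEXTURE


def test_texture_gate_auto_homogeneous_batch_retains_all():
    objs = [obj_with(texture=t) for t in (1.0, 1.02, 0.98, 1.05, 0.96)]
    assert len(texture_gate(objs, DebrisConfig())) == 5


def test_texture_gate_auto_single_object_warns_and_retains():
    objs = [obj_with(texture=1.0)]
    with pytest.warns(UserWarning):
        retained = texture_gate(objs, DebrisConfig())
    assert retained == objs


def test_otsu_split_separates_two_populations():
    x = np.array([0.85, 0.88, 0.9, 0.92, 0.95, 3.87])
    thr = otsu_split(x)
    assert 0.95 < thr < 3.87


# ---------------------------------------------------------------------------
# full three-phase rejection

def test_fixture_trips_each_gate_once():
    """5 nuclei + 3 sub-minimum specks + 1 fiber + 1 blotchy blob."""
    scene, cfg = debris_fixture_scene(seed=0)
    gray = rgb_to_gray(scene.image)
    retained, report = reject_debris(gray, scene.segmentation_view(), cfg,
                                     linear_scale=scene.linear_scale)
    assert len(retained) == 5
    assert report.counts == {RejectionStage.SIZE: 3, RejectionStage.SHAPE: 1,
                             RejectionStage.TEXTURE: 1}


def test_rejection_is_sequential_and_conserves_objects():
    scene, cfg = debris_fixture_scene(seed=3)
    gray = rgb_to_gray(scene.image)
    retained, report = reject_debris(gray, scene.segmentation_view(), cfg,
                                     linear_scale=scene.linear_scale)
    # partition: retained + rejected == all candidates
    n_rejected = sum(report.counts.values())
    assert len(retained) + n_rejected == len(report.objects)
    # no object carries a later-stage rejection while violating the size band
    for o in report.objects:
        if o.rejection_stage in (RejectionStage.SHAPE, RejectionStage.TEXTURE):
            assert cfg.area_min <= o.area <= cfg.area_max
        if o.rejection_stage == RejectionStage.TEXTURE:
            assert cfg.compactness_low <= o.compactness_score <= cfg.compactness_high


def test_empty_label_map_gives_empty_output():
    lab = np.full((30, 30), int(SceneClass.BACKGROUND))
    gray = GrayImage(np.full((30, 30), 200.0))
    retained, report = reject_debris(gray, one_hot_map(lab))
    assert retained == [] and report.objects == []
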