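import numpy as np
import pytest

from papscreen import (AnnotationSet, ConfigError, ContractError,
                       FilterBankConfig, GrayImage, build_pixel_features,
                       segment_scene, train_pixel_classifier, zsi)
from papscreen.pixel_segmentation import SceneClass


# ---------------------------------------------------------------------------
# filter bank

def test_constant_image_edge_planes_zero():
    stack = build_pixel_features(GrayImage(np.full((48, 48), 77.0)))
    for i, name in enumerate(stack.feature_names):
        if name.startswith(("sobel", "hessian", "gabor")):
            assert np.allclose(stack.data[..., i], 0, atol=1e-5), name


def test_vertical_step_sobel_maximal_at_step():
    px = np.zeros((32, 32))
    px[:, 16:] = 200.0
    stack = build_pixel_features(GrayImage(px))
    sobel_plane = stack.data[..., stack.feature_names.index("sobel")]
    col_strength = sobel_plane[8:-8].mean(axis=0)
    assert col_strength.argmax() in (15, 16)


def test_rank_planes_match_brute_force_on_crop(rng):
    px = rng.uniform(0, 255, (40, 40))
    bank = FilterBankConfig()
    stack = build_pixel_features(GrayImage(px), bank)
    r = 2
    size = 2 * r + 1
    # interior crop where windows are fully inside the image
    for stat, fn in [("mean", np.mean), ("variance", np.var),
                     ("median", np.median), ("max", np.max), ("min", np.min)]:
        plane = stack.data[..., stack.feature_names.index(f"{stat}_r{r}")]
        for i in range(12, 28):
            for j in range(12, 28):
                window = px[i - r:i + r + 1, j - r:j + r + 1]
                assert plane[i, j] == pytest.approx(fn(window), rel=1e-5)


def test_raw_intensity_plane_passthrough(rng):
    px = rng.uniform(0, 255, (16, 16))
    stack = build_pixel_features(GrayImage(px))
    assert np.allclose(stack.data[..., 0], px, atol=1e-4)


def test_empty_image_rejected():
    from papscreen._errors import DataError
    with pytest.raises((DataError, ValueError)):
        build_pixel_features(GrayImage(np.zeros((1, 1))[:0, :0]))


# ---------------------------------------------------------------------------
# training and inference

def _scribbles(scene, n, seed):
    """Annotation-style scribbles: drawn through region interiors (1-px
    erosion), the way a human marks representative pixels."""
    from scipy import ndimage as ndi
    rng = np.random.default_rng(seed)
    scrib = []
    for c in SceneClass:
        mask = scene.truth.labels == int(c)
        eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool))
        coords = np.argwhere(eroded if eroded.any() else mask)
        pick = coords[rng.choice(len(coords), size=min(n, len(coords)),
                                 replace=False)]
        scrib.append((pick, c))
    return AnnotationSet(scrib)


def _disk_scene(seed):
    """Simple scene: dark disks (nuclei) inside mid-gray annuli (cytoplasm)
    on a bright field, plus small black specks (debris)."""
    rng = np.random.default_rng(seed)
    px = np.full((200, 200), 220.0)
    lab = np.full((200, 200), int(SceneClass.BACKGROUND))
    yy, xx = np.mgrid[0:200, 0:200]
    for cy, cx in [(50, 50), (50, 150), (150, 50), (150, 150)]:
        cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= 35**2
        nuc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 12**2
        px[cell] = 140.0
        px[nuc] = 60.0
        lab[cell] = int(SceneClass.CYTOPLASM)
        lab[nuc] = int(SceneClass.NUCLEUS)
    for cy, cx in [(100, 20), (20, 100), (180, 100)]:
        speck = (yy - cy) ** 2 + (xx - cx) ** 2 <= 3**2
        px[speck] = 10.0
        lab[speck] = int(SceneClass.DEBRIS)
    px += rng.normal(0, 3, px.shape)
    return GrayImage(np.clip(px, 0, 255)), lab


def _scene_scribbles(lab, n, seed):
    rng = np.random.default_rng(seed)
    scrib = []
    for c in SceneClass:
        coords = np.argwhere(lab == int(c))
        pick = coords[rng.choice(len(coords), size=min(n, len(coords)),
                                 replace=False)]
        scrib.append((pick, c))
    return AnnotationSet(scrib)


def test_heldout_annotated_pixel_accuracy():
    """50 scribbled pixels per class on one disk/annulus/speck scene train a
    classifier that labels held-out annotated pixels of a second scene with
    >= 95% accuracy."""
    img_a, lab_a = _disk_scene(0)
    img_b, lab_b = _disk_scene(1)
    stack_a = build_pixel_features(img_a)
    clf = train_pixel_classifier([stack_a], [_scene_scribbles(lab_a, 50, 2)],
                                 seed=0, n_trees=100)
    lm = segment_scene(img_b, clf)
    held = _scene_scribbles(lab_b, 50, 3)
    correct = total = 0
    for coords, cls_ in held.scribbles:
        pred = lm.labels[coords[:, 0], coords[:, 1]]
        correct += int((pred == int(cls_)).sum())
        total += len(coords)
    assert correct / total >= 0.95
    # training-set annotated pixels do at least as well (sanity)
    lm_a = segment_scene(img_a, clf, features=stack_a)
    tr_correct = tr_total = 0
    for coords, cls_ in _scene_scribbles(lab_a, 50, 2).scribbles:
        pred = lm_a.labels[coords[:, 0], coords[:, 1]]
        tr_correct += int((pred == int(cls_)).sum())
        tr_total += len(coords)
    assert tr_correct / tr_total >= correct / total - 0.05


def test_missing_class_raises_naming_it(seg_fixture):
    train, _, clf, _, _ = seg_fixture
    gray = None
    stack = build_pixel_features(
        GrayImage(np.full((32, 32), 120.0)))
    ann = AnnotationSet([(np.array([[1, 1], [2, 2]]), SceneClass.NUCLEUS)])
    with pytest.raises(ContractError, match="CYTOPLASM|BACKGROUND|DEBRIS"):
        train_pixel_classifier([stack], [ann], seed=0, n_trees=5)


def test_training_is_deterministic(rng):
    px = rng.uniform(0, 255, (48, 48))
    px[10:20, 10:20] = 30.0
    img = GrayImage(px)
    stack = build_pixel_features(img)
    coords = {
        SceneClass.NUCLEUS: np.argwhere(px < 60)[:30],
        SceneClass.CYTOPLASM: np.argwhere((px >= 60) & (px < 120))[:30],
        SceneClass.BACKGROUND: np.argwhere((px >= 120) & (px < 200))[:30],
        SceneClass.DEBRIS: np.argwhere(px >= 200)[:30],
    }
    ann = AnnotationSet([(v, k) for k, v in coords.items()])
    a = train_pixel_classifier([stack], [ann], seed=3, n_trees=20)
    b = train_pixel_classifier([stack], [ann], seed=3, n_trees=20)
    la = segment_scene(img, a, features=stack)
    lb = segment_scene(img, b, features=stack)
    assert np.array_equal(la.labels, lb.labels)
    assert np.allclose(la.probabilities, lb.probabilities)


def test_probabilities_normalized_and_labels_argmax(seg_fixture):
    *_, label_map, _ = seg_fixture
    sums = label_map.probabilities.sum(axis=-1)
    assert np.abs(sums - 1).max() <= 1e-9
    assert np.array_equal(label_map.labels,
                          np.argmax(label_map.probabilities, axis=-1))


def test_all_background_image_labelled_background(seg_fixture):
    _, _, clf, _, _ = seg_fixture
    rng = np.random.default_rng(4)
    px = np.clip(220 + 3 * rng.standard_normal((96, 96)), 0, 255)
    lm = segment_scene(GrayImage(px), clf)
    assert (lm.labels == int(SceneClass.BACKGROUND)).mean() >= 0.99


def test_filter_bank_mismatch_is_config_error(seg_fixture):
    _, test, clf, _, gray = seg_fixture
    other = FilterBankConfig(rank_radii=(2,))
    stack = build_pixel_features(gray, other)
    with pytest.raises(ConfigError):
        segment_scene(gray, clf, features=stack)


# ---------------------------------------------------------------------------
# ZSI

def test_zsi_values_and_symmetry(rng):
    a = np.zeros((20, 20), bool)
    a[:10] = True
    assert zsi(a, a) == 1.0
    b = ~a
    assert zsi(a, b) == 0.0
    # |A|=|B|=100, |A & B|=50
    c = np.zeros((20, 20), bool)
    c[5:15] = True
    assert zsi(a, c) == pytest.approx(0.5)
    r1 = rng.random((20, 20)) > 0.5
    r2 = rng.random((20, 20)) > 0.5
    assert zsi(r1, r2) == zsi(r2, r1)


def test_zsi_empty_masks_error():
    empty = np.zeros((5, 5), bool)
    with pytest.raises(ContractError):
        zsi(empty, empty)
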