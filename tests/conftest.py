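"""Shared fixtures: rendered scenes and trained models reused across tests.

Everything is generated programmatically with fixed seeds; the expensive
segmentation fixture is session-scoped.
"""

import numpy as np
import pytest

from papscreen import (
    SceneRecipe,
    build_pixel_features,
    clahe,
    gen_feature_table,
    render_scene,
    rgb_to_gray,
    segment_scene,
    train_pixel_classifier,
)
from papscreen.cell_features import CellClass
from papscreen.pipeline import scribbles_from_truth


@pytest.fixture(scope="session")
def seg_fixture():
    """Two small rendered scenes plus a pixel classifier trained on the
    first: (train_scene, test_scene, classifier, test LabelMap, gray)."""
    train = render_scene(SceneRecipe(
        cells_per_class={CellClass.SUPERFICIAL: 1, CellClass.COLUMNAR: 2,
                         CellClass.SEVERE: 2, CellClass.MODERATE: 1},
        debris={"speck": 2, "noisy_blob": 1}, scale=0.4, seed=101))
    test = render_scene(SceneRecipe(
        cells_per_class={CellClass.SUPERFICIAL: 1, CellClass.COLUMNAR: 2,
                         CellClass.SEVERE: 2, CellClass.MODERATE: 1},
        debris={"speck": 2, "noisy_blob": 1}, scale=0.4, seed=102))
    gray_train = clahe(rgb_to_gray(train.image))
    gray_test = clahe(rgb_to_gray(test.image))
    stack = build_pixel_features(gray_train)
    ann = scribbles_from_truth(train, n_per_class=600, seed=0)
    clf = train_pixel_classifier([stack], [ann], seed=0)
    label_map = segment_scene(gray_test, clf)
    return train, test, clf, label_map, gray_test


@pytest.fixture(scope="session")
def herlev_table():
    """Labelled synthetic feature table at the reference statistics."""
    return gen_feature_table(n_per_class=100, seed=1)


@pytest.fixture(scope="session")
def herlev_table_test():
    return gen_feature_table(n_per_class=50, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
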