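"""Pipeline orchestration: enhance -> segment -> reject debris -> extract ->
classify -> diagnose.

The stage order is fixed; later stages only consume objects earlier stages
retained.  ``train_models_on_scene`` builds both models (pixel classifier and
cell classifier) from a rendered training scene by running the same
measurement pipeline that inference uses, so training and test features share
every measurement convention; cell labels come from matching detected objects
back to the scene manifest.  ``synthetic_end_to_end`` packages the whole
benchmark: train on one seeded scene, screen a second, and score the binary
per-cell decisions against the manifest truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ContractError
from .cell_features import (CellClass, LABEL_COLUMN, binary_label,
                            extract_features, feature_table)
from .debris_rejection import (AUTO, DebrisConfig, RejectionReport,
                               reject_debris)
from .evaluation import confusion, metrics, roc_curve
from .fcm_classifier import (FCMClassifier, FCMClassifierConfig, SlideDiagnosis,
                             screen_slide, table_to_xy)
from .feature_selection import REFERENCE_SELECTED_FEATURES
from .imaging import EnhanceConfig, GrayImage, RGBImage, clahe, rgb_to_gray
from .pixel_segmentation import (AnnotationSet, FilterBankConfig, LabelMap,
                                 PixelClassifier, SceneClass,
                                 build_pixel_features, segment_scene,
                                 train_pixel_classifier)
from .synthetic_data import (RenderedScene, SceneRecipe, match_cells_to_objects,
                             render_scene)

#: fallback feature set for cells whose cytoplasm was not recovered: all
#: nucleus measurements plus the N/C ratio (1 by definition when CA = 0)
NUCLEUS_ONLY_FEATURES: list[str] = [
    n for n in REFERENCE_SELECTED_FEATURES
    if n.startswith("nucleus_") and n != "nucleus_relative_position"
] + ["nc_ratio"]


@dataclass
class PipelineModels:
    """Everything inference needs: the two trained models plus stage configs."""

    pixel_classifier: PixelClassifier
    cell_classifier: FCMClassifier
    debris_config: DebrisConfig
    enhance_config: EnhanceConfig = field(default_factory=EnhanceConfig)
    feature_subset: list[str] = field(default_factory=lambda:
                                      list(REFERENCE_SELECTED_FEATURES))
    texture_reference_scores: np.ndarray | None = None
    smooth_sigma: float = 1.0
    merge_nuclei: bool = True
    close_radius: int = 2
    nucleus_classifier: FCMClassifier | None = None
    nucleus_subset: list[str] = field(default_factory=lambda:
                                      list(NUCLEUS_ONLY_FEATURES))


@dataclass
class SlideResult:
    """Outcome of screening one image."""

    label_map: LabelMap
    report: RejectionReport
    features: pd.DataFrame
    cell_objects: list
    predicted_classes: np.ndarray
    posteriors: np.ndarray
    binary: list[str]
    diagnosis: SlideDiagnosis
    stage_log: list[dict] = field(default_factory=list)


def predict_cells(models: PipelineModels, df: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify a table of extracted features.

    Rows with complete features go through the full classifier; rows whose
    cytoplasm features are missing fall back to the nucleus-only classifier.
    Returns (class codes, class posteriors, abnormal scores); code -1 marks
    cells no model could classify.
    """
    n = len(df)
    n_classes = len(models.cell_classifier.defuzz.classes)
    preds = np.full(n, -1, dtype=int)
    post = np.zeros((n, n_classes))
    score = np.zeros(n)
    full = df[models.feature_subset].to_numpy(dtype=float)
    ok = np.isfinite(full).all(axis=1)
    if ok.any():
        preds[ok] = models.cell_classifier.predict(full[ok])
        post[ok] = models.cell_classifier.predict_posteriors(full[ok])
        score[ok] = models.cell_classifier.abnormal_score(full[ok])
    if models.nucleus_classifier is not None and (~ok).any():
        nuc = df[models.nucleus_subset].to_numpy(dtype=float)
        fb = ~ok & np.isfinite(nuc).all(axis=1)
        if fb.any():
            preds[fb] = models.nucleus_classifier.predict(nuc[fb])
            score[fb] = models.nucleus_classifier.abnormal_score(nuc[fb])
            nc_post = models.nucleus_classifier.predict_posteriors(nuc[fb])
            if nc_post.shape[1] == n_classes:
                post[fb] = nc_post
    return preds, post, score


def enhance(image: RGBImage | GrayImage, cfg: EnhanceConfig | None = None
            ) -> GrayImage:
    gray = rgb_to_gray(image) if isinstance(image, RGBImage) else image
    return clahe(gray, cfg)


def refine_nucleus_masks(gray: GrayImage, objects, min_pixels: int = 9) -> None:
    """Per-cell refinement of the nucleus-cytoplasm boundary.

    The pixel classifier delimits whole cells reliably but places the
    nucleus boundary noisily, which propagates into the N/C ratio — the most
    diagnostic feature.  For each object with an attached cytoplasm, the
    nucleus mask is re-estimated by an Otsu intensity split inside a local
    window around the detected nucleus (nuclear chromatin is darker than
    cytoplasm), keeping the largest dark component.  Objects where the split
    fails keep their original masks.  Masks are modified in place.
    """
    from .debris_rejection import otsu_split

    px = gray.pixels
    eight = np.ones((3, 3), dtype=bool)
    from scipy import ndimage as ndi
    for obj in objects:
        if obj.cytoplasm_mask is None or obj.nucleus_mask.sum() < min_pixels:
            continue
        cell = obj.full_mask
        r0, c0 = obj.bbox
        crop = px[r0:r0 + cell.shape[0], c0:c0 + cell.shape[1]]
        # local window: nucleus dilated to ~3x its equivalent radius
        rad = max(int(np.sqrt(obj.nucleus_mask.sum() / np.pi)), 2)
        window = ndi.binary_dilation(obj.nucleus_mask, structure=eight,
                                     iterations=2 * rad) & cell
        vals = crop[window]
        if len(vals) < 2 * min_pixels or np.ptp(vals) == 0:
            continue
        if len(vals) > 5000:
            vals = np.sort(vals)[:: len(vals) // 5000 + 1]
        try:
            thr = otsu_split(vals)
        except Exception:
            continue
        dark = (crop < thr) & window
        lab, n = ndi.label(dark, structure=eight)
        if n == 0:
            continue
        sizes = ndi.sum_labels(dark, lab, index=np.arange(1, n + 1))
        nucleus = lab == (int(np.argmax(sizes)) + 1)
        nucleus = ndi.binary_fill_holes(
            ndi.binary_closing(nucleus, structure=eight))
        npx = int(nucleus.sum())
        if npx < min_pixels or npx > 0.95 * cell.sum():
            continue
        obj.nucleus_mask = nucleus
        obj.cytoplasm_mask = cell & ~nucleus
        obj.nucleus_area = npx * obj.linear_scale**2
        from .debris_rejection import mask_perimeter
        obj.nucleus_perimeter = mask_perimeter(nucleus) * obj.linear_scale
        com = ndi.center_of_mass(nucleus)
        obj.centroid = (r0 + float(com[0]), c0 + float(com[1]))


def analyze_image(image: RGBImage | GrayImage, models: PipelineModels,
                  linear_scale: float = 1.0, min_abnormal: int = 1
                  ) -> SlideResult:
    """Run the full screening pipeline on one image."""
    log: list[dict] = []
    gray = enhance(image, models.enhance_config)
    label_map = segment_scene(gray, models.pixel_classifier,
                              smooth_sigma=models.smooth_sigma)
    log.append({"stage": "segment",
                "nucleus_px": int(label_map.mask(SceneClass.NUCLEUS).sum())})
    retained, report = reject_debris(
        gray, label_map, models.debris_config, linear_scale=linear_scale,
        reference_scores=models.texture_reference_scores,
        merge_nuclei=models.merge_nuclei, close_radius=models.close_radius)
    refine_nucleus_masks(gray, retained)
    log.append({"stage": "debris", "candidates": len(report.objects),
                "retained": len(retained),
                "rejected": {s.value: n for s, n in report.counts.items()}})
    rows = [extract_features(gray, obj) for obj in retained]
    df = feature_table(rows)
    if len(df):
        preds, post, _ = predict_cells(models, df)
        classes = [CellClass(p) if p >= 0 else None for p in preds]
        binary = [binary_label(c) if c is not None else "NORMAL"
                  for c in classes]
        diagnosed = [c for c in classes if c is not None]
    else:
        preds = np.array([], dtype=int)
        post = np.zeros((0, 0))
        binary = []
        diagnosed = []
    diagnosis = screen_slide(diagnosed, min_abnormal=min_abnormal)
    log.append({"stage": "classify", "cells": len(df),
                "abnormal": diagnosis.n_abnormal})
    return SlideResult(label_map=label_map, report=report, features=df,
                       cell_objects=retained, predicted_classes=preds,
                       posteriors=post, binary=binary, diagnosis=diagnosis,
                       stage_log=log)


# ---------------------------------------------------------------------------
# training on rendered scenes

def scribbles_from_truth(scene: RenderedScene, n_per_class: int = 400,
                         seed: int = 0) -> AnnotationSet:
    """Seeded scribble annotations sampled from the scene's ground truth.

    Nucleus and cytoplasm scribbles are stratified per cell (every cell gets
    an equal quota) the way an annotator marks each cell they see, so rare
    appearance modes — e.g. the brighter nuclei of glandular cells — are
    represented; background and debris pixels are sampled uniformly.
    """
    rng = np.random.default_rng(seed)
    scrib = []
    cells = scene.cells()
    quota = max(n_per_class // max(len(cells), 1), 4)
    shape = scene.truth.labels.shape
    for which, cls_ in (("nucleus", SceneClass.NUCLEUS),
                        ("cytoplasm", SceneClass.CYTOPLASM)):
        parts = []
        for rec in cells:
            local = (rec.nucleus_mask if which == "nucleus"
                     else rec.cytoplasm_mask)
            if local is None or not local.any():
                continue
            coords = np.argwhere(local) + np.asarray(rec.bbox)
            take = min(quota, len(coords))
            parts.append(coords[rng.choice(len(coords), size=take,
                                           replace=False)])
        if parts:
            merged = np.concatenate(parts)
            # keep only pixels that truly carry this label (nucleus overlap
            # trimming in the render can reassign a few)
            keep = scene.truth.labels[merged[:, 0], merged[:, 1]] == int(cls_)
            if keep.any():
                scrib.append((merged[keep], cls_))
    for cls_ in (SceneClass.BACKGROUND, SceneClass.DEBRIS):
        coords = np.argwhere(scene.truth.labels == int(cls_))
        if len(coords) == 0:
            continue
        pick = coords[rng.choice(len(coords), size=min(n_per_class, len(coords)),
                                 replace=False)]
        scrib.append((pick, cls_))
    return AnnotationSet(scrib)


def train_models_on_scene(scene: RenderedScene, seed: int = 0,
                          debris_config: DebrisConfig | None = None,
                          clf_config: FCMClassifierConfig | None = None,
                          feature_subset: list[str] | None = None,
                          bank: FilterBankConfig | None = None,
                          n_trees: int = 200,
                          scribble_pixels: int = 1200,
                          smooth_sigma: float = 1.0,
                          merge_nuclei: bool = True,
                          close_radius: int = 2,
                          select_clusters: list[int] | None = None
                          ) -> PipelineModels:
    """Train the pixel classifier and the cell classifier on one scene.

    ``select_clusters`` optionally picks the cluster count by k-fold CV over
    the given candidates before the final fit (the cluster-count-vs-CV-error
    analysis of the reference method).

    The cell classifier is trained on features measured by the same pipeline
    used at inference (segmentation-derived masks), labelled by matching
    detected objects to the manifest.  The texture scores of every
    shape-gate survivor (true cells and debris alike) become the AUTO
    texture-threshold reference.
    """
    debris_config = debris_config or DebrisConfig()
    subset = list(feature_subset or REFERENCE_SELECTED_FEATURES)
    gray = enhance(scene.image)
    stack = build_pixel_features(gray, bank)
    ann = scribbles_from_truth(scene, n_per_class=scribble_pixels, seed=seed)
    pix = train_pixel_classifier([stack], [ann], seed=seed, bank=bank,
                                 n_trees=n_trees)
    label_map = segment_scene(gray, pix, features=stack,
                              smooth_sigma=smooth_sigma)

    # retain-all texture pass: collect scores for the reference distribution
    open_cfg = DebrisConfig(
        area_min=debris_config.area_min, area_max=debris_config.area_max,
        compactness_low=debris_config.compactness_low,
        compactness_high=debris_config.compactness_high,
        zernike_order=debris_config.zernike_order,
        zernike_window=debris_config.zernike_window,
        texture_threshold=float("inf"),
        texture_max_pixels=debris_config.texture_max_pixels)
    survivors, _ = reject_debris(gray, label_map, open_cfg,
                                 linear_scale=scene.linear_scale,
                                 merge_nuclei=merge_nuclei,
                                 close_radius=close_radius)
    ref_scores = np.array([o.texture_score for o in survivors], dtype=float)
    refine_nucleus_masks(gray, survivors)

    pairs = match_cells_to_objects(scene, survivors,
                                   max_dist=30.0)
    rows, labels, cell_scores = [], [], []
    for rec, obj in pairs:
        if obj is None:
            continue
        rows.append(extract_features(gray, obj))
        labels.append(rec.cell_class)
        cell_scores.append(obj.texture_score)
    df = feature_table(rows, labels)
    if select_clusters:
        from .fcm_classifier import choose_cluster_count
        base = clf_config or FCMClassifierConfig()
        probe = FCMClassifierConfig(
            n_clusters=base.n_clusters, fuzzifier=base.fuzzifier,
            tol=base.tol, max_iter=base.max_iter, n_restarts=3,
            smoothing=base.smoothing)
        rep_cc = choose_cluster_count(df, list(select_clusters), k=5,
                                      seed=seed, subset=subset,
                                      base_config=probe)
        clf_config = FCMClassifierConfig(
            n_clusters=rep_cc.chosen, fuzzifier=base.fuzzifier, tol=base.tol,
            max_iter=base.max_iter, n_restarts=base.n_restarts,
            smoothing=base.smoothing)
    # calibrate the texture gate on the known-cell score distribution: keep
    # everything up to the training-cell ceiling (20% headroom)
    if cell_scores:
        debris_config = DebrisConfig(
            area_min=debris_config.area_min, area_max=debris_config.area_max,
            compactness_low=debris_config.compactness_low,
            compactness_high=debris_config.compactness_high,
            zernike_order=debris_config.zernike_order,
            zernike_window=debris_config.zernike_window,
            texture_threshold=1.2 * float(np.nanmax(cell_scores)),
            texture_max_pixels=debris_config.texture_max_pixels)
    X, y, _ = table_to_xy(df, subset=subset)
    if len(np.unique(y)) < 2:
        raise ContractError("training scene yielded fewer than two classes")
    clf = FCMClassifier(config=clf_config, seed=seed, feature_names=subset)
    clf.fit(X, y)
    # nucleus-only fallback for cells whose cytoplasm was not recovered
    Xn, yn, _ = table_to_xy(df, subset=NUCLEUS_ONLY_FEATURES)
    nuc_clf = None
    if len(np.unique(yn)) >= 2:
        nuc_clf = FCMClassifier(config=clf_config, seed=seed,
                                feature_names=list(NUCLEUS_ONLY_FEATURES))
        nuc_clf.fit(Xn, yn)
    return PipelineModels(pixel_classifier=pix, cell_classifier=clf,
                          nucleus_classifier=nuc_clf,
                          debris_config=debris_config,
                          feature_subset=subset,
                          texture_reference_scores=ref_scores,
                          smooth_sigma=smooth_sigma,
                          merge_nuclei=merge_nuclei,
                          close_radius=close_radius)


def synthetic_end_to_end(seed: int = 0, cells_per_class_train: int = 25,
                         cells_per_class_test: int = 20,
                         scale: float = 0.4,
                         clf_config: FCMClassifierConfig | None = None,
                         n_trees: int = 200) -> dict:
    """Full-pipeline benchmark on rendered scenes.

    Trains on one scene, screens a second (disjoint seed), and scores the
    per-cell binary decision against the manifest: a manifest cell that is
    not recovered as a retained object counts as an error.  Returns accuracy,
    the confusion-derived metrics, the ROC AUC over matched cells and the
    underlying sizes.
    """
    debris_cfg = DebrisConfig(zernike_window=13)
    train_recipe = SceneRecipe(cells_per_class=cells_per_class_train,
                               debris={"speck": 2, "fiber": 1, "noisy_blob": 2},
                               scale=scale, seed=seed * 1000 + 1)
    test_recipe = SceneRecipe(cells_per_class=cells_per_class_test,
                              debris={"speck": 3, "fiber": 1, "noisy_blob": 2},
                              scale=scale, seed=seed * 1000 + 2)
    train_scene = render_scene(train_recipe)
    test_scene = render_scene(test_recipe)
    models = train_models_on_scene(train_scene, seed=seed,
                                   debris_config=debris_cfg,
                                   clf_config=clf_config, n_trees=n_trees,
                                   select_clusters=[10, 15, 20, 25])
    gray = enhance(test_scene.image)
    label_map = segment_scene(gray, models.pixel_classifier,
                              smooth_sigma=models.smooth_sigma)
    retained, report = reject_debris(
        gray, label_map, models.debris_config,
        linear_scale=test_scene.linear_scale,
        reference_scores=models.texture_reference_scores,
        merge_nuclei=models.merge_nuclei, close_radius=models.close_radius)
    refine_nucleus_masks(gray, retained)
    pairs = match_cells_to_objects(test_scene, retained, max_dist=30.0)

    truths, preds, scores = [], [], []
    n_missed = 0
    for rec, obj in pairs:
        truths.append(binary_label(rec.cell_class))
        if obj is None:
            n_missed += 1
            preds.append("NORMAL")   # a lost cell can never raise an alarm
            scores.append(0.0)
            continue
        row = feature_table([extract_features(gray, obj)])
        p, _, s = predict_cells(models, row)
        if p[0] < 0:
            n_missed += 1
            preds.append("NORMAL")
            scores.append(0.0)
            continue
        preds.append(binary_label(CellClass(p[0])))
        scores.append(float(s[0]))

    correct = sum(1 for t, p in zip(truths, preds) if t == p)
    acc = correct / len(truths)
    cm = confusion(truths, preds)
    mt = metrics(cm)
    _, _, auc = roc_curve(truths, scores)
    per_class: dict[str, list[int]] = {}
    for rec, t, p in zip(pairs, truths, preds):
        name = rec[0].cell_class.name
        hit, tot = per_class.get(name, [0, 0])
        per_class[name] = [hit + (t == p), tot + 1]
    return {
        "n_cells": len(truths), "n_missed": n_missed,
        "binary_accuracy": acc, "metrics": mt, "confusion": cm, "auc": auc,
        "per_class": per_class,
        "rejections": {s.value: n for s, n in report.counts.items()},
        "models": models,
    }
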