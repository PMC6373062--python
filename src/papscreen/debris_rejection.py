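"""Three-phase sequential debris rejection: size, then shape, then texture.

Candidate objects are 8-connected components of nucleus-labelled pixels with
any touching cytoplasm component attached.  Each object is tested by three
gates strictly in order; an object reaches a later gate only if it passed all
earlier ones:

SIZE     whole-object area must lie in [area_min, area_max] (bounds inclusive,
         defaults 625 and 85,267 area units — the plausible range for a
         cervical epithelial cell).
SHAPE    normalized circularity 4*pi*A/p^2 must lie inside
         (compactness_low, compactness_high) = (0.15, 0.97): elongated fibres
         fall below the band, perfectly circular droplets/blood cells above it.
         The raw perimeter^2/area descriptor is kept alongside.
TEXTURE  nuclear stain is texturally homogeneous while debris is erratic; the
         mean Zernike-moment magnitude over windows centred at nucleus pixels
         separates the two, thresholded either at a fixed value or by an Otsu
         split (AUTO).

Areas are measured as pixel counts times a configurable squared linear scale,
so the printed thresholds compare directly with reference-dataset pixel
statistics; perimeters use the same linear unit and are measured along the
outer 8-connected contour through pixel centres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi

from ._errors import ConfigError, ContractError
from .imaging import GrayImage
from .pixel_segmentation import LabelMap, SceneClass
from .zernike import ZernikeBasis

AUTO = "auto"


class RejectionStage(Enum):
    NONE = "none"
    SIZE = "size"
    SHAPE = "shape"
    TEXTURE = "texture"


@dataclass(frozen=True)
class DebrisConfig:
    """Thresholds for the three gates (areas in squared linear units)."""

    area_min: float = 625.0
    area_max: float = 85_267.0
    compactness_low: float = 0.15
    compactness_high: float = 0.97
    zernike_order: int = 9
    zernike_window: int = 25
    texture_threshold: float | str = AUTO
    texture_max_pixels: int = 4096

    def __post_init__(self):
        if not (0 < self.area_min < self.area_max):
            raise ConfigError("need 0 < area_min < area_max")
        if not (0 <= self.compactness_low < self.compactness_high):
            raise ConfigError("need 0 <= compactness_low < compactness_high")


@dataclass
class CellObject:
    """One candidate object: nucleus mask, optional attached cytoplasm.

    Masks are stored on the object's local bounding box; ``bbox`` gives the
    (row, col) offset of that box in the source image.
    """

    object_id: int
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray | None = None
    bbox: tuple[int, int] = (0, 0)
    linear_scale: float = 1.0          # measurement units per pixel edge
    area: float = 0.0                  # whole object, unit^2
    perimeter: float = 0.0             # whole object outer contour, units
    nucleus_area: float = 0.0
    nucleus_perimeter: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    compactness_score: float = float("nan")
    p2a_raw: float = float("nan")
    texture_score: float = float("nan")
    rejection_stage: RejectionStage = RejectionStage.NONE

    @property
    def full_mask(self) -> np.ndarray:
        if self.cytoplasm_mask is None:
            return self.nucleus_mask
        return self.nucleus_mask | self.cytoplasm_mask


@dataclass
class RejectionReport:
    """Per-stage rejection counts plus the per-object outcomes."""

    counts: dict[RejectionStage, int] = field(default_factory=dict)
    objects: list[CellObject] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {s.value: n for s, n in self.counts.items()},
            "objects": [
                {
                    "id": o.object_id,
                    "area": o.area,
                    "perimeter": o.perimeter,
                    "compactness": o.compactness_score,
                    "texture": o.texture_score,
                    "stage": o.rejection_stage.value,
                }
                for o in self.objects
            ],
        }


# ---------------------------------------------------------------------------
# geometry helpers

_NBRS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a connected mask as pixel centres, Moore tracing.

    Returns the closed contour as an (N, 2) array of (row, col) points.  A
    single-pixel mask returns its one point (degenerate contour).
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    rs, cs = np.nonzero(padded)
    if len(rs) == 0:
        raise ContractError("cannot trace an empty mask")
    start = (int(rs[0]), int(cs[0]))       # topmost, then leftmost
    came_from = (start[0], start[1] - 1)   # background west of start
    contour = [start]
    b, c = start, came_from

    def step(b, c):
        i = _NBRS.index((c[0] - b[0], c[1] - b[1]))
        for k in range(1, 9):
            dy, dx = _NBRS[(i + k) % 8]
            p = (b[0] + dy, b[1] + dx)
            if padded[p]:
                pdy, pdx = _NBRS[(i + k - 1) % 8]
                return p, (b[0] + pdy, b[1] + pdx)
        return None  # isolated pixel

    nxt = step(b, c)
    if nxt is not None:
        first_state = nxt  # stop when this (pixel, came-from) state recurs
        b, c = nxt
        while True:
            contour.append(b)
            nxt = step(b, c)
            b, c = nxt
            if (b, c) == first_state:
                break
    return np.asarray(contour) - 1  # undo padding offset


def perimeter_length(contour: np.ndarray) -> float:
    """Length of the closed contour polygon (steps of 1 or sqrt 2)."""
    if len(contour) < 2:
        return 0.0
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def mask_perimeter(mask: np.ndarray) -> float:
    return perimeter_length(trace_boundary(mask))


# ---------------------------------------------------------------------------
# object construction

def label_objects(labels: LabelMap, linear_scale: float = 1.0,
                  merge_nuclei: bool = False,
                  close_radius: int = 0) -> list[CellObject]:
    """Connected nucleus components plus any touching cytoplasm component.

    Areas are pixel counts times ``linear_scale**2``; perimeters are contour
    lengths times ``linear_scale``.  With ``merge_nuclei``, nucleus
    components that touch the same cytoplasm component are treated as
    fragments of one nucleus and merged into a single object (one candidate
    per cell); isolated nuclei are unaffected.  ``close_radius`` > 0 applies
    morphological closing (and hole filling) to the whole-object mask before
    measurement, regularizing ragged segmentation boundaries; the filled-in
    pixels are counted as cytoplasm.
    """
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    nuc = labels.mask(SceneClass.NUCLEUS)
    cyt = labels.mask(SceneClass.CYTOPLASM)
    nuc_lab, n_nuc = ndi.label(nuc, structure=structure)
    cyt_lab, n_cyt = ndi.label(cyt, structure=structure)
    h, w = nuc.shape
    objects: list[CellObject] = []
    nuc_slices = ndi.find_objects(nuc_lab)
    cyt_slices = ndi.find_objects(cyt_lab) if n_cyt else []

    touches: list[np.ndarray] = []
    for i in range(1, n_nuc + 1):
        sl = nuc_slices[i - 1]
        grown = (slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, h)),
                 slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, w)))
        nmask_loc = nuc_lab[grown] == i
        dilated = ndi.binary_dilation(nmask_loc, structure=structure)
        touching = np.unique(cyt_lab[grown][dilated])
        touches.append(touching[touching > 0])

    if merge_nuclei:
        # union-find over nucleus components sharing a cytoplasm component
        parent = list(range(n_nuc))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        by_cyt: dict[int, int] = {}
        for i, tch in enumerate(touches):
            for t in tch:
                if t in by_cyt:
                    ra, rb = find(by_cyt[t]), find(i)
                    parent[rb] = ra
                else:
                    by_cyt[t] = i
        groups: dict[int, list[int]] = {}
        for i in range(n_nuc):
            groups.setdefault(find(i), []).append(i)
        members = list(groups.values())
    else:
        members = [[i] for i in range(n_nuc)]

    for group in members:
        touching = (np.unique(np.concatenate([touches[i] for i in group]))
                    if group else np.array([], dtype=int))
        r0 = min(nuc_slices[i][0].start for i in group)
        r1 = max(nuc_slices[i][0].stop for i in group)
        c0 = min(nuc_slices[i][1].start for i in group)
        c1 = max(nuc_slices[i][1].stop for i in group)
        for t in touching:
            csl = cyt_slices[t - 1]
            r0, r1 = min(r0, csl[0].start), max(r1, csl[0].stop)
            c0, c1 = min(c0, csl[1].start), max(c1, csl[1].stop)
        pad = close_radius + 1
        r0, r1 = max(r0 - pad, 0), min(r1 + pad, h)
        c0, c1 = max(c0 - pad, 0), min(c1 + pad, w)
        box = (slice(r0, r1), slice(c0, c1))
        nmask = np.isin(nuc_lab[box], [i + 1 for i in group])
        cmask = np.isin(cyt_lab[box], touching) if len(touching) else None
        full = nmask if cmask is None else (nmask | cmask)
        if close_radius > 0:
            selem = np.ones((2 * close_radius + 1,) * 2, dtype=bool)
            closed = ndi.binary_fill_holes(
                ndi.binary_closing(full, structure=selem))
            if cmask is not None or (closed & ~nmask).any():
                cmask = closed & ~nmask
            full = closed
        area_px = int(full.sum())
        com = ndi.center_of_mass(nmask)
        obj = CellObject(
            object_id=len(objects),
            nucleus_mask=nmask,
            cytoplasm_mask=cmask,
            bbox=(r0, c0),
            linear_scale=linear_scale,
            area=area_px * linear_scale**2,
            perimeter=mask_perimeter(full) * linear_scale,
            nucleus_area=int(nmask.sum()) * linear_scale**2,
            nucleus_perimeter=mask_perimeter(nmask) * linear_scale,
            centroid=(r0 + float(com[0]), c0 + float(com[1])),
        )
        objects.append(obj)
    return objects


# ---------------------------------------------------------------------------
# gates

def size_gate(obj: CellObject, cfg: DebrisConfig) -> bool:
    """Retain iff area_min <= area <= area_max (inclusive)."""
    ok = cfg.area_min <= obj.area <= cfg.area_max
    if not ok:
        obj.rejection_stage = RejectionStage.SIZE
    return ok


def compactness(obj: CellObject) -> float:
    """Normalized circularity 4*pi*A/p^2 of the whole object (1 = circle).

    The raw perimeter^2/area descriptor is stored on the object as well.
    """
    if obj.perimeter <= 0:
        raise ContractError(
            "degenerate object (no measurable perimeter); compactness undefined"
        )
    obj.p2a_raw = obj.perimeter**2 / obj.area
    obj.compactness_score = 4.0 * math.pi * obj.area / obj.perimeter**2
    return obj.compactness_score


def shape_gate(obj: CellObject, cfg: DebrisConfig) -> bool:
    """Reject objects outside the (low, high) circularity band."""
    c = obj.compactness_score
    if math.isnan(c):
        c = compactness(obj)
    ok = cfg.compactness_low <= c <= cfg.compactness_high
    if not ok:
        obj.rejection_stage = RejectionStage.SHAPE
    return ok


def zernike_texture(img: GrayImage, obj: CellObject,
                    basis: ZernikeBasis | None = None,
                    max_pixels: int = 4096) -> float:
    """Mean Zernike-moment magnitude over windows centred at nucleus pixels.

    Intensities are scaled to [0, 1]; the image is reflection-padded so
    windows near the border stay valid.  For very large nuclei an evenly
    strided subset of at most ``max_pixels`` centre pixels is used.
    """
    basis = basis or ZernikeBasis()
    m = basis.window
    h, w = img.pixels.shape
    if m > min(h, w) + 2 * (m // 2):
        raise ConfigError("Zernike window larger than the padded image")
    if obj.nucleus_mask.sum() == 0:
        raise ContractError("object has an empty nucleus mask")
    # centre windows on interior pixels so the score measures nuclear texture
    # rather than the boundary step; erosion depth adapts to small nuclei
    dist = ndi.distance_transform_edt(obj.nucleus_mask)
    depth = min(m // 2, int(dist.max()) - 1)
    coords = np.argwhere(dist > depth) if depth > 0 else np.argwhere(obj.nucleus_mask)
    if len(coords) > max_pixels:
        step = len(coords) / max_pixels
        coords = coords[(np.arange(max_pixels) * step).astype(int)]
    coords = coords + np.asarray(obj.bbox)   # local mask -> image coordinates
    pad = m // 2
    padded = np.pad(img.pixels / 255.0, pad, mode="reflect")
    # gather flattened m x m patches centred at each pixel
    offs = np.arange(m)
    rows = coords[:, 0][:, None, None] + offs[None, :, None]
    cols = coords[:, 1][:, None, None] + offs[None, None, :]
    patches = padded[rows, cols].reshape(len(coords), m * m)
    mags = np.abs(basis.moments_many(patches))
    score = float(mags.mean())
    obj.texture_score = score
    return score


def otsu_split(values: np.ndarray) -> float:
    """Exact Otsu threshold on a sample: the split of the sorted values that
    maximizes the between-class variance, placed midway between the classes.

    Unbinned, so it behaves sensibly on the small score batches the texture
    gate sees (ties go to the smallest split).
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        raise ContractError("need at least two distinct values")
    csum = np.cumsum(xs)
    total = csum[-1]
    best_v, best_i = -1.0, 1
    for i in range(1, n):
        w0 = i / n
        m0 = csum[i - 1] / i
        m1 = (total - csum[i - 1]) / (n - i)
        v = w0 * (1 - w0) * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_i = v, i
    return 0.5 * (xs[best_i - 1] + xs[best_i])


def texture_gate(objs: list[CellObject], cfg: DebrisConfig,
                 reference_scores: np.ndarray | None = None) -> list[CellObject]:
    """Reject objects whose texture score exceeds the threshold.

    With ``texture_threshold=AUTO`` the threshold is the Otsu split of the
    reference score distribution (the current batch's scores when no explicit
    training reference is supplied).  Fewer than two objects under AUTO falls
    back to retaining everything, with a warning.
    """
    if not objs:
        return []
    scores = np.array([o.texture_score for o in objs], dtype=float)
    if np.isnan(scores).any():
        raise ContractError("texture_score missing on some objects")
    if cfg.texture_threshold == AUTO:
        ref = scores if reference_scores is None else np.asarray(reference_scores)
        if len(ref) < 2 or np.ptp(ref) == 0:
            warnings.warn(
                "texture gate AUTO needs at least two distinct scores; "
                "retaining all objects", stacklevel=2
            )
            return list(objs)
        thr = otsu_split(ref)
        # only gate when the split separates two genuine score populations:
        # the gap at the split must dominate the overall spread, otherwise a
        # debris-free batch would lose its highest-scoring nuclei
        xs = np.sort(ref)
        above = xs[xs > thr]
        below = xs[xs <= thr]
        gap = above.min() - below.max()
        # textured debris is the high-score minority: a split whose gap does
        # not dominate the spread, or that would reject the majority, is a
        # homogeneous batch, not a cell/debris separation
        if gap < 0.5 * np.ptp(xs) or len(above) > len(below):
            return list(objs)
    else:
        thr = float(cfg.texture_threshold)
    retained = []
    for o in objs:
        if o.texture_score > thr:
            o.rejection_stage = RejectionStage.TEXTURE
        else:
            retained.append(o)
    return retained


def reject_debris(img: GrayImage, labels: LabelMap, cfg: DebrisConfig | None = None,
                  linear_scale: float = 1.0,
                  reference_scores: np.ndarray | None = None,
                  merge_nuclei: bool = False,
                  close_radius: int = 0,
                  ) -> tuple[list[CellObject], RejectionReport]:
    """Run the three gates strictly in order SIZE -> SHAPE -> TEXTURE.

    Returns the retained objects and a report with per-stage rejection counts
    covering every candidate object.
    """
    cfg = cfg or DebrisConfig()
    objects = label_objects(labels, linear_scale=linear_scale,
                            merge_nuclei=merge_nuclei,
                            close_radius=close_radius)
    report = RejectionReport(
        counts={RejectionStage.SIZE: 0, RejectionStage.SHAPE: 0,
                RejectionStage.TEXTURE: 0},
        objects=objects,
    )
    survivors = []
    for obj in objects:
        if size_gate(obj, cfg):
            survivors.append(obj)
        else:
            report.counts[RejectionStage.SIZE] += 1
    after_shape = []
    for obj in survivors:
        if shape_gate(obj, cfg):
            after_shape.append(obj)
        else:
            report.counts[RejectionStage.SHAPE] += 1
    basis = ZernikeBasis(window=cfg.zernike_window, n_max=cfg.zernike_order)
    for obj in after_shape:
        zernike_texture(img, obj, basis=basis, max_pixels=cfg.texture_max_pixels)
    retained = texture_gate(after_shape, cfg, reference_scores=reference_scores)
    report.counts[RejectionStage.TEXTURE] += len(after_shape) - len(retained)
    return retained, report
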