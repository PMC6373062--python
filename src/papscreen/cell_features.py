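"""Per-cell morphometry: the 29 nucleus/cytoplasm features.

For every retained cell the nucleus (and, when present, cytoplasm) mask is
measured on the enhanced gray image.  Operational definitions:

* shortest diameter — diameter of the largest inscribed circle (twice the
  maximum of the Euclidean distance transform inside the mask);
* longest diameter — diameter of the minimum enclosing circle of the mask;
* elongation — shortest / longest diameter;
* roundness — area / (pi * (longest diameter / 2)^2);
* perimeter — outer 8-connected contour through pixel centres (same
  convention as the debris gates);
* maxima/minima counts — number of regional intensity extrema under a disk
  structuring element of radius 3 px;
* gray level / mean — mean intensity of mask pixels;
* std / variance — dispersion of mask intensities on the [0, 255] scale;
* smoothness — 1 - 1/(1 + sigma^2) with sigma on intensities scaled to [0, 1];
* entropy / energy — -sum p log2 p and sum p^2 over the 256-bin normalized
  intensity histogram;
* eccentricity — from the mask's second central moments (ellipse-equivalent);
* solidity — area / convex hull area;
* compactness — normalized circularity 4 pi A / p^2;
* relative position — distance between nucleus and cytoplasm centroids over
  the cytoplasm's longest radius (0 = perfectly centred);
* N/C ratio — NA / (NA + CA), which is 1 when no cytoplasm is attached.

Cytoplasm geometric features (diameters, elongation, roundness, perimeter)
are measured on the filled whole-cell region, while cytoplasm area and gray
level cover cytoplasm pixels only, matching how the reference statistics are
tabulated.  Cells without an attached cytoplasm carry NaN in the cytoplasm
columns; such cells are excluded from training statistics rather than imputed.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from shapely import MultiPoint, minimum_bounding_radius
from skimage.measure import regionprops
from skimage.morphology import disk

from ._errors import ContractError, DataError
from .debris_rejection import CellObject, mask_perimeter
from .imaging import GrayImage

#: canonical column order of a feature table (Table-style numbering)
FEATURE_NAMES: list[str] = [
    "nucleus_area",
    "nucleus_gray_level",
    "nucleus_shortest_diameter",
    "nucleus_longest_diameter",
    "nucleus_elongation",
    "nucleus_roundness",
    "nucleus_perimeter",
    "nucleus_maxima",
    "nucleus_minima",
    "nc_ratio",
    "nucleus_solidity",
    "nucleus_eccentricity",
    "nucleus_std",
    "nucleus_variance",
    "nucleus_entropy",
    "cytoplasm_area",
    "cytoplasm_gray_level",
    "cytoplasm_shortest_diameter",
    "cytoplasm_longest_diameter",
    "cytoplasm_elongation",
    "cytoplasm_roundness",
    "cytoplasm_perimeter",
    "cytoplasm_maxima",
    "cytoplasm_minima",
    "nucleus_relative_position",
    "nucleus_compactness",
    "nucleus_mean",
    "nucleus_smoothness",
    "nucleus_energy",
]

LABEL_COLUMN = "label"


class CellClass(IntEnum):
    """The seven cervical cell classes; the first three are normal."""

    SUPERFICIAL = 0
    INTERMEDIATE = 1
    COLUMNAR = 2
    MILD = 3
    MODERATE = 4
    SEVERE = 5
    CARCINOMA_IN_SITU = 6


NORMAL_CLASSES = (CellClass.SUPERFICIAL, CellClass.INTERMEDIATE, CellClass.COLUMNAR)


def binary_label(c: CellClass) -> str:
    """Collapse the 7-class label to the NORMAL/ABNORMAL screening dichotomy."""
    return "NORMAL" if CellClass(c) in NORMAL_CLASSES else "ABNORMAL"


# ---------------------------------------------------------------------------
# mask-level measurements

def inscribed_diameter(mask: np.ndarray) -> float:
    """Largest inscribed circle diameter, via the distance transform."""
    dist = ndi.distance_transform_edt(mask)
    return 2.0 * float(dist.max())


def enclosing_diameter(mask: np.ndarray) -> float:
    """Minimum enclosing circle diameter of the mask's pixel centres."""
    coords = np.argwhere(mask)
    if len(coords) == 1:
        return 1.0
    if len(coords) > 16:  # reduce to the convex hull before the circle fit
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:   # degenerate (collinear) masks
            pass
    return 2.0 * float(minimum_bounding_radius(MultiPoint(coords[:, ::-1])))


def _extrema_count(values: np.ndarray, mask: np.ndarray, mode: str) -> int:
    """Regional extrema components under a radius-3 disk, inside the mask."""
    footprint = disk(3)
    img = np.where(mask, values, np.nan)
    filled = np.where(mask, values, -np.inf if mode == "max" else np.inf)
    if mode == "max":
        filt = ndi.maximum_filter(filled, footprint=footprint, mode="nearest")
        extrema = (values >= filt) & mask
    else:
        filt = ndi.minimum_filter(filled, footprint=footprint, mode="nearest")
        extrema = (values <= filt) & mask
    _, n = ndi.label(extrema, structure=np.ones((3, 3), bool))
    return int(n)


def _histogram_stats(values: np.ndarray) -> dict[str, float]:
    """Mean/std/variance, and entropy/energy/smoothness of the 256-bin histogram."""
    mean = float(values.mean())
    var = float(values.var())
    std = float(np.sqrt(var))
    hist, _ = np.histogram(np.clip(values, 0, 255), bins=256, range=(0, 256))
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    sigma01 = std / 255.0
    smoothness = 1.0 - 1.0 / (1.0 + sigma01**2)
    return {"mean": mean, "std": std, "variance": var, "entropy": entropy,
            "energy": energy, "smoothness": smoothness}


def extract_features(img: GrayImage, obj: CellObject) -> dict[str, float]:
    """Measure the 29 features of one cell; deterministic.

    Lengths and areas are reported in the object's calibrated units
    (``obj.linear_scale`` units per pixel edge).
    """
    nmask = obj.nucleus_mask
    if nmask.sum() == 0:
        raise ContractError("nucleus mask is empty")
    scale = obj.linear_scale
    r0, c0 = obj.bbox
    px = img.pixels[r0:r0 + nmask.shape[0], c0:c0 + nmask.shape[1]]
    f: dict[str, float] = {}

    nvals = px[nmask]
    nstats = _histogram_stats(nvals)
    na = float(nmask.sum()) * scale**2
    n_long = enclosing_diameter(nmask) * scale
    # digital disks can put the inscribed estimate a fraction of a pixel
    # above the enclosing one; the inequality is restored by construction
    n_short = min(inscribed_diameter(nmask) * scale, n_long)
    n_perim = (obj.nucleus_perimeter if obj.nucleus_perimeter > 0
               else mask_perimeter(nmask) * scale)
    props = regionprops(nmask.astype(np.uint8))[0]

    f["nucleus_area"] = na
    f["nucleus_gray_level"] = nstats["mean"]
    f["nucleus_shortest_diameter"] = n_short
    f["nucleus_longest_diameter"] = n_long
    f["nucleus_elongation"] = n_short / n_long
    f["nucleus_roundness"] = min(na / (np.pi * (n_long / 2.0) ** 2), 1.0)
    f["nucleus_perimeter"] = n_perim
    f["nucleus_maxima"] = _extrema_count(px, nmask, "max")
    f["nucleus_minima"] = _extrema_count(px, nmask, "min")
    f["nucleus_solidity"] = float(props.solidity)
    f["nucleus_eccentricity"] = float(props.eccentricity)
    f["nucleus_std"] = nstats["std"]
    f["nucleus_variance"] = nstats["variance"]
    f["nucleus_entropy"] = nstats["entropy"]
    f["nucleus_mean"] = nstats["mean"]
    f["nucleus_smoothness"] = nstats["smoothness"]
    f["nucleus_energy"] = nstats["energy"]
    if n_perim > 0:
        f["nucleus_compactness"] = 4.0 * np.pi * na / n_perim**2
    else:
        f["nucleus_compactness"] = np.nan

    cmask = obj.cytoplasm_mask
    if cmask is not None and cmask.sum() > 0:
        cvals = px[cmask]
        ca = float(cmask.sum()) * scale**2
        cell = obj.full_mask
        cell = ndi.binary_fill_holes(cell)
        c_long = enclosing_diameter(cell) * scale
        c_short = min(inscribed_diameter(cell) * scale, c_long)
        c_area_full = float(cell.sum()) * scale**2
        f["cytoplasm_area"] = ca
        f["cytoplasm_gray_level"] = float(cvals.mean())
        f["cytoplasm_shortest_diameter"] = c_short
        f["cytoplasm_longest_diameter"] = c_long
        f["cytoplasm_elongation"] = c_short / c_long
        f["cytoplasm_roundness"] = min(
            c_area_full / (np.pi * (c_long / 2.0) ** 2), 1.0)
        f["cytoplasm_perimeter"] = mask_perimeter(cell) * scale
        f["cytoplasm_maxima"] = _extrema_count(px, cmask, "max")
        f["cytoplasm_minima"] = _extrema_count(px, cmask, "min")
        ncom = ndi.center_of_mass(nmask)
        ccom = ndi.center_of_mass(cell)
        offset = float(np.hypot(ncom[0] - ccom[0], ncom[1] - ccom[1])) * scale
        f["nucleus_relative_position"] = offset / (c_long / 2.0)
        f["nc_ratio"] = na / (na + ca)
    else:
        for name in ("cytoplasm_area", "cytoplasm_gray_level",
                     "cytoplasm_shortest_diameter", "cytoplasm_longest_diameter",
                     "cytoplasm_elongation", "cytoplasm_roundness",
                     "cytoplasm_perimeter", "cytoplasm_maxima",
                     "cytoplasm_minima", "nucleus_relative_position"):
            f[name] = np.nan
        f["nc_ratio"] = 1.0  # NA / (NA + 0)

    return {name: f[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# feature-table I/O

def feature_table(rows: list[dict[str, float]],
                  labels: list[CellClass] | None = None) -> pd.DataFrame:
    """Assemble extraction results into a canonical feature table."""
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    if labels is not None:
        df[LABEL_COLUMN] = [CellClass(l).name for l in labels]
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV, validating the 29-column header exactly."""
    df = pd.read_csv(path)
    expected = FEATURE_NAMES + ([LABEL_COLUMN] if LABEL_COLUMN in df.columns else [])
    if list(df.columns) != expected:
        raise DataError(
            "feature table header mismatch; expected the canonical 29 feature "
            f"columns (+ optional '{LABEL_COLUMN}'), got {list(df.columns)!r}"
        )
    return df
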