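"""The 37-feature histologic description of a tissue-class label map.

Given a per-pixel segmentation of a whole-slide image into epithelium, stroma
and fat, three families of features are computed:

* **Global tissue quantities** (6): absolute area of each class in square
  microns and the same quantities normalised to total tissue area (percent).
* **Epithelial morphology** (11): the number of connected epithelial regions
  plus {mean, median, SD, interquartile range, max} summaries of region area
  and of region eccentricity (elongation of the moment-equivalent ellipse).
* **Spatial arrangement** (20): the area-Voronoi diagram assigns every tissue
  pixel to its nearest epithelial region (Euclidean distance to the region's
  pixel set), partitioning tissue into influence zones; features summarise
  zone areas, the ratio of each region's area to its zone (near 1 = the
  region fills its zone, coalescent growth; near 0 = sparse epithelium), the
  ratio of region area to the non-epithelial part of the zone, and the number
  of Delaunay neighbours of each region centroid (local packing).

Summaries use Q3 - Q1 with linear-interpolation quantiles for the
interquartile range and the population standard deviation (so a single
region yields SD 0, never a missing value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import Delaunay, QhullError
from skimage.measure import label as cc_label, regionprops

from .errors import EmptySlideError, NoEpitheliumError
from .io import TissueMap

STATS = ("mean", "median", "sd", "iq", "max")

GLOBAL_FEATURES = (
    "fat_amount", "fat_amount_norm",
    "stroma_amount", "stroma_amount_norm",
    "epi_amount", "epi_amount_norm",
)
MORPHOLOGY_FEATURES = (
    ("n_epi_regions",)
    + tuple(f"epi_area_{s}" for s in STATS)
    + tuple(f"epi_ecc_{s}" for s in STATS)
)
VORONOI_FEATURES = (
    tuple(f"voronoi_area_{s}" for s in STATS)
    + tuple(f"ratio_epi_voronoi_{s}" for s in STATS)
    + tuple(f"ratio_epi_nonepi_{s}" for s in STATS)
)
DELAUNAY_FEATURES = tuple(f"delaunay_neighbors_{s}" for s in STATS)

#: canonical 37-feature roster, in canonical column order
FEATURE_NAMES: tuple[str, ...] = (
    GLOBAL_FEATURES + MORPHOLOGY_FEATURES + VORONOI_FEATURES + DELAUNAY_FEATURES
)

FEATURE_FAMILIES: dict[str, str] = {}
for _f in GLOBAL_FEATURES:
    FEATURE_FAMILIES[_f] = "global"
for _f in MORPHOLOGY_FEATURES:
    FEATURE_FAMILIES[_f] = "morphology"
for _f in VORONOI_FEATURES:
    FEATURE_FAMILIES[_f] = "voronoi"
for _f in DELAUNAY_FEATURES:
    FEATURE_FAMILIES[_f] = "delaunay"

#: families describing epithelial organisation rather than tissue quantity
SPATIAL_FAMILIES = ("morphology", "voronoi", "delaunay")

DEFAULT_MIN_REGION_AREA = 50.0  # um^2; suppresses single-pixel segmentation noise


def _summary(values: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {f"{prefix}_{s}": 0.0 for s in STATS}
    out[f"{prefix}_mean"] = float(np.mean(v))
    out[f"{prefix}_median"] = float(np.median(v))
    out[f"{prefix}_sd"] = float(np.std(v))
    q1, q3 = np.percentile(v, [25.0, 75.0])
    out[f"{prefix}_iq"] = float(q3 - q1)
    out[f"{prefix}_max"] = float(np.max(v))
    return out


def extract_regions(tmap: TissueMap,
                    min_region_area: float = DEFAULT_MIN_REGION_AREA):
    """Connected epithelial components with geometry.

    Components of label 1 under 8-connectivity; those smaller than
    ``min_region_area`` (in um^2) are discarded.  Returns ``(regions,
    region_labels)`` where ``regions`` is a DataFrame with columns
    ``region_label, area_px, area, centroid_row, centroid_col, eccentricity``
    (area in um^2) and ``region_labels`` is an image whose positive values
    are the retained regions' labels, relabelled 1..n in raster order.
    """
    labeled = cc_label(tmap.labels == 1, connectivity=2)
    px_area = tmap.pixel_area_um2
    rows = []
    keep = np.zeros(labeled.max() + 1, dtype=np.int32)
    next_label = 0
    for prop in regionprops(labeled):
        area = prop.area * px_area
        if area < min_region_area:
            continue
        next_label += 1
        keep[prop.label] = next_label
        rows.append({
            "region_label": next_label,
            "area_px": int(prop.area),
            "area": float(area),
            "centroid_row": float(prop.centroid[0]),
            "centroid_col": float(prop.centroid[1]),
            "eccentricity": float(prop.eccentricity),
        })
    region_labels = keep[labeled]
    regions = pd.DataFrame(
        rows, columns=["region_label", "area_px", "area",
                       "centroid_row", "centroid_col", "eccentricity"])
    return regions, region_labels


def area_voronoi(tmap: TissueMap, region_labels: np.ndarray) -> np.ndarray:
    """Area-Voronoi influence zones of the epithelial regions.

    Every tissue pixel (labels 1-3) is assigned to the region whose pixel set
    is nearest in Euclidean distance; a region's own pixels belong to its own
    zone; ties go to the lowest region label.  Background pixels stay 0.  The
    zones partition the tissue mask.
    """
    n = int(region_labels.max())
    if n == 0:
        raise NoEpitheliumError("no epithelial regions: Voronoi undefined")
    tissue = tmap.tissue_mask()
    # squared distances are integers, so exact comparison is safe; iterating
    # labels in ascending order with a strict '<' gives ties to the lowest
    best_d2 = np.full(region_labels.shape, np.inf)
    assign = np.zeros(region_labels.shape, dtype=np.int32)
    for lab in range(1, n + 1):
        d = distance_transform_edt(region_labels != lab)
        d2 = np.rint(d * d)
        upd = tissue & (d2 < best_d2)
        assign[upd] = lab
        best_d2[upd] = d2[upd]
    return assign


def voronoi_areas(regions: pd.DataFrame, voronoi: np.ndarray,
                  pixel_area_um2: float) -> pd.DataFrame:
    """Attach each region's influence-zone area (um^2) to the region table."""
    counts = np.bincount(voronoi.ravel(), minlength=len(regions) + 1)
    out = regions.copy()
    out["voronoi_area_px"] = counts[out["region_label"].to_numpy()]
    out["voronoi_area"] = out["voronoi_area_px"] * pixel_area_um2
    return out


def voronoi_ratios(regions: pd.DataFrame) -> pd.DataFrame:
    """Region-to-zone area ratios.

    ``ratio_epi_voronoi`` = area / voronoi_area (in (0, 1]);
    ``ratio_epi_nonepi`` = area / (voronoi_area - area), undefined (NaN) when
    the region fills its zone exactly.  NaNs are excluded from summaries.
    """
    out = regions.copy()
    out["ratio_epi_voronoi"] = out["area"] / out["voronoi_area"]
    nonepi = out["voronoi_area"] - out["area"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["area"] / nonepi
    out["ratio_epi_nonepi"] = ratio.where(nonepi > 0, np.nan)
    return out


def _collinear_chain_degrees(points: np.ndarray) -> np.ndarray:
    """Degrees for degenerate centroid sets: a chain along the dominant axis."""
    n = len(points)
    if n == 1:
        return np.array([0])
    if n == 2:
        return np.array([1, 1])
    centered = points - points.mean(axis=0)
    # project onto the principal direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    deg = np.full(n, 2)
    deg[order[0]] = deg[order[-1]] = 1
    return deg


def delaunay_degrees(regions: pd.DataFrame) -> pd.DataFrame:
    """Number of Delaunay-triangulation neighbours of each region centroid.

    Fewer than 3 regions (or collinear centroids) fall back to chain
    adjacency so that small biopsies still yield features.
    """
    out = regions.copy()
    pts = out[["centroid_row", "centroid_col"]].to_numpy()
    n = len(pts)
    if n == 0:
        out["delaunay_degree"] = pd.Series(dtype=int)
        return out
    if n < 3:
        out["delaunay_degree"] = _collinear_chain_degrees(pts)
        return out
    try:
        tri = Delaunay(pts)
    except QhullError:
        out["delaunay_degree"] = _collinear_chain_degrees(pts)
        return out
    indptr, _ = tri.vertex_neighbor_vertices
    out["delaunay_degree"] = np.diff(indptr)
    return out


def extract_features(tmap: TissueMap,
                     min_region_area: float = DEFAULT_MIN_REGION_AREA) -> pd.Series:
    """The full 37-feature vector for one label map.

    Returns a Series indexed by :data:`FEATURE_NAMES` plus a trailing
    ``no_epithelium`` flag (1.0 when the slide has no retained epithelial
    region, in which case all region-based features are 0).
    """
    labels = tmap.labels
    px_area = tmap.pixel_area_um2
    class_px = np.bincount(labels.ravel(), minlength=4)
    tissue_px = int(class_px[1:].sum())
    if tissue_px == 0:
        raise EmptySlideError(f"slide {tmap.slide_id!r} has no tissue pixels")

    feats: dict[str, float] = {}
    for code, name in ((3, "fat"), (2, "stroma"), (1, "epi")):
        amount = class_px[code] * px_area
        feats[f"{name}_amount"] = float(amount)
        feats[f"{name}_amount_norm"] = float(100.0 * class_px[code] / tissue_px)

    regions, region_labels = extract_regions(tmap, min_region_area)
    feats["n_epi_regions"] = float(len(regions))
    if len(regions) == 0:
        for prefix in ("epi_area", "epi_ecc", "voronoi_area",
                       "ratio_epi_voronoi", "ratio_epi_nonepi",
                       "delaunay_neighbors"):
            feats.update({f"{prefix}_{s}": 0.0 for s in STATS})
        feats["no_epithelium"] = 1.0
    else:
        vor = area_voronoi(tmap, region_labels)
        regions = voronoi_areas(regions, vor, px_area)
        regions = voronoi_ratios(regions)
        regions = delaunay_degrees(regions)
        feats.update(_summary(regions["area"].to_numpy(), "epi_area"))
        feats.update(_summary(regions["eccentricity"].to_numpy(), "epi_ecc"))
        feats.update(_summary(regions["voronoi_area"].to_numpy(), "voronoi_area"))
        feats.update(_summary(regions["ratio_epi_voronoi"].to_numpy(),
                              "ratio_epi_voronoi"))
        feats.update(_summary(regions["ratio_epi_nonepi"].to_numpy(),
                              "ratio_epi_nonepi"))
        feats.update(_summary(regions["delaunay_degree"].to_numpy(),
                              "delaunay_neighbors"))
        feats["no_epithelium"] = 0.0

    index = list(FEATURE_NAMES) + ["no_epithelium"]
    return pd.Series([feats[k] for k in index], index=index, dtype=float)


def aggregate_patient(slide_vectors: pd.DataFrame) -> pd.Series:
    """Patient-level feature vector: per-feature median across slides."""
    if len(slide_vectors) == 0:
        raise ValueError("cannot aggregate zero slide vectors")
    return slide_vectors.median(axis=0)


def extract_cohort_features(table: pd.DataFrame, maps: dict,
                            min_region_area: float = DEFAULT_MIN_REGION_AREA):
    """Per-slide and per-patient feature tables for a cohort.

    ``table`` follows the cohort CSV schema (one row per slide); ``maps``
    maps slide_id -> TissueMap.  Returns ``(slide_df, patient_df)`` where
    ``patient_df`` carries the aggregated features joined with the
    patient-level metadata columns.
    """
    slide_rows = []
    for rec in table.itertuples(index=False):
        vec = extract_features(maps[rec.slide_id], min_region_area)
        vec["slide_id"] = rec.slide_id
        vec["patient_id"] = rec.patient_id
        slide_rows.append(vec)
    slide_df = pd.DataFrame(slide_rows).set_index("slide_id")

    feature_cols = list(FEATURE_NAMES) + ["no_epithelium"]
    agg = (slide_df.groupby("patient_id")[feature_cols]
           .median().reset_index())
    meta_cols = [c for c in ("patient_id", "split", "diagnosis", "global_fgv",
                             "localized_fgv", "bmi", "menopause")
                 if c in table.columns]
    meta = table[meta_cols].drop_duplicates("patient_id")
    patient_df = agg.merge(meta, on="patient_id", how="left")
    return slide_df.reset_index(), patient_df
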