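"""Tissue-class label maps and their on-disk representation.

Label maps are 2-D integer grids with codes 0 = background, 1 = epithelium,
2 = stroma, 3 = fat, stored as single-channel 8-bit PNG.  The physical scale
(microns per pixel) travels alongside the raster, either in a
:class:`TissueMap` or in a sidecar CSV/YAML mapping slide_id -> scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

VALID_LABELS = frozenset({0, 1, 2, 3})


@dataclass
class TissueMap:
    """One slide's tissue-class label image with its pixel scale."""

    labels: np.ndarray
    microns_per_pixel: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not set(np.unique(self.labels)).issubset(VALID_LABELS):
            raise ValueError("labels must contain only codes {0, 1, 2, 3}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.microns_per_pixel ** 2

    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


def write_map_png(tmap: TissueMap, path: str | Path) -> None:
    Image.fromarray(tmap.labels.astype(np.uint8), mode="L").save(str(path))


def read_map_png(path: str | Path, microns_per_pixel: float,
                 slide_id: str = "") -> TissueMap:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    if not slide_id:
        slide_id = Path(path).stem
    return TissueMap(labels=arr, microns_per_pixel=microns_per_pixel,
                     slide_id=slide_id)
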