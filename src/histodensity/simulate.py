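"""Synthetic tissue label-map cohorts with a known composition -> density mapping.

Whole-slide H&E sections segmented into epithelium, stroma and fat carry two
kinds of information: how much of each tissue class is present, and how the
epithelial regions are arranged in space.  This module simulates both, so that
the downstream feature extraction and modelling stages can be validated on a
cohort whose ground truth is known by construction:

* percent fibroglandular volume (FGV) is tied to tissue composition through
  the identity ``FGV = 100 x (stroma + epithelium fraction of tissue)``, i.e.
  100 x (1 - fat fraction), plus measurement noise;
* invasive patients differ from benign patients only in how their epithelium
  is organised (few large coalescent blobs vs. many dispersed small regions),
  not in how much epithelium they carry.

Label codes follow the convention 0 = background (glass), 1 = epithelium,
2 = stroma, 3 = fat.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .errors import InfeasibleCompositionError
from .io import TissueMap, write_map_png

BACKGROUND, EPITHELIUM, STROMA, FAT = 0, 1, 2, 3

#: diagnosis categories, ordered from least to most severe
DIAGNOSES = (
    "benign_nonproliferative",
    "proliferative",
    "atypia",
    "insitu",
    "invasive",
)

#: relative frequencies of the non-invasive diagnoses (quota-based assignment)
_NONINVASIVE_SHARES = {
    "benign_nonproliferative": 0.39,
    "proliferative": 0.43,
    "atypia": 0.08,
    "insitu": 0.10,
}

#: fraction of patients assigned to the training split
TRAIN_FRACTION = 0.69

CLUSTERING_MODES = ("dispersed", "clustered", "coalescent")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``fat_fraction``, ``stroma_fraction`` and ``epi_fraction`` are cohort-mean
    proportions of the *tissue* area and must sum to 1; per-patient
    compositions are drawn around them.  ``background_fraction`` is the mean
    proportion of the image that is glass; it varies per slide (biopsy
    sections fill the slide to different degrees), which is what makes
    normalised tissue quantities more informative than absolute ones.
    """

    image_height: int = 256
    image_width: int = 256
    microns_per_pixel: float = 0.5
    n_patients: int = 580
    slides_per_patient: int = 2
    fat_fraction: float = 0.45
    stroma_fraction: float = 0.45
    epi_fraction: float = 0.10
    background_fraction: float = 0.30
    epi_region_count_mean: float = 9.0
    epi_region_area_mean: float = 600.0
    epi_eccentricity_mean: float = 0.6
    clustering_mode: str = "dispersed"
    fgv_noise_sd: float = 5.0
    invasive_fraction: float = 0.15
    rng_seed: int = 0
    # secondary dials of the generative model (documented in docs/methods.md)
    composition_concentration: float = 8.0      # Beta concentration of the fat share
    epi_fraction_sd: float = 0.03               # patient-level epithelial spread
    slide_jitter_sd: float = 0.02               # slide-level composition jitter (fractions)
    local_fgv_jitter_sd: float = 0.03           # localized-vs-global fat-share perturbation
    background_jitter: float = 0.25             # half-width of the per-slide background draw

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.n_patients <= 0 or self.slides_per_patient <= 0:
            raise ValueError("counts must be positive")
        fracs = (self.fat_fraction, self.stroma_fraction, self.epi_fraction,
                 self.background_fraction, self.invasive_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        total = self.fat_fraction + self.stroma_fraction + self.epi_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"fat + stroma + epi fractions must sum to 1 (got {total!r})")
        if not 0.0 <= self.epi_eccentricity_mean < 1.0:
            raise ValueError("epi_eccentricity_mean must lie in [0, 1)")
        if self.clustering_mode not in CLUSTERING_MODES:
            raise ValueError(f"clustering_mode must be one of {CLUSTERING_MODES}")
        if self.fgv_noise_sd < 0:
            raise ValueError("fgv_noise_sd must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PatientState:
    """Per-patient draws shared by all of the patient's slides."""

    patient_id: str
    index: int
    fat_share: float          # fat / (fat + stroma), patient level
    epi_fraction: float       # epithelium fraction of tissue, patient level
    local_fat_share: float    # perturbed share defining localized FGV
    diagnosis: str
    clustering_mode: str
    split: str
    true_global_fgv: float
    true_localized_fgv: float
    bmi: float
    menopause: str
    slide_ids: list = field(default_factory=list)


def _slide_rng(config: SimulationConfig, patient_index: int, slide_index: int):
    # independent, reproducible stream per slide
    return np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed) & 0x7FFFFFFF,
                                patient_index, slide_index]))


def _composition_fgv(fat_share: float, epi_fraction: float) -> float:
    """FGV implied by composition: 100 x (1 - fat fraction of tissue)."""
    fat_fraction = fat_share * (1.0 - epi_fraction)
    return 100.0 * (1.0 - fat_fraction)


def _quota_counts(n: int, shares: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n into the given shares."""
    raw = {k: n * v for k, v in shares.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(shares, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _tissue_mask(h: int, w: int, background_fraction: float) -> np.ndarray:
    """Centered rectangular tissue region covering 1 - background_fraction."""
    if background_fraction <= 0:
        return np.ones((h, w), dtype=bool)
    side = np.sqrt(1.0 - background_fraction)
    th, tw = max(1, int(round(h * side))), max(1, int(round(w * side)))
    mask = np.zeros((h, w), dtype=bool)
    r0, c0 = (h - th) // 2, (w - tw) // 2
    mask[r0:r0 + th, c0:c0 + tw] = True
    return mask


def _draw_centers(rng, mode: str, n: int, bounds: tuple[int, int, int, int]) -> np.ndarray:
    """Region centres by point process: hard-core, Thomas, or single-cluster."""
    r0, r1, c0, c1 = bounds
    span = min(r1 - r0, c1 - c0)

    def uniform(k):
        return np.column_stack([rng.uniform(r0, r1, k), rng.uniform(c0, c1, k)])

    if mode == "dispersed":
        area = (r1 - r0) * (c1 - c0)
        d_min = 0.6 * np.sqrt(area / max(n, 1))
        centers: list[np.ndarray] = []
        d = d_min
        while len(centers) < n:
            placed = False
            for _ in range(200):
                cand = uniform(1)[0]
                if all(np.hypot(*(cand - c)) >= d for c in centers):
                    centers.append(cand)
                    placed = True
                    break
            if not placed:
                d *= 0.8  # relax the hard core rather than fail
        return np.array(centers)
    if mode == "clustered":
        n_parents = max(1, int(round(n / 3)))
        parents = uniform(n_parents)
        idx = rng.integers(0, n_parents, n)
        pts = parents[idx] + rng.normal(0.0, 0.08 * span, (n, 2))
    else:  # pragma: no cover - validated upstream
        raise ValueError(mode)
    pts[:, 0] = np.clip(pts[:, 0], r0, r1 - 1)
    pts[:, 1] = np.clip(pts[:, 1], c0, c1 - 1)
    return pts


def _coalescent_centers(rng, n: int, target_px: int,
                        bounds: tuple[int, int, int, int]) -> np.ndarray:
    """Centres for coalescent growth: blobs packed into one dense patch.

    The patch is sized so epithelium locally half-fills it; a mild hard core
    keeps several regions distinct (adjacent, occasionally merging), which is
    what drives their influence-zone ratios toward 1.
    """
    r0, r1, c0, c1 = bounds
    span = min(r1 - r0, c1 - c0)
    patch_r = min(np.sqrt(2.2 * target_px / np.pi), 0.45 * span)
    d_min = 2.0 * np.sqrt(target_px / max(n, 1) / np.pi)
    hub = np.array([rng.uniform(r0 + 0.25 * (r1 - r0), r1 - 0.25 * (r1 - r0)),
                    rng.uniform(c0 + 0.25 * (c1 - c0), c1 - 0.25 * (c1 - c0))])
    centers: list[np.ndarray] = []
    d = d_min
    while len(centers) < n:
        placed = False
        for _ in range(200):
            ang = rng.uniform(0.0, 2 * np.pi)
            rad = patch_r * np.sqrt(rng.uniform())
            cand = hub + rad * np.array([np.cos(ang), np.sin(ang)])
            if all(np.hypot(*(cand - c)) >= d for c in centers):
                centers.append(cand)
                placed = True
                break
        if not placed:
            d *= 0.8
    pts = np.array(centers)
    pts[:, 0] = np.clip(pts[:, 0], r0, r1 - 1)
    pts[:, 1] = np.clip(pts[:, 1], c0, c1 - 1)
    return pts


def _paint_epithelium(rng, tissue: np.ndarray, target_px: int, mode: str,
                      count_mean: float, ecc_mean: float) -> np.ndarray:
    """Paint elliptical epithelial blobs totalling ~target_px inside tissue."""
    h, w = tissue.shape
    rows = np.any(tissue, axis=1).nonzero()[0]
    cols = np.any(tissue, axis=0).nonzero()[0]

    n = max(1, int(rng.poisson(count_mean)))
    if mode == "coalescent":
        n = max(9, n)
        rel = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    else:
        rel = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    areas = rel / rel.sum() * target_px
    # floor the size distribution so blobs survive the downstream
    # minimum-region-area filter, then restore the total
    floor = min(250.0, 0.5 * target_px / n)
    if target_px > 4 * n:
        areas = np.maximum(areas, floor)
        areas *= target_px / areas.sum()

    # inset placement by the typical blob radius to limit edge truncation
    span = min(rows[-1] - rows[0], cols[-1] - cols[0])
    margin = 2 + int(min(np.sqrt(target_px / n / np.pi), span / 5))
    bounds = (rows[0] + margin, rows[-1] + 1 - margin,
              cols[0] + margin, cols[-1] + 1 - margin)
    eccs = np.clip(rng.normal(ecc_mean, 0.15, n), 0.0, 0.95)
    thetas = rng.uniform(0.0, np.pi, n)
    if mode == "coalescent":
        centers = _coalescent_centers(rng, n, target_px, bounds)
    else:
        centers = _draw_centers(rng, mode, n, bounds)

    scale = 1.0
    epi = np.zeros_like(tissue)
    for _ in range(5):
        epi[:] = False
        for a, e, th, (cr, cc) in zip(areas, eccs, thetas, centers):
            a = max(a * scale**2, 4.0)
            q = np.sqrt(1.0 - e**2)          # minor/major axis ratio
            major = np.sqrt(a / (np.pi * q))
            rr, cc_ = draw_ellipse(cr, cc, major * q, major,
                                   shape=(h, w), rotation=th)
            epi[rr, cc_] = True
        epi &= tissue
        realized = int(epi.sum())
        if realized == 0 or abs(realized - target_px) <= 0.01 * tissue.sum():
            break
        scale *= np.sqrt(target_px / realized)
    return epi


def generate_tissue_map(config: SimulationConfig, patient_state: PatientState,
                        slide_index: int) -> TissueMap:
    """Render one slide's label map for a patient.

    Slide-level composition jitters around the patient draw; the realized
    class fractions land within a few percentage points of the slide targets.
    """
    config.validate()
    rng = _slide_rng(config, patient_state.index, slide_index)
    h, w = config.image_height, config.image_width

    # per-slide background (sections fill the slide to varying degrees)
    if config.background_fraction > 0:
        bg = float(np.clip(
            config.background_fraction
            + rng.uniform(-config.background_jitter, config.background_jitter),
            0.03, 0.7))
    else:
        bg = 0.0
    tissue = _tissue_mask(h, w, bg)
    tissue_px = int(tissue.sum())

    # slide-level composition; exact-zero components stay exactly zero so that
    # degenerate compositions are honoured
    fat_share = patient_state.fat_share
    if 0.0 < fat_share < 1.0:
        fat_share = float(np.clip(
            fat_share + rng.normal(0.0, config.slide_jitter_sd), 0.0, 1.0))
    epi_frac = patient_state.epi_fraction
    if epi_frac > 1.0 or int(round(epi_frac * tissue_px)) > tissue_px:
        raise InfeasibleCompositionError(
            f"epithelial fraction {epi_frac} exceeds available tissue")
    if epi_frac > 0.0:
        epi_frac = float(np.clip(
            epi_frac + rng.normal(0.0, config.slide_jitter_sd / 2), 0.005, 0.6))

    target_epi_px = int(round(epi_frac * tissue_px))
    if target_epi_px > tissue_px:
        raise InfeasibleCompositionError(
            f"epithelial target {target_epi_px} px exceeds tissue area {tissue_px} px")

    labels = np.zeros((h, w), dtype=np.uint8)
    if target_epi_px > 0:
        epi = _paint_epithelium(rng, tissue, target_epi_px,
                                patient_state.clustering_mode,
                                config.epi_region_count_mean,
                                config.epi_eccentricity_mean)
    else:
        epi = np.zeros_like(tissue)
    labels[epi] = EPITHELIUM

    # fat vs stroma: threshold a smooth random field at the exact quantile so
    # the realized fat share of non-epithelial tissue matches the target
    rest = tissue & ~epi
    n_rest = int(rest.sum())
    if n_rest > 0:
        if fat_share <= 0.0:
            labels[rest] = STROMA
        elif fat_share >= 1.0:
            labels[rest] = FAT
        else:
            fld = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
            thr = np.quantile(fld[rest], 1.0 - fat_share)
            fat = rest & (fld > thr)
            labels[fat] = FAT
            labels[rest & ~fat] = STROMA

    slide_id = f"{patient_state.patient_id}_s{slide_index}"
    return TissueMap(labels=labels, microns_per_pixel=config.microns_per_pixel,
                     slide_id=slide_id)


def _draw_patients(config: SimulationConfig) -> list[PatientState]:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed) & 0x7FFFFFFF, 915]))
    n = config.n_patients

    n_invasive = int(round(config.invasive_fraction * n))
    counts = _quota_counts(n - n_invasive, _NONINVASIVE_SHARES)
    diagnoses = (["invasive"] * n_invasive
                 + [d for d, c in counts.items() for _ in range(c)])
    diagnoses = [diagnoses[i] for i in rng.permutation(n)]

    n_train = int(round(TRAIN_FRACTION * n))
    split_order = rng.permutation(n)
    splits = np.array(["test"] * n, dtype=object)
    splits[split_order[:n_train]] = "train"

    n_post = int(round(0.42 * n))
    meno = np.array(["premenopausal"] * n, dtype=object)
    meno[rng.permutation(n)[:n_post]] = "postmenopausal"

    tot = config.fat_fraction + config.stroma_fraction
    mean_share = config.fat_fraction / tot if tot > 0 else 0.0
    conc = config.composition_concentration

    patients = []
    for i in range(n):
        if mean_share <= 0.0:
            fat_share = 0.0
        elif mean_share >= 1.0:
            fat_share = 1.0
        else:
            fat_share = float(rng.beta(conc * mean_share, conc * (1 - mean_share)))
        if config.epi_fraction > 0:
            epi_frac = float(np.clip(
                rng.normal(config.epi_fraction, config.epi_fraction_sd), 0.02, 0.4))
        else:
            epi_frac = 0.0
        if 0.0 < fat_share < 1.0:
            local_share = float(np.clip(
                fat_share + rng.normal(0.0, config.local_fgv_jitter_sd), 0.0, 1.0))
        else:
            local_share = fat_share

        g = _composition_fgv(fat_share, epi_frac)
        l = _composition_fgv(local_share, epi_frac)
        if config.fgv_noise_sd > 0:
            g += rng.normal(0.0, config.fgv_noise_sd)
            l += rng.normal(0.0, config.fgv_noise_sd)
        g = float(np.clip(g, 0.0, 100.0))
        l = float(np.clip(l, 0.0, 100.0))

        diagnosis = diagnoses[i]
        if diagnosis == "invasive":
            mode = "coalescent"
        elif diagnosis == "insitu":
            mode = "clustered"
        else:
            mode = config.clustering_mode

        bmi = float(np.clip(27.0 - 0.12 * (g - 35.0) + rng.normal(0.0, 4.0),
                            16.0, 55.0))
        patients.append(PatientState(
            patient_id=f"P{i:04d}", index=i, fat_share=fat_share,
            epi_fraction=epi_frac, local_fat_share=local_share,
            diagnosis=diagnosis, clustering_mode=mode, split=str(splits[i]),
            true_global_fgv=g, true_localized_fgv=l, bmi=bmi,
            menopause=str(meno[i])))
    return patients


def generate_cohort(config: SimulationConfig, out_dir: str | Path | None = None):
    """Generate the full synthetic cohort.

    Returns ``(table, maps)`` where ``table`` is a per-slide pandas DataFrame
    with columns ``patient_id, slide_id, path, split, diagnosis, global_fgv,
    localized_fgv, bmi, menopause`` and ``maps`` maps slide_id -> TissueMap.
    When ``out_dir`` is given, label maps are written as 8-bit PNGs under
    ``out_dir/maps`` and the table as ``out_dir/cohort.csv``.
    """
    import pandas as pd

    config.validate()
    if config.n_patients < 10:
        raise ValueError("n_patients < 10: downstream models are meaningless")

    patients = _draw_patients(config)
    rows, maps = [], {}
    maps_dir = None
    if out_dir is not None:
        maps_dir = Path(out_dir) / "maps"
        maps_dir.mkdir(parents=True, exist_ok=True)

    for p in patients:
        for s in range(config.slides_per_patient):
            tmap = generate_tissue_map(config, p, s)
            maps[tmap.slide_id] = tmap
            path = ""
            if maps_dir is not None:
                # stored relative to the cohort directory so artifacts are
                # location-independent (and reruns byte-identical)
                path = f"maps/{tmap.slide_id}.png"
                write_map_png(tmap, maps_dir / f"{tmap.slide_id}.png")
            p.slide_ids.append(tmap.slide_id)
            rows.append({
                "patient_id": p.patient_id, "slide_id": tmap.slide_id,
                "path": path, "split": p.split, "diagnosis": p.diagnosis,
                "global_fgv": p.true_global_fgv,
                "localized_fgv": p.true_localized_fgv,
                "bmi": p.bmi, "menopause": p.menopause,
            })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "cohort.csv", index=False)
        config.to_yaml(Path(out_dir) / "config.yaml")
    return table, maps


def cohort_checksum(table, maps) -> str:
    """SHA-256 digest over the cohort table and every map's raw bytes."""
    h = hashlib.sha256()
    h.update(table.to_csv(index=False).encode())
    for sid in sorted(maps):
        h.update(sid.encode())
        h.update(maps[sid].labels.tobytes())
    return h.hexdigest()
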