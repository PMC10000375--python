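"""Lesion candidate detection and the fixed-schema feature vector.

Candidates are found by robust color thresholds: dark-red lesions
(microaneurysms, hemorrhages) are outliers below the green-channel
median by several MADs; bright lesions (hard exudates) are luminance
outliers with a yellow cast (red+green high, blue low).  Vessel and disc
pixels are excluded before connected-component labelling, and a size gate
separates microaneurysms (small) from hemorrhages.

The feature vector has a fixed schema: lesion counts per type, total
lesion area fraction, macular lesion count, shape statistics (mean
eccentricity, mean circularity), an 8-bin orientation histogram of region
major axes, color statistics (mean/std of RGB and HSV channels inside
lesions and over background) and vessel density.  All entries are finite
and aggregate over candidates, so the vector is invariant to candidate
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from .segmentation import VesselSegmentation

__all__ = [
    "CandidateParams",
    "LesionRegion",
    "LesionCandidates",
    "detect_candidates",
    "compute_features",
    "cosine_similarity",
    "feature_names",
    "FEATURE_SCHEMA_VERSION",
]

FEATURE_SCHEMA_VERSION = "1"

_N_ORIENT_BINS = 8


@dataclass
class CandidateParams:
    """Detection thresholds; defaults tuned once against the synthetic
    generator and frozen."""

    dark_k: float = 6.0            # MADs below green median for red lesions
    bright_k: float = 6.0          # MADs above luminance median for exudates
    yellow_margin: float = 0.12    # (R+G)/2 - B margin for exudates, [0,1] units
    ma_max_area: float = 30.0      # px^2; larger red lesions become hemorrhages
    max_area: float = 600.0        # reject implausibly large components
    min_area: float = 2.0
    vessel_dilate: int = 1         # exclusion-margin around vessels, px


@dataclass
class LesionRegion:
    pixels: np.ndarray            # (n, 2) row/col coordinates
    type_hypothesis: str          # MA | HE | EX
    centroid: tuple[float, float]
    area: float
    eccentricity: float
    orientation: float            # radians, major axis vs row axis
    mean_color: np.ndarray        # RGB in [0, 1]
    circularity: float


@dataclass
class LesionCandidates:
    regions: list[LesionRegion] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for r in self.regions if r.type_hypothesis == kind)

    def __len__(self) -> int:
        return len(self.regions)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med))) * 1.4826


def detect_candidates(
    image: np.ndarray,
    segmentation: VesselSegmentation,
    params: CandidateParams | None = None,
) -> LesionCandidates:
    """Detect lesion candidate regions outside vessels and the optic disc."""
    params = params or CandidateParams()
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1:
        img = img / 255.0
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    lum = img.mean(axis=2)
    h, w = lum.shape

    exclude = segmentation.disc_mask.copy()
    if segmentation.vessel_mask is not None:
        exclude |= morphology.dilation(
            segmentation.vessel_mask, morphology.disk(params.vessel_dilate)
        )
    # stay inside the illuminated field of view
    aperture = morphology.erosion(lum > 0.06, morphology.disk(max(2, int(0.02 * min(h, w)))))
    valid = aperture & ~exclude
    if not valid.any():
        return LesionCandidates()

    g_med, g_mad = np.median(g[valid]), max(_mad(g[valid]), 0.01)
    l_med, l_mad = np.median(lum[valid]), max(_mad(lum[valid]), 0.01)

    dark = (g < g_med - params.dark_k * g_mad) & valid
    yellow = (r + g) / 2.0 - b > params.yellow_margin
    bright = (lum > l_med + params.bright_k * l_mad) & yellow & valid

    regions: list[LesionRegion] = []
    for mask, kinds in ((dark, ("MA", "HE")), (bright, ("EX", "EX"))):
        labels = measure.label(mask, connectivity=2)
        for prop in measure.regionprops(labels):
            if not params.min_area <= prop.area <= params.max_area:
                continue
            kind = kinds[0] if prop.area <= params.ma_max_area else kinds[1]
            pix = prop.coords
            circ = 4 * np.pi * prop.area / max(prop.perimeter, 1.0) ** 2
            regions.append(
                LesionRegion(
                    pixels=pix,
                    type_hypothesis=kind,
                    centroid=prop.centroid,
                    area=float(prop.area),
                    eccentricity=float(prop.eccentricity),
                    orientation=float(prop.orientation),
                    mean_color=img[pix[:, 0], pix[:, 1]].mean(axis=0),
                    circularity=float(min(circ, 1.5)),
                )
            )
    return LesionCandidates(regions=regions)


def _estimate_macula_mask(segmentation: VesselSegmentation, shape) -> np.ndarray:
    """Macula estimate from disc geometry: fovea 2.5 disc diameters temporal
    (toward the image centre), macular radius one disc diameter."""
    h, w = shape
    disc = segmentation.disc_mask
    if disc is None or not disc.any():
        # fall back to the image centre with a nominal radius
        cy, cx, rad = h / 2.0, w / 2.0, 0.14 * min(h, w)
    else:
        ys, xs = np.nonzero(disc)
        cy, cx = ys.mean(), xs.mean()
        disc_diam = 2.0 * np.sqrt(disc.sum() / np.pi)
        direction = 1.0 if cx < w / 2 else -1.0
        cx = cx + direction * 2.5 * disc_diam
        rad = disc_diam
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2


def feature_names() -> list[str]:
    names = [
        "ma_count",
        "he_count",
        "ex_count",
        "lesion_area_fraction",
        "macular_lesion_count",
        "mean_eccentricity",
        "mean_circularity",
    ]
    names += [f"orientation_bin_{i}" for i in range(_N_ORIENT_BINS)]
    for region in ("lesion", "background"):
        for ch in ("r", "g", "b", "h", "s", "v"):
            names += [f"{region}_{ch}_mean", f"{region}_{ch}_std"]
    names.append("vessel_density")
    return names


def compute_features(
    image: np.ndarray,
    candidates: LesionCandidates,
    segmentation: VesselSegmentation,
    macula_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Fill the fixed feature schema; deterministic, length ``len(feature_names())``."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1:
        img = img / 255.0
    h, w = img.shape[:2]
    hsv = skcolor.rgb2hsv(img)
    stacked = np.concatenate([img, hsv], axis=2)  # 6 channels

    if macula_mask is None:
        macula_mask = _estimate_macula_mask(segmentation, (h, w))

    lesion_mask = np.zeros((h, w), dtype=bool)
    macular_count = 0
    eccs, circs, orients = [], [], []
    for region in candidates.regions:
        lesion_mask[region.pixels[:, 0], region.pixels[:, 1]] = True
        ry, rx = int(round(region.centroid[0])), int(round(region.centroid[1]))
        if 0 <= ry < h and 0 <= rx < w and macula_mask[ry, rx]:
            macular_count += 1
        eccs.append(region.eccentricity)
        circs.append(region.circularity)
        orients.append(region.orientation)

    vec = [
        float(candidates.count("MA")),
        float(candidates.count("HE")),
        float(candidates.count("EX")),
        float(lesion_mask.mean()),
        float(macular_count),
        float(np.mean(eccs)) if eccs else 0.0,
        float(np.mean(circs)) if circs else 0.0,
    ]
    hist = np.zeros(_N_ORIENT_BINS)
    if orients:
        # major-axis angles folded onto [0, pi)
        ang = np.mod(np.asarray(orients), np.pi)
        hist, _ = np.histogram(ang, bins=_N_ORIENT_BINS, range=(0, np.pi))
    vec.extend(hist.astype(float))

    background = ~lesion_mask
    for mask in (lesion_mask, background):
        for ch in range(6):
            vals = stacked[..., ch][mask]
            if vals.size:
                vec.extend([float(vals.mean()), float(vals.std())])
            else:
                vec.extend([0.0, 0.0])
    vessel_density = (
        float(segmentation.vessel_mask.mean()) if segmentation.vessel_mask is not None else 0.0
    )
    vec.append(vessel_density)
    out = np.asarray(vec, dtype=float)
    assert np.all(np.isfinite(out))
    return out


def cosine_similarity(i: np.ndarray, j: np.ndarray) -> float:
    """dot(i, j) / (||i|| * ||j||); raises on zero-norm input."""
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    if i.shape != j.shape:
        raise ValueError(f"dimension mismatch: {i.shape} vs {j.shape}")
    ni, nj = np.linalg.norm(i), np.linalg.norm(j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(i, j) / (ni * nj))
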