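"""Synthetic labeled fundus images.

Generates RGB retina-like images with full ground truth so that every
downstream stage (denoising, enhancement, vessel segmentation, lesion
detection, classification, severity grading) is testable without any
external dataset.  The scene model:

* a circular fundus aperture over a reddish-orange radial background;
* a bright optic disc at mid-height on the nasal (left) side;
* the macula centred on the fovea, 2.5 disc diameters temporal to the
  disc, with macular radius equal to one disc diameter;
* a recursive binary vessel tree rooted at the disc centre (child width
  0.7x parent, branch angle jitter uniform +/-25 degrees), guaranteeing a
  connected vessel mask that touches the disc;
* lesions: microaneurysms (small sharp dark-red discs, radius 1-3 px),
  hemorrhages (irregular dark-red polygons) and hard exudates (bright
  yellow blobs); DME images place at least one exudate inside the macula;
* corruption applied after rendering: Gaussian blur, a multiplicative
  linear illumination ramp, then salt-and-pepper impulse noise.

Everything is driven by a single integer seed; regenerating from the same
spec yields a byte-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

__all__ = [
    "CLASS_NAMES",
    "LESION_TYPES",
    "FundusSpec",
    "LabeledFundus",
    "generate_fundus",
    "generate_labeled_set",
    "generate_dataset",
    "corrupt",
    "severity_from_count",
]

CLASS_NAMES = ("normal", "DR", "DME")
LESION_TYPES = ("MA", "HE", "EX")

#: lesion-count severity bands used for fixture labels
SEVERITY_BANDS = {"mild": (1, 3), "moderate": (4, 9), "severe": (10, None)}


@dataclass
class FundusSpec:
    """Generation parameters for one synthetic fundus image."""

    height: int = 224
    width: int = 224
    class_label: str = "normal"
    n_microaneurysms: int = 0
    n_hemorrhages: int = 0
    n_exudates: int = 0
    vessel_depth: int = 5
    noise_density: float = 0.01
    illumination_strength: float = 0.3
    blur_sigma: float = 0.5
    seed: int = 0


@dataclass
class LabeledFundus:
    """A synthetic fundus image with its full ground truth."""

    image: np.ndarray                      # HxWx3 uint8
    vessel_mask: np.ndarray                # HxW bool
    disc_mask: np.ndarray
    macula_mask: np.ndarray
    lesion_masks: dict[str, np.ndarray]    # lesion type -> HxW bool
    class_label: str
    severity_label: str | None
    spec: FundusSpec
    fovea: tuple[float, float] = (0.0, 0.0)
    clean_image: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_lesions(self) -> int:
        return (
            self.spec.n_microaneurysms + self.spec.n_hemorrhages + self.spec.n_exudates
        )


def severity_from_count(count: int) -> str | None:
    """Map a total lesion count to the fixture severity bands."""
    if count <= 0:
        return None
    if count <= SEVERITY_BANDS["mild"][1]:
        return "mild"
    if count <= SEVERITY_BANDS["moderate"][1]:
        return "moderate"
    return "severe"


def _validate(spec: FundusSpec) -> None:
    if spec.height < 64:
        raise ValueError(f"height must be >= 64, got {spec.height}")
    if spec.width < 64:
        raise ValueError(f"width must be >= 64, got {spec.width}")
    if spec.class_label not in CLASS_NAMES:
        raise ValueError(f"class_label must be one of {CLASS_NAMES}, got {spec.class_label!r}")
    for name in ("n_microaneurysms", "n_hemorrhages", "n_exudates"):
        if getattr(spec, name) < 0:
            raise ValueError(f"{name} must be >= 0, got {getattr(spec, name)}")
    if not 0.0 <= spec.noise_density <= 1.0:
        raise ValueError(f"noise_density must lie in [0, 1], got {spec.noise_density}")
    if spec.illumination_strength < 0:
        raise ValueError(
            f"illumination_strength must be >= 0, got {spec.illumination_strength}"
        )
    if spec.blur_sigma < 0:
        raise ValueError(f"blur_sigma must be >= 0, got {spec.blur_sigma}")
    if spec.vessel_depth < 1:
        raise ValueError(f"vessel_depth must be >= 1, got {spec.vessel_depth}")
    total = spec.n_microaneurysms + spec.n_hemorrhages + spec.n_exudates
    if spec.class_label == "normal" and total != 0:
        raise ValueError("class_label 'normal' requires all lesion counts to be 0")
    if spec.class_label == "DME" and spec.n_exudates < 1:
        raise ValueError("class_label 'DME' requires n_exudates >= 1")
    if spec.class_label == "DR" and total < 1:
        raise ValueError("class_label 'DR' requires at least one lesion")


def _geometry(h: int, w: int):
    """Aperture / disc / fovea geometry shared by rendering and masks."""
    s = min(h, w)
    aperture_c = (h / 2.0, w / 2.0)
    aperture_r = 0.49 * s
    disc_r = 0.07 * s
    disc_c = (h / 2.0, 0.15 * w)
    fovea = (h / 2.0, disc_c[1] + 2.5 * (2 * disc_r))  # 2.5 disc diameters temporal
    macula_r = 2.0 * disc_r                            # one disc diameter
    return aperture_c, aperture_r, disc_c, disc_r, fovea, macula_r


def _disk_mask(h, w, center, radius):
    yy, xx = np.ogrid[:h, :w]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _vessel_tree(
    mask: np.ndarray,
    rng: np.random.Generator,
    start: tuple[float, float],
    angle: float,
    depth: int,
    width: float,
    seg_len: float,
) -> None:
    """Recursively draw one vessel branch; children connect at the endpoint."""
    h, w = mask.shape
    if depth <= 0:
        return
    end = (
        float(np.clip(start[0] + seg_len * np.sin(angle), 0, h - 1)),
        float(np.clip(start[1] + seg_len * np.cos(angle), 0, w - 1)),
    )
    rr, cc = draw.line(int(round(start[0])), int(round(start[1])),
                       int(round(end[0])), int(round(end[1])))
    half = max(0, int(round(width / 2)) - 1)
    for dy in range(-half, half + 1):
        yy = np.clip(rr + dy, 0, h - 1)
        mask[yy, cc] = True
        mask[rr, np.clip(cc + dy, 0, w - 1)] = True
    jitter = np.deg2rad(25.0)
    for sign in (-1.0, 1.0):
        child_angle = angle + sign * np.deg2rad(20.0) + rng.uniform(-jitter, jitter)
        _vessel_tree(mask, rng, end, child_angle, depth - 1, width * 0.7, seg_len * 0.85)


def _place_in_region(rng, center, radius, n=1):
    """Uniform points within a disc of given centre/radius."""
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.stack([center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)], axis=1)


def _irregular_blob(rng, center, r_lo, r_hi, shape):
    """Pixel coordinates of an irregular polygon around ``center``."""
    n_vert = rng.integers(6, 11)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = rng.uniform(r_lo, r_hi, n_vert)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return draw.polygon(rows, cols, shape=shape)


def corrupt(
    image: np.ndarray,
    noise_density: float,
    illumination_strength: float,
    blur_sigma: float,
    seed: int,
) -> np.ndarray:
    """Degrade an 8-bit RGB image: blur, illumination ramp, impulse noise.

    Exactly ``round(noise_density * H * W)`` pixels are set to 0 or 255
    (uniform choice per pixel, all channels).  The illumination ramp is a
    multiplicative linear gradient across the image width.  With all three
    parameters at zero the input is returned unchanged.
    """
    if not 0.0 <= noise_density <= 1.0:
        raise ValueError(f"noise_density must lie in [0, 1], got {noise_density}")
    img = np.asarray(image)
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed)
    out = img.astype(np.float64)
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=(blur_sigma, blur_sigma, 0))
    if illumination_strength > 0:
        ramp = 1.0 + illumination_strength * (np.arange(w) / max(w - 1, 1) - 0.5)
        out = out * ramp[None, :, None]
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    k = int(round(noise_density * h * w))
    if k > 0:
        flat = rng.choice(h * w, size=k, replace=False)
        vals = rng.integers(0, 2, size=k, dtype=np.uint8) * 255
        out.reshape(-1, img.shape[2])[flat] = vals[:, None]
    return out


def generate_fundus(spec: FundusSpec) -> LabeledFundus:
    """Render one labeled synthetic fundus image from a spec.

    Lesions are rendered on the clean retina before corruption, so the
    returned masks mark true lesion support.  Fully deterministic in
    ``spec.seed``.
    """
    _validate(spec)
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    aperture_c, aperture_r, disc_c, disc_r, fovea, macula_r = _geometry(h, w)

    yy, xx = np.mgrid[:h, :w]
    dist = np.hypot(yy - aperture_c[0], xx - aperture_c[1]) / aperture_r
    aperture = dist <= 1.0

    # background: reddish-orange radial gradient with mild smooth texture
    t = np.clip(dist, 0, 1)[..., None]
    inner = np.array([0.82, 0.44, 0.26])
    outer = np.array([0.62, 0.28, 0.16])
    img = inner * (1 - t) + outer * t
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6)
    img += 0.02 * texture[..., None]
    img[~aperture] = 0.02

    # macula: gentle darkening around the fovea
    macula_mask = _disk_mask(h, w, fovea, macula_r)
    fovea_dist = np.hypot(yy - fovea[0], xx - fovea[1]) / macula_r
    shade = 1.0 - 0.18 * np.exp(-(fovea_dist**2))
    img *= shade[..., None]

    # optic disc: bright compact region, slightly soft edge
    disc_mask = _disk_mask(h, w, disc_c, disc_r)
    disc_soft = ndimage.gaussian_filter(disc_mask.astype(float), sigma=1.0)
    disc_color = np.array([0.96, 0.87, 0.62])
    img = img * (1 - disc_soft[..., None]) + disc_color * disc_soft[..., None]

    # vessel tree rooted at the disc centre
    vessel_mask = np.zeros((h, w), dtype=bool)
    trunk_width = max(2.0, 0.016 * min(h, w))
    seg_len = 0.16 * min(h, w)
    for trunk_angle in (-1.1, -0.45, 0.45, 1.1):  # radians, fanning temporally
        _vessel_tree(
            vessel_mask, rng, disc_c, trunk_angle, spec.vessel_depth, trunk_width, seg_len
        )
    vessel_mask &= aperture
    # branches may exit the aperture and re-enter; keep only the component
    # connected to the disc so the mask invariant holds
    lab, _ = ndimage.label(vessel_mask | disc_mask, structure=np.ones((3, 3)))
    disc_labels = np.unique(lab[disc_mask])
    vessel_mask &= np.isin(lab, disc_labels[disc_labels > 0])
    vessel_soft = ndimage.gaussian_filter(vessel_mask.astype(float), sigma=0.6)
    vessel_soft = np.clip(vessel_soft / max(vessel_soft.max(), 1e-9), 0, 1)
    vessel_color = np.array([0.38, 0.10, 0.10])
    img = img * (1 - 0.9 * vessel_soft[..., None]) + vessel_color * 0.9 * vessel_soft[..., None]

    # lesions
    lesion_masks = {t_: np.zeros((h, w), dtype=bool) for t_ in LESION_TYPES}
    safe_r = aperture_r * 0.92

    def _lesion_centers(n: int) -> np.ndarray:
        pts = []
        while len(pts) < n:
            cand = _place_in_region(rng, aperture_c, safe_r)[0]
            if not disc_mask[int(cand[0]), int(cand[1])]:
                pts.append(cand)
        return np.array(pts) if pts else np.empty((0, 2))

    # microaneurysms: sharp dark-red discs, radius 1-3 px
    for cy, cx in _lesion_centers(spec.n_microaneurysms):
        rr, cc = draw.disk((cy, cx), rng.uniform(1.0, 3.0), shape=(h, w))
        lesion_masks["MA"][rr, cc] = True
        img[rr, cc] = [0.30, 0.05, 0.05]

    # hemorrhages: irregular dark-red polygons
    for cy, cx in _lesion_centers(spec.n_hemorrhages):
        rr, cc = _irregular_blob(rng, (cy, cx), 3.0, 8.0, (h, w))
        lesion_masks["HE"][rr, cc] = True
        img[rr, cc] = [0.26, 0.04, 0.06]

    # hard exudates: bright yellowish-white blobs; for DME the first ones
    # are placed inside the macular radius of the fovea
    n_ex = spec.n_exudates
    if n_ex:
        centers = []
        if spec.class_label == "DME":
            n_macular = max(1, int(np.ceil(n_ex / 2)))
            centers.extend(_place_in_region(rng, fovea, macula_r * 0.8, n_macular))
            centers.extend(_lesion_centers(n_ex - n_macular))
        else:
            centers.extend(_lesion_centers(n_ex))
        for cy, cx in centers:
            rr, cc = _irregular_blob(rng, (cy, cx), 1.5, 5.0, (h, w))
            lesion_masks["EX"][rr, cc] = True
            img[rr, cc] = [0.97, 0.93, 0.60]

    clean = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
    corrupted = corrupt(
        clean,
        spec.noise_density,
        spec.illumination_strength,
        spec.blur_sigma,
        seed=spec.seed + 1,
    )

    total = spec.n_microaneurysms + spec.n_hemorrhages + spec.n_exudates
    return LabeledFundus(
        image=corrupted,
        vessel_mask=vessel_mask,
        disc_mask=disc_mask,
        macula_mask=macula_mask,
        lesion_masks=lesion_masks,
        class_label=spec.class_label,
        severity_label=severity_from_count(total) if spec.class_label != "normal" else None,
        spec=spec,
        fovea=fovea,
        clean_image=clean,
    )


def _class_spec(cls: str, rng: np.random.Generator, size: int, seed: int, **kw) -> FundusSpec:
    """Draw per-class lesion counts: DR carries red lesions, DME macular
    exudates plus a few microaneurysms, normal none."""
    if cls == "normal":
        counts = dict(n_microaneurysms=0, n_hemorrhages=0, n_exudates=0)
    elif cls == "DR":
        counts = dict(
            n_microaneurysms=int(rng.integers(1, 11)),
            n_hemorrhages=int(rng.integers(0, 5)),
            n_exudates=0,
        )
    else:  # DME
        counts = dict(
            n_microaneurysms=int(rng.integers(0, 5)),
            n_hemorrhages=int(rng.integers(0, 3)),
            n_exudates=int(rng.integers(1, 7)),
        )
    return FundusSpec(height=size, width=size, class_label=cls, seed=seed, **counts, **kw)


def generate_labeled_set(
    n_per_class: int, base_seed: int, size: int = 224, **spec_kw
) -> list[LabeledFundus]:
    """In-memory dataset: ``n_per_class`` images per class, deterministic."""
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    out = []
    meta = np.random.default_rng(base_seed)
    for cls in CLASS_NAMES:
        for _ in range(n_per_class):
            seed = int(meta.integers(0, 2**31 - 1))
            out.append(generate_fundus(_class_spec(cls, meta, size, seed, **spec_kw)))
    return out


def generate_dataset(
    n_per_class: int, base_seed: int, out_dir: str | Path, size: int = 224, **spec_kw
) -> pd.DataFrame:
    """Write a PNG + CSV dataset and return the manifest records.

    Layout: ``<out_dir>/images/*.png``, ``<out_dir>/masks/<name>_<kind>.png``
    (masks stored as 0/255 single-channel PNG) and ``<out_dir>/manifest.csv``
    with header ``filename,class_label,severity,ma_count,he_count,ex_count,seed``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for lf in generate_labeled_set(n_per_class, base_seed, size=size, **spec_kw):
        name = f"{lf.class_label}_{lf.spec.seed:010d}"
        iio.imwrite(out / "images" / f"{name}.png", lf.image)
        for kind, mask in (
            ("vessel", lf.vessel_mask),
            ("disc", lf.disc_mask),
            ("macula", lf.macula_mask),
            *((f"lesion_{t_}", m) for t_, m in lf.lesion_masks.items()),
        ):
            iio.imwrite(out / "masks" / f"{name}_{kind}.png",
                        (mask.astype(np.uint8) * 255))
        records.append(
            {
                "filename": f"images/{name}.png",
                "class_label": lf.class_label,
                "severity": lf.severity_label or "none",
                "ma_count": lf.spec.n_microaneurysms,
                "he_count": lf.spec.n_hemorrhages,
                "ex_count": lf.spec.n_exudates,
                "seed": lf.spec.seed,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
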