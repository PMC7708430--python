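"""Seeded synthetic H&E-like image generator with exact ground truth.

Real murine pancreas sections are not shippable test fixtures, so this module
fabricates images that reproduce the *statistical* structure the segmentation
pipeline relies on, with a pixel-exact label map by construction:

* spatially coherent tissue classes (normal acinar, ADM, dysplasia, stromal
  "other") with deliberately distinct colour and texture statistics,
* a white background (all channels > 200) surrounding the tissue,
* ring-shaped ductal lesions whose lumina are background-coloured holes,
* smooth multiplicative staining gradients within an image and per-channel
  colour shifts between images, plus additive Gaussian pixel noise,
* matched binarised immunofluorescence channels: AMY marks acinar tissue,
  panK marks ADM and dysplasia, DAPI marks all cellular tissue.

Class palette (a documented free choice — the generator makes classes
separable primarily by colour, with texture as a secondary cue, so that a
small network can learn them):

====================  =================  =============================
class                 base RGB           texture
====================  =================  =============================
acinar                (170, 100, 160)    dense dark-purple speckle
ADM wall              (110, 120, 190)    thin ring, faint banding
dysplasia wall        (185,  70, 110)    thick wobbly ring
other (stroma)        (225, 170, 195)    diffuse low-amplitude fibres
background / lumen    (245, 245, 245)    none (always > 200 pre-noise)
====================  =================  =============================

Photorealism is an explicit non-goal; exactness of the ground truth and
controllability of class area fractions are the design targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

# ---------------------------------------------------------------------------
# label codes (shared by the whole package)
# ---------------------------------------------------------------------------

BACKGROUND, OTHER, ACINAR, ADM, DYSPLASIA = 0, 1, 2, 3, 4
LABEL_CODES = {
    "background": BACKGROUND,
    "other": OTHER,
    "acinar": ACINAR,
    "adm": ADM,
    "dysplasia": DYSPLASIA,
}
CLASS_NAMES = ("other", "acinar", "adm", "dysplasia")  # cellular classes
DUCTAL_CLASSES = ("adm", "dysplasia")

_PALETTE = {
    ACINAR: (170.0, 100.0, 160.0),
    ADM: (110.0, 120.0, 190.0),
    DYSPLASIA: (185.0, 70.0, 110.0),
    OTHER: (225.0, 170.0, 195.0),
}
_SPECKLE_RGB = (80.0, 50.0, 120.0)
_BACKGROUND_VALUE = 245.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic section.

    ``target_fractions`` are fractions of the *cellular* (non-background)
    area and should sum to 1; sums below 1 are renormalised for the class
    quota split and the shortfall stays white background.
    """

    image_height: int = 256
    image_width: int = 256
    target_fractions: dict = field(
        default_factory=lambda: {
            "acinar": 0.45,
            "adm": 0.20,
            "dysplasia": 0.15,
            "other": 0.20,
        }
    )
    n_lesions: int = 6  # per ductal class
    lumen_fraction: float = 0.25  # of each ductal lesion disk
    unevenness_amplitude: float = 0.15
    color_shift: tuple = (0.0, 0.0, 0.0)
    noise_sigma: float = 4.0
    seed: int = 0
    tissue_coverage: float = 0.72  # planned tissue fraction of the frame

    def validate(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image must be at least 8x8 pixels")
        fr = self.target_fractions
        unknown = set(fr) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in target_fractions: {unknown}")
        vals = [float(fr.get(c, 0.0)) for c in CLASS_NAMES]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("target fractions must lie in [0, 1]")
        if sum(vals) > 1.0 + 1e-9:
            raise ValueError("target fractions must sum to at most 1")
        if not (0.0 <= self.lumen_fraction < 1.0):
            raise ValueError("lumen_fraction must lie in [0, 1)")
        if not (0.0 <= self.unevenness_amplitude <= 0.5):
            raise ValueError("unevenness_amplitude must lie in [0, 0.5]")
        if any(abs(s) > 0.25 for s in self.color_shift):
            raise ValueError("color_shift components must lie in [-0.25, 0.25]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")


@dataclass
class SyntheticSample:
    """A generated image plus its exact ground truth and IF channels."""

    image: np.ndarray  # H x W x 3 uint8
    truth: np.ndarray  # H x W uint8 label codes
    if_amy: np.ndarray  # H x W bool, == (truth == ACINAR)
    if_pank: np.ndarray  # H x W bool, == (truth in {ADM, DYSPLASIA})
    if_dapi: np.ndarray  # H x W bool, == (truth != BACKGROUND)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited Gaussian random field, zero mean, unit-ish scale."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _top_k_mask(field: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting exactly the k largest-valued pixels."""
    if k <= 0:
        return np.zeros(field.shape, bool)
    flat = field.ravel()
    idx = np.argpartition(flat, flat.size - k)[flat.size - k:]
    mask = np.zeros(flat.size, bool)
    mask[idx] = True
    return mask.reshape(field.shape)


def _place_lesions(
    rng: np.random.Generator,
    tissue: np.ndarray,
    occupied: np.ndarray,
    n_lesions: int,
    wall_quota: int,
    lumen_fraction: float,
    wobble: float,
):
    """Place ring lesions near `tissue`; returns (wall_mask, lumen_mask).

    Each lesion is a disk of radius r with an inner lumen disk; r is sized so
    n_lesions rings together cover wall_quota pixels.  The disk boundary is
    modulated by a low-order angular wobble (papillary look for dysplasia).
    Centres are drawn from tissue pixels; a lesion only needs to fit inside
    the frame and avoid previously placed lesions, so rings near the tissue
    edge may bulge into the background (as real ducts at a section margin
    do).  If the nominal count under-fills the quota — dense packings can
    fail — extra smaller rings are added until the quota is met.  Raises if
    the frame cannot hold even one lesion.
    """
    H, W = tissue.shape
    wall = np.zeros((H, W), bool)
    lumen = np.zeros((H, W), bool)
    if n_lesions == 0 or wall_quota <= 0:
        return wall, lumen
    area_per = wall_quota / n_lesions / max(1.0 - lumen_fraction, 1e-6)
    r0 = float(np.sqrt(area_per / np.pi))
    if 2 * r0 * (1 + wobble) + 2 > min(H, W):
        raise ValueError(
            f"image ({H}x{W}) is smaller than one lesion diameter ({2 * r0:.0f}px)"
        )
    rows, cols = np.mgrid[0:H, 0:W]
    cand = np.flatnonzero(tissue.ravel())
    if cand.size == 0:
        return wall, lumen

    def try_place(r: float) -> bool:
        for _ in range(80):
            c = cand[rng.integers(cand.size)]
            cy, cx = divmod(int(c), W)
            rmax = r * (1 + wobble)
            if cy < rmax or cx < rmax or cy > H - 1 - rmax or cx > W - 1 - rmax:
                continue
            dy, dx = rows - cy, cols - cx
            dist = np.hypot(dy, dx)
            if wobble > 0:
                k = int(rng.integers(3, 6))
                phase = rng.uniform(0, 2 * np.pi)
                dist = dist * (1.0 + wobble * np.sin(k * np.arctan2(dy, dx) + phase))
            disk = dist <= r
            if np.any(disk & occupied):
                continue
            lum = dist <= r * np.sqrt(lumen_fraction)
            wall[disk & ~lum] = True
            lumen[lum] = True
            occupied[disk] = True
            return True
        return False

    r = r0
    placed = 0
    while placed < n_lesions and r >= 2.0:
        if try_place(r):
            placed += 1
        else:
            r *= 0.8  # shrink and keep trying — packing got tight
    # top up the area quota with smaller rings if the packing fell short
    r = max(r0 * 0.5, 3.0)
    for _ in range(4 * n_lesions + 8):
        if int(wall.sum()) >= wall_quota or r < 2.0:
            break
        if not try_place(r):
            r *= 0.8
    return wall, lumen


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Generate one synthetic section; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    fr = {c: float(spec.target_fractions.get(c, 0.0)) for c in CLASS_NAMES}
    total = sum(fr.values())
    if total > 0:
        fr = {c: v / total for c, v in fr.items()}

    # organic tissue mask with an exact pixel count
    n_plan = int(round(spec.tissue_coverage * total * H * W))
    tissue = _top_k_mask(_smooth_field(rng, (H, W), min(H, W) / 12), n_plan)

    # cellular budget D accounting for lumina carved out of ductal lesions:
    # walls + lumina + acinar + other must exhaust the planned tissue area.
    lf = {"adm": spec.lumen_fraction, "dysplasia": min(0.95, spec.lumen_fraction * 1.6)}
    lumen_load = sum(fr[c] * lf[c] / (1.0 - lf[c]) for c in DUCTAL_CLASSES)
    D = n_plan / (1.0 + lumen_load)
    quota = {c: int(round(fr[c] * D)) for c in CLASS_NAMES}

    truth = np.zeros((H, W), np.uint8)
    occupied = np.zeros((H, W), bool)
    # rarer, higher-grade lesions first so they get unobstructed placements
    for cname, code, wob in (("dysplasia", DYSPLASIA, 0.25), ("adm", ADM, 0.08)):
        wall, lum = _place_lesions(
            rng, tissue, occupied, spec.n_lesions, quota[cname], lf[cname], wob
        )
        truth[wall] = code
        tissue &= ~lum  # lumina become background holes

    # split the remaining tissue between acinar and other along a smooth
    # field, in the target acinar:other ratio (robust to wall-quota shortfall)
    remaining = tissue & (truth == 0)
    n_rem = int(remaining.sum())
    denom = fr["acinar"] + fr["other"]
    n_aci = int(round(n_rem * fr["acinar"] / denom)) if denom > 0 else 0
    g = _smooth_field(rng, (H, W), min(H, W) / 10)
    g = np.where(remaining, g, -np.inf)
    truth[_top_k_mask(g, n_aci)] = ACINAR
    truth[remaining & (truth == 0)] = OTHER

    image = _render(rng, truth, spec)
    return SyntheticSample(
        image=image,
        truth=truth,
        if_amy=truth == ACINAR,
        if_pank=(truth == ADM) | (truth == DYSPLASIA),
        if_dapi=truth != BACKGROUND,
    )


def _render(rng: np.random.Generator, truth: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    H, W = truth.shape
    img = np.full((H, W, 3), _BACKGROUND_VALUE, np.float64)
    for code, base in _PALETTE.items():
        img[truth == code] = base

    # class textures (before any staining fields, so truth stays exact)
    tex = _smooth_field(rng, (H, W), 1.5)
    img[truth == OTHER] += (12.0 * tex[truth == OTHER])[:, None]
    img[truth == ADM] += (10.0 * tex[truth == ADM])[:, None]
    img[truth == DYSPLASIA] += (14.0 * tex[truth == DYSPLASIA])[:, None]
    speckle = (_smooth_field(rng, (H, W), 1.0) > 0.55) & (truth == ACINAR)
    img[speckle] = _SPECKLE_RGB

    cellular = truth != BACKGROUND
    # uneven staining: smooth multiplicative planar + radial gradient on tissue
    if spec.unevenness_amplitude > 0:
        yy, xx = np.mgrid[0:H, 0:W]
        yy = yy / max(H - 1, 1) - 0.5
        xx = xx / max(W - 1, 1) - 0.5
        a, b = rng.uniform(-1, 1, 2)
        plane = (a * yy + b * xx) / max(np.hypot(a, b), 1e-9) * np.sqrt(2)
        radial = 1.0 - np.hypot(yy, xx) * 2.0
        fieldm = 1.0 + spec.unevenness_amplitude * 0.5 * (plane + radial)
        img[cellular] *= fieldm[cellular][:, None]

    # inter-image colour shift, tissue only
    shift = np.asarray(spec.color_shift, float)
    if np.any(shift != 0):
        img[cellular] *= (1.0 + shift)[None, :]

    img = np.clip(img, 0, 255)
    # guarantee background purity pre-noise
    img[~cellular] = np.maximum(img[~cellular], 201.0)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(specs) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate one sample per spec plus a manifest of realised fractions.

    The manifest has one row per (sample, cellular class) with the pixel
    count and the fraction of the cellular area.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("generate_cohort requires at least one spec")
    samples, rows = [], []
    for i, spec in enumerate(specs):
        try:
            s = generate_sample(spec)
        except ValueError as e:
            raise ValueError(f"spec at index {i} failed: {e}") from e
        samples.append(s)
        cellular = int((s.truth != BACKGROUND).sum())
        for cname in CLASS_NAMES:
            n = int((s.truth == LABEL_CODES[cname]).sum())
            rows.append(
                {
                    "sample_id": i,
                    "class": cname,
                    "pixel_count": n,
                    "fraction": n / cellular if cellular else float("nan"),
                }
            )
    return samples, pd.DataFrame(rows)


def perturb_stain(
    image: np.ndarray, max_shift: float, noise_sigma: float, seed: int
) -> np.ndarray:
    """Synthetic stain variation: random per-channel gain plus Gaussian noise.

    Each channel is multiplied by an independent factor drawn uniformly from
    ``[1 - max_shift, 1 + max_shift]``, then i.i.d. Gaussian noise of standard
    deviation ``noise_sigma`` (8-bit units) is added, and the result is
    clipped to [0, 255].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if not (0.0 <= max_shift <= 0.5):
        raise ValueError("max_shift must lie in [0, 0.5]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - max_shift, 1.0 + max_shift, size=3)
    out = image.astype(np.float64) * factors[None, None, :]
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def cohort_specs(
    n: int,
    seed: int,
    image_size: int = 256,
    vary_composition: bool = True,
) -> list[SyntheticSpec]:
    """Convenience factory for a cohort of specs with varying composition.

    Compositions are drawn (seeded) around the default mix so that area
    fractions differ between samples — the variation the cohort-level
    Spearman correlation needs.  Colour shifts emulate between-image staining
    differences; the per-image gradient emulates within-image unevenness.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        if vary_composition:
            w = rng.dirichlet((8.0, 5.0, 3.0, 4.0))  # acinar, adm, dys, other
            fr = {
                "acinar": float(w[0]),
                "adm": float(w[1]),
                "dysplasia": float(w[2]),
                "other": float(w[3]),
            }
        else:
            fr = dict(SyntheticSpec().target_fractions)
        specs.append(
            SyntheticSpec(
                image_height=image_size,
                image_width=image_size,
                target_fractions=fr,
                n_lesions=4,
                color_shift=tuple(rng.uniform(-0.1, 0.1, 3)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
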