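"""H&E stain/intensity normalization.

Staining is uneven both within a section and between sections, so images are
normalized to a common reference before tiling.  Reinhard colour transfer —
match per-channel mean and standard deviation to a reference in a
decorrelated colour space — is the default and is applied on intermediate
overlapping crops (default 5000 px, 50% overlap) rather than whole images:
crop-wise statistics track the local staining gradient that a single global
transform cannot correct.  Macenko and Vahadane stain-matrix normalizers are
provided as comparison baselines.

Background (non-tissue) pixels — every channel strictly greater than 200 —
are excluded from all statistics and returned unchanged by every normalizer.

The decorrelated space is CIELAB (D65) by default; the original Reinhard
recipe's lαβ space is available via ``space="lab_ruderman"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .tiling import plan_grid

logger = logging.getLogger(__name__)

BACKGROUND_THRESHOLD = 200


class NoTissueError(ValueError):
    """Raised when an operation that needs tissue pixels gets none."""


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    return image


def background_mask(image: np.ndarray, threshold: int = BACKGROUND_THRESHOLD) -> np.ndarray:
    """True where a pixel is background: min(R,G,B) strictly > threshold."""
    image = _check_rgb(image)
    return image.min(axis=2) > threshold


# ---------------------------------------------------------------------------
# decorrelated colour spaces
# ---------------------------------------------------------------------------

# Ruderman et al. lαβ forward matrices (RGB -> LMS -> log -> lαβ)
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2LAB = (
    np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)])
    @ np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]], float)
)


def _to_decorrelated(rgb01: np.ndarray, space: str) -> np.ndarray:
    if space == "cielab":
        return skcolor.rgb2lab(rgb01)
    if space == "lab_ruderman":
        lms = np.clip(rgb01 @ _RGB2LMS.T, 1e-6, None)
        return np.log10(lms) @ _LMS2LAB.T
    raise ValueError(f"unknown colour space: {space!r}")


def _from_decorrelated(arr: np.ndarray, space: str) -> np.ndarray:
    if space == "cielab":
        return skcolor.lab2rgb(arr)
    lms = 10.0 ** (arr @ np.linalg.inv(_LMS2LAB).T)
    return lms @ np.linalg.inv(_RGB2LMS).T


# ---------------------------------------------------------------------------
# Reinhard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReinhardStats:
    """Per-channel mean/std of tissue pixels in the decorrelated space."""

    means: tuple
    stds: tuple
    space: str = "cielab"

    def __post_init__(self):
        if any(s < 0 for s in self.stds):
            raise ValueError("standard deviations must be non-negative")


def compute_reinhard_stats(
    image: np.ndarray, bg: np.ndarray | None = None, space: str = "cielab"
) -> ReinhardStats:
    """Channel statistics over tissue (non-background) pixels only."""
    image = _check_rgb(image)
    if bg is None:
        bg = background_mask(image)
    tissue = ~bg
    if not tissue.any():
        raise NoTissueError("image contains no tissue pixels")
    dec = _to_decorrelated(image[tissue][None, :, :] / 255.0, space)[0]
    stds = dec.std(axis=0)
    stds[stds < 1e-9] = 0.0  # constant channels: snap float noise to zero
    return ReinhardStats(
        means=tuple(float(v) for v in dec.mean(axis=0)),
        stds=tuple(float(v) for v in stds),
        space=space,
    )


def reinhard_normalize(
    src: np.ndarray, ref: ReinhardStats, bg: np.ndarray | None = None
) -> np.ndarray:
    """Match tissue statistics of ``src`` to ``ref``; background unchanged.

    Tissue pixels are mapped channel-wise in the decorrelated space as
    ``(v - mu_src) * (sigma_ref / sigma_src) + mu_ref``.  A zero-variance
    source channel maps to the reference mean (degenerate rule, no crash).
    """
    src = _check_rgb(src)
    if bg is None:
        bg = background_mask(src)
    stats = compute_reinhard_stats(src, bg, ref.space)
    tissue = ~bg
    dec = _to_decorrelated(src[tissue][None, :, :] / 255.0, ref.space)[0]
    out = np.empty_like(dec)
    for c in range(3):
        if stats.stds[c] == 0.0:
            out[:, c] = ref.means[c]
        else:
            out[:, c] = (dec[:, c] - stats.means[c]) * (
                ref.stds[c] / stats.stds[c]
            ) + ref.means[c]
    rgb = _from_decorrelated(out[None, :, :], ref.space)[0]
    result = src.copy()
    result[tissue] = np.clip(np.rint(rgb * 255.0), 0, 255).astype(src.dtype)
    return result


def normalize_by_crops(
    image: np.ndarray,
    ref: ReinhardStats,
    crop_size: int = 5000,
    overlap_fraction: float = 0.5,
    threshold: int = BACKGROUND_THRESHOLD,
    bg: np.ndarray | None = None,
) -> np.ndarray:
    """Reinhard-normalize intermediate overlapping crops independently.

    Each crop's tissue statistics are matched to the reference, overlapping
    regions are blended by unweighted averaging, and background pixels are
    copied through from the input.  Images smaller than one crop degrade to
    whole-image normalization.  ``bg`` overrides the thresholded background
    mask when the caller knows the section geometry better than the pixel
    rule (e.g. under synthetic stain shifts that darken the glass).
    """
    image = _check_rgb(image)
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    H, W = image.shape[:2]
    if bg is None:
        bg = background_mask(image, threshold)
    if H <= crop_size and W <= crop_size:
        logger.info("image %dx%d fits one crop; whole-image normalization", H, W)
        return reinhard_normalize(image, ref, bg)
    stride = max(1, int(round(crop_size * (1.0 - overlap_fraction))))
    grid = plan_grid(H, W, tile_size=crop_size, stride=stride)
    acc = np.zeros((H, W, 3), np.float64)
    cnt = np.zeros((H, W, 1), np.int32)
    for t in grid.tiles:
        sl = np.s_[t.row_start : t.row_stop, t.col_start : t.col_stop]
        crop, crop_bg = image[sl], bg[sl]
        if crop_bg.all():
            norm = crop  # no tissue to normalize in this crop
        else:
            norm = reinhard_normalize(crop, ref, crop_bg)
        acc[sl] += norm
        cnt[sl] += 1
    out = np.clip(np.rint(acc / cnt), 0, 255).astype(image.dtype)
    out[bg] = image[bg]
    return out


# ---------------------------------------------------------------------------
# Macenko / Vahadane stain-matrix baselines
# ---------------------------------------------------------------------------

_OD_EPS = 1e-6
_OD_TISSUE_MIN = 0.15  # drop near-transparent pixels from stain estimation


@dataclass(frozen=True)
class StainStats:
    """Stain matrix (3x2, unit columns: H and E) and the per-stain 99th
    percentile concentrations of a reference image."""

    stain_matrix: tuple
    max_concentrations: tuple


def _optical_density(rgb: np.ndarray) -> np.ndarray:
    return -np.log10(np.maximum(rgb.astype(np.float64), _OD_EPS) / 255.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(255.0 * 10.0 ** (-od)), 0, 255)


def _stain_matrix_macenko(od: np.ndarray) -> np.ndarray:
    odh = od[(od > _OD_TISSUE_MIN).any(axis=1)]
    if odh.shape[0] < 10:
        raise NoTissueError("too few stained pixels for stain estimation")
    cov = np.cov(odh.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-10:
        raise ValueError("rank-deficient optical-density matrix")
    plane = evecs[:, [-1, -2]]  # top-2 eigenvectors
    proj = odh @ plane
    # orient the first axis along the data so angles stay in (-pi/2, pi/2)
    # and percentiles are wrap-free
    if proj[:, 0].mean() < 0:
        plane[:, 0] *= -1
        proj[:, 0] *= -1
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [1, 99])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    for v in (v1, v2):
        if v.sum() < 0:
            v *= -1
    # order: hematoxylin first (higher blue OD)
    stains = np.stack([v1, v2], axis=1)
    if stains[2, 0] < stains[2, 1]:
        stains = stains[:, ::-1]
    return stains / np.linalg.norm(stains, axis=0, keepdims=True)


def _stain_matrix_vahadane(od: np.ndarray, seed: int = 0) -> np.ndarray:
    # sparse non-negative dictionary; sklearn NMF stands in for SPAMS
    from sklearn.decomposition import NMF

    odh = od[(od > _OD_TISSUE_MIN).any(axis=1)]
    if odh.shape[0] < 10:
        raise NoTissueError("too few stained pixels for stain estimation")
    if np.linalg.matrix_rank(odh, tol=1e-8) < 2:
        raise ValueError("rank-deficient optical-density matrix")
    nmf = NMF(
        n_components=2,
        init="nndsvda",
        l1_ratio=0.8,
        alpha_W=1e-3,
        max_iter=400,
        random_state=seed,
    )
    nmf.fit(np.maximum(odh, 0))
    stains = nmf.components_.T  # 3 x 2
    if stains[2, 0] < stains[2, 1]:
        stains = stains[:, ::-1]
    norms = np.linalg.norm(stains, axis=0, keepdims=True)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate stain vector from NMF")
    return stains / norms


def fit_stain_stats(image: np.ndarray, method: str = "macenko", seed: int = 0) -> StainStats:
    """Estimate the stain matrix and reference concentrations of an image."""
    image = _check_rgb(image)
    bg = background_mask(image)
    if not (~bg).any():
        raise NoTissueError("image contains no tissue pixels")
    od = _optical_density(image[~bg])
    if method == "macenko":
        stains = _stain_matrix_macenko(od)
    elif method == "vahadane":
        stains = _stain_matrix_vahadane(od, seed)
    else:
        raise ValueError(f"unknown stain method: {method!r}")
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    maxc = np.percentile(np.maximum(conc, 0), 99, axis=1)
    return StainStats(
        stain_matrix=tuple(map(tuple, stains)),
        max_concentrations=tuple(float(v) for v in np.maximum(maxc, 1e-8)),
    )


def _normalize_stains(image: np.ndarray, ref: StainStats, method: str, seed: int = 0) -> np.ndarray:
    image = _check_rgb(image)
    bg = background_mask(image)
    src = fit_stain_stats(image, method, seed)
    tissue = ~bg
    od = _optical_density(image[tissue])
    src_m = np.asarray(src.stain_matrix)
    conc, *_ = np.linalg.lstsq(src_m, od.T, rcond=None)
    conc = np.maximum(conc, 0)
    scale = np.asarray(ref.max_concentrations) / np.asarray(src.max_concentrations)
    conc *= scale[:, None]
    out_od = (np.asarray(ref.stain_matrix) @ conc).T
    result = image.copy()
    result[tissue] = _od_to_rgb(out_od).astype(image.dtype)
    return result


def normalize_macenko(image: np.ndarray, ref: StainStats) -> np.ndarray:
    """Macenko stain normalization (SVD-plane stain estimation)."""
    return _normalize_stains(image, ref, "macenko")


def normalize_vahadane(image: np.ndarray, ref: StainStats, seed: int = 0) -> np.ndarray:
    """Vahadane-style stain normalization (sparse NMF stain estimation)."""
    return _normalize_stains(image, ref, "vahadane", seed)
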