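"""Evaluation metrics: Dice, SSIM, Spearman, Mann-Whitney U, robustness.

Serial H&E and IF sections are adjacent but not aligned slices, so pixel-wise
overlap against IF is biased; the suite therefore combines

* Dice, ``2|X ∩ Y| / (|X| + |Y|)``, for masks that *are* aligned (model vs
  annotation, perturbed vs unperturbed predictions),
* windowed SSIM (7-px uniform window, k1 = 0.01, k2 = 0.03, dynamic range
  estimated from the images, optional small Gaussian pre-blur) for
  mask-vs-mask structural agreement across serial sections,
* Spearman rank correlation of per-image area fractions across a cohort, and
* the two-sided Mann-Whitney U test for group contrasts (exact null
  distribution for small samples, normal approximation with continuity and
  tie corrections otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

from .fusion import ClassThresholds, fuse
from .normalization import normalize_by_crops
from .synthetic import LABEL_CODES, perturb_stain

POSITIVE_CLASSES = ("acinar", "adm", "dysplasia")


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient of two binary masks; 1.0 when both are empty
    (agreement on absence — a documented convention)."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("masks must share a shape")
    sx, sy = int(x.sum()), int(y.sum())
    if sx + sy == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (sx + sy)


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSIMParams:
    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None  # None: max - min over both images
    pre_blur_sigma: float = 0.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.pre_blur_sigma < 0:
            raise ValueError("pre_blur_sigma must be non-negative")


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean windowed structural similarity of two single-channel images.

    The dynamic range L defaults to max - min over both images jointly.  If
    that range is zero the two images are identical constants and the value
    is 1 by the identity property.  Computation delegates to scikit-image
    (uniform window) after the optional Gaussian pre-blur.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if x.ndim != 2:
        raise ValueError("expected single-channel 2-D images")
    if min(x.shape) < params.window:
        raise ValueError("images are smaller than the SSIM window")
    if params.pre_blur_sigma > 0:
        x = ndimage.gaussian_filter(x, params.pre_blur_sigma)
        y = ndimage.gaussian_filter(y, params.pre_blur_sigma)
    L = params.data_range
    if L is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        L = float(hi - lo)
    if L == 0.0:
        # joint range zero => both images are the same constant
        return 1.0
    return float(
        structural_similarity(
            x,
            y,
            win_size=params.window,
            K1=params.k1,
            K2=params.k2,
            data_range=L,
            gaussian_weights=False,
        )
    )


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def spearman(pairs) -> float:
    """Spearman rank correlation (midranks for ties) of paired values."""
    arr = np.asarray(list(pairs), np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (x, y) pairs")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation is undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts (a, b) pairs with a > b, plus 1/2 per tie.  The p-value uses
    the exact null distribution when min(n_a, n_b) <= 8 and the data are
    tie-free, and the normal approximation with continuity and tie
    corrections otherwise.
    """
    a = np.asarray(list(group_a), np.float64)
    b = np.asarray(list(group_b), np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = min(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return u, float(res.pvalue)


# ---------------------------------------------------------------------------
# perturbation self-consistency
# ---------------------------------------------------------------------------


def perturbation_consistency(
    models: dict,
    image: np.ndarray,
    n_perturbations: int,
    max_shift: float,
    noise_sigma: float,
    thresholds: ClassThresholds = ClassThresholds(),
    seed: int = 0,
    reference_stats=None,
    crop_size: int = 5000,
    stride: int | None = None,
) -> pd.DataFrame:
    """Dice of per-class predictions under synthetic stain perturbation.

    The image is predicted once unperturbed, then ``n_perturbations`` times
    after a seeded per-channel shift of up to ``max_shift`` plus Gaussian
    noise; every run is renormalized to the same reference, predicted, and
    fused, and the per-class indicator masks are compared with Dice against
    the unperturbed labels.  Returns one row per (perturbation, class).

    The background mask is computed once from the unperturbed image and
    reused for every perturbed run: the perturbation emulates staining
    variation of one physical section, whose glass geometry is invariant —
    a strong downward channel gain would otherwise pull white background
    below the colour threshold and corrupt the normalization statistics.
    """
    from .models import predict_image  # local import to avoid a cycle
    from .normalization import background_mask, compute_reinhard_stats

    if n_perturbations < 1:
        raise ValueError("n_perturbations must be >= 1")
    if reference_stats is None:
        reference_stats = compute_reinhard_stats(image)
    bg = background_mask(image)

    def predict_labels(img):
        norm = normalize_by_crops(img, reference_stats, crop_size=crop_size, bg=bg)
        probs = {
            name: predict_image(models[name], norm, stride=stride)
            for name in POSITIVE_CLASSES
        }
        return fuse(
            probs["acinar"], probs["adm"], probs["dysplasia"], img, thresholds, bg=bg
        )

    base = predict_labels(image)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_perturbations):
        pert = perturb_stain(image, max_shift, noise_sigma, int(rng.integers(2**31 - 1)))
        lab = predict_labels(pert)
        for name in POSITIVE_CLASSES:
            code = LABEL_CODES[name]
            rows.append(
                {
                    "perturbation": i,
                    "class": name,
                    "dice": dice(lab == code, base == code),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------


def evaluate_cohort(
    predicted_fractions: pd.DataFrame,
    reference_fractions: pd.DataFrame,
    pred_masks: dict | None = None,
    ref_masks: dict | None = None,
    ssim_params: SSIMParams = SSIMParams(pre_blur_sigma=1.0),
) -> dict:
    """Spearman correlation per IF-equivalent channel, optional SSIM.

    Both frames need columns (sample_id, amy, pank, other) holding area
    fractions of the cellular region.  When mask dictionaries
    ``{sample_id: {channel: binary mask}}`` are supplied, a per-sample SSIM
    between predicted and reference masks (treated as images, blurred with
    the harness sigma of 1) is reported as well.
    """
    pf = predicted_fractions.set_index("sample_id").sort_index()
    rf = reference_fractions.set_index("sample_id").sort_index()
    if len(pf) != len(rf) or not (pf.index == rf.index).all():
        raise ValueError("predicted and reference cohorts must list the same samples")
    if len(pf) < 3:
        raise ValueError("need at least 3 samples for cohort correlation")
    out = {"spearman": {}, "n": int(len(pf)), "flags": []}
    for ch in ("amy", "pank", "other"):
        try:
            out["spearman"][ch] = spearman(zip(pf[ch], rf[ch]))
        except ValueError:
            # constant fraction vector: correlation undefined, flagged not fatal
            out["spearman"][ch] = None
            out["flags"].append(f"{ch}: constant fraction vector")
    if pred_masks is not None and ref_masks is not None:
        rows = []
        for sid in pf.index:
            for ch, pm in pred_masks[sid].items():
                rows.append(
                    {
                        "sample_id": sid,
                        "channel": ch,
                        "ssim": ssim(
                            np.asarray(pm, np.float64),
                            np.asarray(ref_masks[sid][ch], np.float64),
                            ssim_params,
                        ),
                    }
                )
        out["ssim"] = pd.DataFrame(rows)
    return out
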