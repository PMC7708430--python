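"""Fuse per-class probability maps into one label map and quantify areas.

Each binary model produces an independent probability map, so one pixel can
be claimed by several classes.  Conflicts are resolved by a fixed priority
order: background (white pixels, every channel > 200) overrides everything;
then normal acinar overrides ADM and dysplasia; ADM overrides dysplasia;
and any positive class overrides generic cellular tissue ("other", the
DAPI-positive remainder).  Positivity is inclusive: probability >= the
class threshold.  Default thresholds (acinar 0.3, ADM 0.5, dysplasia 0.7)
are the published operating points; ROC machinery is provided so users can
pick their own.

Area fractions are reported over the cellular region (all non-background
pixels).  The immunofluorescence-equivalent groupings are: AMY = acinar,
panK = ADM + dysplasia (pan-keratin does not separate the two), and
other = DAPI minus AMY and panK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import background_mask, BACKGROUND_THRESHOLD
from .synthetic import BACKGROUND, OTHER, ACINAR, ADM, DYSPLASIA, LABEL_CODES


@dataclass(frozen=True)
class ClassThresholds:
    acinar: float = 0.3
    adm: float = 0.5
    dysplasia: float = 0.7

    def __post_init__(self):
        for name in ("acinar", "adm", "dysplasia"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"threshold {name}={v} must lie in (0, 1)")


def fuse(
    prob_acinar: np.ndarray,
    prob_adm: np.ndarray,
    prob_dysplasia: np.ndarray,
    image: np.ndarray,
    thresholds: ClassThresholds = ClassThresholds(),
    bg_threshold: int = BACKGROUND_THRESHOLD,
    bg: np.ndarray | None = None,
) -> np.ndarray:
    """Combine three probability maps into a single label map.

    Pixel rule: background if min(R,G,B) > bg_threshold; else acinar if
    p_acinar >= t_acinar; else ADM if p_adm >= t_adm; else dysplasia if
    p_dysplasia >= t_dysplasia; else other.  An explicit ``bg`` mask
    overrides the colour rule when the caller knows the section geometry.
    """
    pa = np.asarray(prob_acinar, np.float64)
    pm = np.asarray(prob_adm, np.float64)
    pd_ = np.asarray(prob_dysplasia, np.float64)
    image = np.asarray(image)
    shape = image.shape[:2]
    if pa.shape != shape or pm.shape != shape or pd_.shape != shape:
        raise ValueError("probability maps must match the image shape")
    labels = np.full(shape, OTHER, np.uint8)
    labels[pd_ >= thresholds.dysplasia] = DYSPLASIA
    labels[pm >= thresholds.adm] = ADM
    labels[pa >= thresholds.acinar] = ACINAR
    if bg is None:
        bg = background_mask(image, bg_threshold)
    labels[bg] = BACKGROUND
    return labels


@dataclass
class AreaReport:
    """Pixel counts and cellular-area fractions for one label map."""

    counts: dict
    cellular_total: int
    fractions: dict  # None values when cellular_total == 0

    @property
    def amy_equiv(self):
        return self.fractions["acinar"]

    @property
    def pank_equiv(self):
        f = self.fractions
        if f["adm"] is None or f["dysplasia"] is None:
            return None
        return f["adm"] + f["dysplasia"]

    @property
    def other_equiv(self):
        return self.fractions["other"]

    def to_frame(self, sample_id="") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "class": c,
                "pixels": self.counts[c],
                "fraction": self.fractions[c] if self.fractions[c] is not None else float("nan"),
            }
            for c in ("other", "acinar", "adm", "dysplasia")
        ]
        return pd.DataFrame(rows)


def quantify(labels: np.ndarray) -> AreaReport:
    """Exhaustive pixel tally of a label map.

    Fractions are per cellular (non-background) pixel; an all-background map
    yields ``None`` fractions rather than zeros.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    if labels.size and labels.max() > DYSPLASIA:
        raise ValueError("label map contains codes outside 0..4")
    bincount = np.bincount(labels.ravel(), minlength=5)
    counts = {name: int(bincount[code]) for name, code in LABEL_CODES.items()}
    cellular = int(labels.size - bincount[BACKGROUND])
    fractions = {
        name: (counts[name] / cellular if cellular > 0 else None)
        for name in ("other", "acinar", "adm", "dysplasia")
    }
    return AreaReport(counts=counts, cellular_total=cellular, fractions=fractions)


def roc_curve(prob: np.ndarray, truth: np.ndarray, n_points: int = 101) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) on an even threshold grid.

    Positivity is inclusive (prob >= threshold).  The grid spans [0, 1] plus
    a final point just above 1 so the curve reaches sensitivity 0; at
    threshold 0 sensitivity is 1.  Sensitivity is non-increasing in the
    threshold.
    """
    prob = np.asarray(prob, np.float64).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if prob.shape != truth.shape:
        raise ValueError("probability map and truth mask must share a shape")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one positive and one negative")
    thresholds = np.concatenate([np.linspace(0.0, 1.0, n_points), [np.nextafter(1.0, 2.0)]])
    pos, neg = prob[truth], prob[~truth]
    sens = np.array([(pos >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(neg < t).sum() / n_neg for t in thresholds])
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})


def roc_auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under the ROC curve (sensitivity vs 1-specificity)."""
    fpr = 1.0 - roc["specificity"].to_numpy()
    tpr = roc["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))  # ties in FPR resolved by ascending TPR
    return float(np.trapezoid(tpr[order], fpr[order]))
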