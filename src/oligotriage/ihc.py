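"""Nuclear immunostain scoring.

Two scoring routes are implemented for the H3K27me3 (and, with a different
threshold, p53) nuclear stains:

1. **Automated intensity scoring** — each field's gray histogram is split by
   Otsu's global threshold into dark foreground (tissue/nuclei) and near-white
   background; the score of a field is the mean gray of the extracted
   foreground pixels, and a case's score is the mean over its fields
   (three by default). On the brightfield proxy, stain is dark, so a HIGHER
   score means LESS stain: the nuclear-loss (NL) cluster sits at high scores,
   the retention (NR) cluster at low scores. Cohort scores are binarized into
   NL/NR by cutting a hierarchical clustering at k = 2.

2. **Cell-fraction scoring** — nuclei are segmented, each nucleus is called
   STAINED / DOTLIKE_NEGATIVE / NEGATIVE, and the case is POSITIVE when more
   than 25% of tumor nuclei show diffuse staining, NEGATIVE when more than 75%
   show loss (dot-like counts as loss). The p53 variant uses a 50% positive
   threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .stats import hcluster_scores

NUCLEUS_CALLS = ("STAINED", "DOTLIKE_NEGATIVE", "NEGATIVE")


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds of the two scoring rules.

    ``positive_fraction_threshold`` (0.25) and ``negative_loss_threshold``
    (0.75) are the fraction rules for H3K27me3; ``p53_fraction_threshold``
    (0.50) is the p53 variant. ``dot_area_fraction_max`` bounds the stained
    area of a nucleus still considered a dot-like (negative) pattern.
    """

    positive_fraction_threshold: float = 0.25
    negative_loss_threshold: float = 0.75
    p53_fraction_threshold: float = 0.50
    dot_area_fraction_max: float = 0.10
    min_nucleus_area: int = 20
    n_fields: int = 3
    nucleus_stain_margin: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.positive_fraction_threshold < 1.0):
            raise ValueError("positive_fraction_threshold must lie in (0, 1)")
        if not (0.0 < self.negative_loss_threshold < 1.0):
            raise ValueError("negative_loss_threshold must lie in (0, 1)")
        if not (0.0 < self.dot_area_fraction_max < 1.0):
            raise ValueError("dot_area_fraction_max must lie in (0, 1)")
        if self.min_nucleus_area < 1:
            raise ValueError("min_nucleus_area must be >= 1")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")


@dataclass(frozen=True)
class IHCFieldScore:
    mean_foreground_gray: float
    n_foreground_pixels: int
    otsu_threshold: int


@dataclass
class IHCCaseScore:
    field_scores: list[float]
    case_score: float
    label: str = "UNSET"  # NR | NL | UNSET


@dataclass(frozen=True)
class NucleusCall:
    nucleus_id: int
    call: str  # one of NUCLEUS_CALLS


def gray_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin gray histogram of an 8-bit image."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) single-channel image")
    return np.bincount(image.ravel(), minlength=256)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's global threshold from a 256-bin gray histogram.

    Returns the integer t in [0, 255] maximizing the between-class variance
    w0(t)*w1(t)*(mu0(t) - mu1(t))**2 between the classes gray <= t and
    gray > t; ties are broken by the smallest t. A histogram with fewer than
    two occupied bins has no foreground/background split and raises.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied gray levels")
    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist) / total  # P(gray <= t)
    mu_cum = np.cumsum(hist * levels) / total
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, mu_cum / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - mu_cum) / w1, 0.0)
    variance = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(variance))  # argmax returns the smallest maximizer


def score_field(image: np.ndarray) -> IHCFieldScore:
    """Score one field: mean gray of the Otsu foreground (gray <= threshold)."""
    hist = gray_histogram(image)
    t = otsu_threshold(hist)
    counts = hist[: t + 1]
    n_fg = int(counts.sum())
    if n_fg == 0:
        raise ValueError("empty foreground: no pixel at or below the Otsu threshold")
    mean_fg = float((counts * np.arange(t + 1)).sum() / n_fg)
    return IHCFieldScore(mean_foreground_gray=mean_fg, n_foreground_pixels=n_fg,
                         otsu_threshold=t)


def score_case(fields: list[np.ndarray]) -> IHCCaseScore:
    """Average the per-field intensity scores of one case (label left UNSET)."""
    if len(fields) < 1:
        raise ValueError("need at least one field image")
    scores = [score_field(img).mean_foreground_gray for img in fields]
    return IHCCaseScore(field_scores=scores, case_score=float(np.mean(scores)))


def segment_nuclei(image: np.ndarray, config: ScoringConfig | None = None):
    """Segment nuclei as connected components of a nucleus-inclusive mask.

    Both stained and unstained nuclei are darker than the near-white
    background, so the mask uses the upper threshold of a three-class Otsu
    split (stained / unstained / background) of the gray histogram, which
    keeps pale unstained nuclei inside the foreground. Components smaller
    than ``min_nucleus_area`` are discarded as debris.

    Returns ``(label_image, regions)`` where regions are skimage regionprops.
    """
    cfg = config or ScoringConfig()
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) single-channel image")
    if np.count_nonzero(np.bincount(image.ravel(), minlength=256)) < 3:
        raise ValueError("image has fewer than three gray populations; cannot segment")
    thresholds = threshold_multiotsu(image, classes=3)
    mask = image <= thresholds[1]
    labeled = cc_label(mask, connectivity=2)
    regions = [r for r in regionprops(labeled) if r.area >= cfg.min_nucleus_area]
    if not regions:
        raise ValueError("no nucleus-sized regions found")
    keep = np.zeros(labeled.max() + 1, dtype=np.int32)
    for new_id, r in enumerate(regions, start=1):
        keep[r.label] = new_id
    return keep[labeled], regions


def classify_nucleus(
    region_mask: np.ndarray,
    image: np.ndarray,
    stain_cutoff: float,
    config: ScoringConfig | None = None,
    nucleus_id: int = 0,
) -> NucleusCall:
    """Call one nucleus STAINED / DOTLIKE_NEGATIVE / NEGATIVE.

    The stained-area fraction is the fraction of the nucleus' pixels at or
    below ``stain_cutoff``. Diffuse staining means the stained area exceeds
    ``dot_area_fraction_max``; a small positive stained area (a single
    punctate focus) is the dot-like pattern and counts as loss.
    """
    cfg = config or ScoringConfig()
    region_mask = np.asarray(region_mask, dtype=bool)
    n_px = int(region_mask.sum())
    if n_px == 0:
        raise ValueError("empty nucleus region")
    vals = np.asarray(image)[region_mask]
    stained = vals <= stain_cutoff
    frac = float(stained.sum()) / n_px
    if frac == 0.0:
        call = "NEGATIVE"
    elif frac <= cfg.dot_area_fraction_max:
        call = "DOTLIKE_NEGATIVE"
    else:
        call = "STAINED"
    return NucleusCall(nucleus_id=nucleus_id, call=call)


def fraction_score_case(
    calls_per_field: list[list[NucleusCall]],
    config: ScoringConfig | None = None,
    p53_variant: bool = False,
) -> str:
    """Fraction rule over all fields pooled: POSITIVE / NEGATIVE.

    POSITIVE when the stained fraction strictly exceeds the positive threshold
    (25%, or 50% for p53); NEGATIVE when the loss fraction (complete loss +
    dot-like) strictly exceeds 75%. An exactly-threshold stained fraction is
    called NEGATIVE (tie-break: the printed rules are strict inequalities).
    """
    cfg = config or ScoringConfig()
    cfg.validate()
    calls = [c.call for field_calls in calls_per_field for c in field_calls]
    if not calls:
        raise ValueError("zero tumor nuclei: cannot apply the fraction rule")
    n = len(calls)
    n_stained = sum(c == "STAINED" for c in calls)
    stained_fraction = n_stained / n
    loss_fraction = 1.0 - stained_fraction
    pos_thr = cfg.p53_fraction_threshold if p53_variant else cfg.positive_fraction_threshold
    if stained_fraction > pos_thr:
        return "POSITIVE"
    # Every nucleus not STAINED counts as loss (dot-like included), so a
    # non-positive case is negative; the exactly-threshold boundary, where
    # neither strict rule fires (loss == negative_loss_threshold), is broken
    # toward NEGATIVE.
    assert loss_fraction >= 1.0 - pos_thr or p53_variant
    return "NEGATIVE"


class IntensityBinarizer(ClusterMixin, BaseEstimator):
    """Binarize per-case intensity scores into NL/NR by 2-cluster hierarchy.

    Agglomerative clustering (average linkage by default) on the 1-D scores is
    cut at k = 2; the cluster with the HIGHER mean score is labeled NL (higher
    mean foreground gray = less stain = nuclear loss).

    Attributes
    ----------
    labels_ : ndarray of str, "NL" or "NR" per case, after ``fit``.
    cut_point_ : float, midpoint between the two clusters' closest edges.
    """

    def __init__(self, linkage: str = "average"):
        self.linkage = linkage

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        scores = X.ravel()
        if scores.size < 2:
            raise ValueError("need at least two case scores")
        if np.unique(scores).size < 2:
            raise ValueError("all case scores identical; no NL/NR split exists")
        _, cluster_ids = hcluster_scores(scores, k=2, method=self.linkage)
        means = {cid: scores[cluster_ids == cid].mean() for cid in np.unique(cluster_ids)}
        nl_id = max(means, key=means.get)
        self.labels_ = np.where(cluster_ids == nl_id, "NL", "NR")
        nl_scores = scores[self.labels_ == "NL"]
        nr_scores = scores[self.labels_ == "NR"]
        self.cut_point_ = float((nl_scores.min() + nr_scores.max()) / 2.0)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def binarize_cohort_scores(case_scores, linkage: str = "average") -> list[str]:
    """Label case intensity scores NL/NR (thin wrapper over IntensityBinarizer).

    Accepts IHCCaseScore objects or raw numbers; returns one "NL"/"NR" per case.
    """
    scores = [
        cs.case_score if isinstance(cs, IHCCaseScore) else float(cs) for cs in case_scores
    ]
    labels = IntensityBinarizer(linkage=linkage).fit_predict(
        np.asarray(scores).reshape(-1, 1)
    )
    for cs, lab in zip(case_scores, labels):
        if isinstance(cs, IHCCaseScore):
            cs.label = str(lab)
    return [str(lab) for lab in labels]
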