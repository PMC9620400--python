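"""Color-class assignment, training-set curation, and wavelength cutoffs.

AgN-DNA emitters fall into discrete "magic color" classes tied to the
number of neutral silver atoms in the cluster: Green (lambda_p < 580 nm),
Red (600-660 nm), Far Red (660-800 nm), NIR (> 800 nm), and Dark (no
bright emission).  Peaks between 580 and 600 nm belong to no class (the
cluster size there is unknown) and sequences whose brightest peak lands
in that gap are excluded from training, as are sequences with bright
peaks in two or more classes and sequences of mediocre brightness.

Boundary conventions (the literature writes strict inequalities on both
sides and never resolves equality): Green is lambda_p < 580, the gap is
the closed interval [580, 600], Red is (600, 660], Far Red is (660, 800],
NIR is lambda_p > 800.  All boundaries are configurable.

The Far Red / NIR cutoff at 800 nm was originally chosen by clustering
the pooled lambda_p values; :func:`kmeans_cutoffs` provides the exact 1-D
k-means used for that analysis, solved by dynamic programming over sorted
values so the result is deterministic (no Lloyd seeding).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorClass",
    "CLASS_ORDER",
    "GAP",
    "CurationConfig",
    "LabeledRecord",
    "CurationResult",
    "CutoffReport",
    "classify_peak",
    "curate_training",
    "evaluate_design_outcome",
    "kmeans_cutoffs",
]


class ColorClass(str, enum.Enum):
    """The five AgN-DNA color classes."""

    DARK = "Dark"
    GREEN = "Green"
    RED = "Red"
    FARRED = "FarRed"
    NIR = "NIR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical class order used for pair enumeration and tie-breaking.
CLASS_ORDER: tuple[ColorClass, ...] = (
    ColorClass.DARK,
    ColorClass.GREEN,
    ColorClass.RED,
    ColorClass.FARRED,
    ColorClass.NIR,
)

#: Marker returned for peaks inside the 580-600 nm no-class gap.
GAP = "Gap"


@dataclass(frozen=True)
class CurationConfig:
    """Wavelength boundaries and brightness thresholds for curation.

    ``brightness_threshold`` is in control-normalized area units; peaks at
    or above it are "bright".  Peaks in ``[mediocre_fraction x threshold,
    threshold)`` are "mediocre" and cause exclusion of otherwise-dark
    sequences.  ``nir_overrides_training`` reproduces the labeling variant
    in which any sequence with a bright NIR peak is labeled NIR regardless
    of other bright peaks (NIR emission is measured on a separate
    instrument, so it does not compete with visible peaks for brightness).
    """

    green_max: float = 580.0
    gap: tuple[float, float] = (580.0, 600.0)
    red_max: float = 660.0
    farred_max: float = 800.0
    brightness_threshold: float = 0.2
    mediocre_fraction: float = 0.5
    nir_overrides_training: bool = False

    def __post_init__(self) -> None:
        bounds = (self.green_max, self.gap[1], self.red_max, self.farred_max)
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise ValueError(f"class boundaries must be strictly increasing, got {bounds}")
        if self.gap[0] > self.gap[1] or self.gap[0] < self.green_max:
            raise ValueError(f"invalid gap interval {self.gap}")
        if not (self.brightness_threshold > 0):
            raise ValueError("brightness_threshold must be positive")


@dataclass(frozen=True)
class LabeledRecord:
    """A curated training example: sequence, class label, and the peaks behind it."""

    sequence: str
    label: ColorClass
    provenance: tuple[tuple[float, float], ...] = ()  # (lambda_p nm, brightness)


@dataclass
class CurationResult:
    """Partition of the input into labeled records and excluded rows."""

    labeled: list[LabeledRecord]
    exclusions: list[tuple[str, str]]  # (sequence, reason)
    duplicates: list[str] = field(default_factory=list)

    def exclusion_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.exclusions:
            out[reason] = out.get(reason, 0) + 1
        return out


@dataclass(frozen=True)
class CutoffReport:
    """Exact 1-D k-means centroids and the midpoints between them."""

    centroids: np.ndarray  # nm, ascending
    midpoints: np.ndarray  # nm, len k - 1
    k: int
    inertia: float


def classify_peak(lambda_p: float, config: CurationConfig | None = None) -> ColorClass | str:
    """Map a peak wavelength (nm) to its color class, or :data:`GAP`.

    Wavelengths in the closed gap interval (580-600 nm by default) return
    the gap marker rather than a class.
    """
    cfg = config or CurationConfig()
    if not (lambda_p > 0):
        raise ValueError(f"lambda_p must be positive, got {lambda_p}")
    if lambda_p < cfg.green_max:
        return ColorClass.GREEN
    if cfg.gap[0] <= lambda_p <= cfg.gap[1]:
        return GAP
    if lambda_p <= cfg.red_max:
        return ColorClass.RED
    if lambda_p <= cfg.farred_max:
        return ColorClass.FARRED
    return ColorClass.NIR


def _split_brightness(
    peaks: list[tuple[float, float]], cfg: CurationConfig
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Partition (lambda_p, brightness) pairs into bright and mediocre lists."""
    lo = cfg.mediocre_fraction * cfg.brightness_threshold
    bright = [p for p in peaks if p[1] >= cfg.brightness_threshold]
    mediocre = [p for p in peaks if lo <= p[1] < cfg.brightness_threshold]
    return bright, mediocre


def _label_one(
    peaks: list[tuple[float, float]], cfg: CurationConfig
) -> tuple[ColorClass | None, str | None]:
    """Label a single record; returns (label, None) or (None, exclusion reason)."""
    bright, mediocre = _split_brightness(peaks, cfg)
    if cfg.nir_overrides_training and any(
        classify_peak(lam, cfg) is ColorClass.NIR for lam, _ in bright
    ):
        return ColorClass.NIR, None
    if bright:
        classes = {
            c for lam, _ in bright if (c := classify_peak(lam, cfg)) is not GAP
        }
        if len(classes) >= 2:
            return None, "multiclass"
        brightest = max(bright, key=lambda p: p[1])
        if classify_peak(brightest[0], cfg) is GAP:
            return None, "gap"
        return classify_peak(brightest[0], cfg), None  # type: ignore[return-value]
    if mediocre:
        return None, "mediocre"
    return ColorClass.DARK, None


def curate_training(
    records: list[tuple[str, list[tuple[float, float]]]],
    config: CurationConfig | None = None,
) -> CurationResult:
    """Build the training set from (sequence, peak list) rows.

    Each input row appears exactly once in either the labeled output or
    the exclusion log.  Peaks are (lambda_p nm, control-normalized
    brightness) pairs.  Duplicate sequences with differing peak lists are
    kept (each row labeled independently) and flagged in ``duplicates``.
    """
    cfg = config or CurationConfig()
    labeled: list[LabeledRecord] = []
    exclusions: list[tuple[str, str]] = []
    seen: dict[str, list[tuple[float, float]]] = {}
    duplicates: list[str] = []
    for seq, peaks in records:
        peaks = [(float(l), float(b)) for l, b in peaks]
        if seq in seen and seen[seq] != peaks:
            duplicates.append(seq)
        seen.setdefault(seq, peaks)
        label, reason = _label_one(peaks, cfg)
        if label is not None:
            labeled.append(LabeledRecord(seq, label, tuple(peaks)))
        else:
            exclusions.append((seq, reason))  # type: ignore[arg-type]
    return CurationResult(labeled=labeled, exclusions=exclusions, duplicates=duplicates)


def evaluate_design_outcome(
    peaks: list[tuple[float, float]],
    target: ColorClass,
    config: CurationConfig | None = None,
) -> tuple[bool, set[ColorClass]]:
    """Judge whether a tested sequence hit its design target.

    NIR emission is recorded on a separate instrument, so NIR peaks do not
    compete with visible peaks for "brightest": a sequence with any bright
    NIR peak is labeled NIR, *and also* carries the class of its brightest
    bright visible peak if one exists (dual label).  Targets Green, Red and
    Far Red succeed iff the brightest bright visible peak falls in the
    target class; target NIR succeeds iff any bright NIR peak exists.
    Sequences with no bright peaks are Dark (never a success).
    """
    cfg = config or CurationConfig()
    bright, _ = _split_brightness([(float(l), float(b)) for l, b in peaks], cfg)
    nir_bright = [p for p in bright if classify_peak(p[0], cfg) is ColorClass.NIR]
    visible_bright = [p for p in bright if classify_peak(p[0], cfg) is not ColorClass.NIR]

    labels: set[ColorClass] = set()
    visible_class: ColorClass | str | None = None
    if visible_bright:
        visible_class = classify_peak(max(visible_bright, key=lambda p: p[1])[0], cfg)
        if visible_class is not GAP:
            labels.add(visible_class)  # type: ignore[arg-type]
    if nir_bright:
        labels.add(ColorClass.NIR)
    if not labels:
        labels.add(ColorClass.DARK)

    if target is ColorClass.NIR:
        success = bool(nir_bright)
    else:
        success = visible_class is target
    return success, labels


def kmeans_cutoffs(lambda_values, k: int = 4) -> CutoffReport:
    """Exact 1-D k-means on peak wavelengths, with inter-centroid midpoints.

    Solved by dynamic programming over the sorted values (globally optimal
    within-cluster sum of squares; deterministic, unlike Lloyd iteration).
    The midpoints between consecutive centroids are the natural candidate
    class cutoffs.

    Parameters
    ----------
    lambda_values : array-like
        Peak wavelengths in nm.
    k : int
        Number of clusters, >= 2.
    """
    x = np.sort(np.asarray(lambda_values, dtype=float))
    n = x.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")

    # prefix sums for O(1) segment cost: cost[i:j] of one cluster over x[i:j]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost_vec(starts: np.ndarray, end: int) -> np.ndarray:
        # within-cluster SS of x[start:end] for a vector of starts
        cnt = end - starts
        s = s1[end] - s1[starts]
        ss = s2[end] - s2[starts]
        return ss - s * s / cnt

    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=np.intp)
    ends = np.arange(1, n + 1)
    cost[1, 1:] = s2[1:] - s1[1:] ** 2 / ends
    for j in range(2, k + 1):
        for i in range(j, n + 1):
            starts = np.arange(j - 1, i)
            cand = cost[j - 1, starts] + seg_cost_vec(starts, i)
            t = int(np.argmin(cand))
            cost[j, i] = cand[t]
            split[j, i] = starts[t]

    # backtrack cluster boundaries
    bounds = [n]
    i = n
    for j in range(k, 1, -1):
        i = int(split[j, i])
        bounds.append(i)
    bounds.append(0)
    bounds = bounds[::-1]
    centroids = np.array([x[bounds[j] : bounds[j + 1]].mean() for j in range(k)])
    midpoints = (centroids[:-1] + centroids[1:]) / 2.0
    return CutoffReport(
        centroids=centroids, midpoints=midpoints, k=k, inertia=float(cost[k, n])
    )
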