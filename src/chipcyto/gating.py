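"""Gate rules, sort decisions, and size-discrimination statistics.

A gate is a list of interval predicates over the recognizer's feature vector.
Rules are checked in list order and the first match wins; a matching rule
carries both the routing intent (collect/waste) and the electrode drive
polarity.  The size benchmark gates on blob area alone, mirroring how two
polystyrene populations of similar diameter are told apart by their area
histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recognition import DetectedParticle

__all__ = [
    "GateRule",
    "SortDecision",
    "DiscriminationResult",
    "classify",
    "fit_area_threshold",
    "discrimination_error",
    "area_histogram",
]


@dataclass(frozen=True)
class GateRule:
    """Interval predicates over detection features, with priority by position.

    ``predicates`` is a list of ``(feature_name, min, max)`` closed intervals;
    ``combination`` is ``'all'`` (conjunction; vacuously true when empty) or
    ``'any'``.  ``action`` says what the rule means for the particle and
    ``drive_polarity`` what the electrodes do when it fires.
    """

    name: str
    predicates: list[tuple[str, float, float]] = field(default_factory=list)
    combination: str = "all"
    action: str = "collect"
    drive_polarity: str = "off"

    def __post_init__(self) -> None:
        if self.combination not in ("all", "any"):
            raise ValueError("combination must be 'all' or 'any'")
        if self.action not in ("collect", "waste"):
            raise ValueError("action must be 'collect' or 'waste'")
        if self.drive_polarity not in ("off", "forward", "reverse"):
            raise ValueError("drive_polarity must be off/forward/reverse")
        for feat, lo, hi in self.predicates:
            if feat not in DetectedParticle.FEATURES:
                raise ValueError(
                    f"unknown feature {feat!r} in rule {self.name!r}; "
                    f"valid: {DetectedParticle.FEATURES}"
                )
            if lo > hi:
                raise ValueError(
                    f"predicate on {feat!r} has min {lo} > max {hi} in rule {self.name!r}"
                )

    def matches(self, detection: DetectedParticle) -> bool:
        results = (
            lo <= detection.feature(feat) <= hi for feat, lo, hi in self.predicates
        )
        return all(results) if self.combination == "all" else any(results)


@dataclass(frozen=True)
class SortDecision:
    """Outcome of gating one detection: which rule fired and what to drive."""

    rule_name: str | None
    action: str  # collect / waste / none (no rule matched)
    drive_polarity: str
    matched: bool


DEFAULT_DECISION = SortDecision(rule_name=None, action="none", drive_polarity="off", matched=False)


def classify(detection: DetectedParticle, rules: list[GateRule]) -> SortDecision:
    """First matching rule wins (list order is priority); no match → default.

    The default decision applies no voltage, so the particle follows the
    unperturbed stream to the default outlet.
    """
    if not rules:
        raise ValueError("rule list must be non-empty")
    for rule in rules:
        if rule.matches(detection):
            return SortDecision(
                rule_name=rule.name,
                action=rule.action,
                drive_polarity=rule.drive_polarity,
                matched=True,
            )
    return DEFAULT_DECISION


def fit_area_threshold(areas_a: list[float], areas_b: list[float]) -> float:
    """Split point minimizing misclassification between two labeled samples.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled values plus one candidate below and above the data.  A sample is
    assigned to the larger-mean population when its value is ≥ the threshold.
    Ties in error count are broken toward the midpoint of the two sample
    means.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    mean_a, mean_b = a.mean(), b.mean()
    mid = 0.5 * (mean_a + mean_b)
    if mean_a == mean_b:
        warnings.warn(
            "samples have identical means; threshold is degenerate", stacklevel=2
        )
        return float(mid)
    # orient so population "low" has the smaller mean
    low, high = (a, b) if mean_a < mean_b else (b, a)

    values = np.concatenate([low, high])
    # label 1 = belongs to the high population
    labels = np.concatenate([np.zeros(low.size), np.ones(high.size)])
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    l_sorted = labels[order]

    uniq = np.unique(v_sorted)
    candidates = np.empty(uniq.size + 1)
    candidates[1:-1] = 0.5 * (uniq[:-1] + uniq[1:])
    candidates[0] = uniq[0] - 1.0
    candidates[-1] = uniq[-1] + 1.0

    # errors(t) = (# high below t) + (# low at or above t)
    n_high_below = np.searchsorted(v_sorted, candidates, side="left")
    high_cum = np.concatenate([[0.0], np.cumsum(l_sorted)])
    high_below = high_cum[n_high_below]
    low_below = n_high_below - high_below
    errors = high_below + (low.size - low_below)

    best = errors == errors.min()
    best_candidates = candidates[best]
    return float(best_candidates[np.argmin(np.abs(best_candidates - mid))])


def discrimination_error(truth_labels, predicted_labels) -> float:
    """Fraction of misclassified particles."""
    truth = np.asarray(truth_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    if truth.size == 0:
        raise ValueError("label vectors must be non-empty")
    return float(np.mean(truth != pred))


def area_histogram(detections, bin_width: float):
    """Histogram of blob areas (μm²) with fixed-width bins.

    ``detections`` may be DetectedParticle objects or raw area values.
    Returns ``(counts, edges)``; the counts sum to the number of inputs.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    areas = np.asarray(
        [
            d.area_um2 if isinstance(d, DetectedParticle) else float(d)
            for d in detections
        ]
    )
    if areas.size == 0:
        return np.zeros(0, dtype=int), np.zeros(1)
    lo = np.floor(areas.min() / bin_width) * bin_width
    hi = np.ceil(areas.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(areas, bins=edges)
    return counts, edges


@dataclass
class DiscriminationResult:
    """End-to-end size-discrimination benchmark outcome.

    ``confusion`` rows are true populations (small, large); columns are
    predicted.  ``error_rate`` is per-particle on the held-out split and
    counts undetected particles as errors.  ``histograms`` maps population
    label → (counts, edges) of measured blob areas.
    """

    threshold: float
    error_rate: float
    confusion: np.ndarray
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    n_test: int = 0
    n_train: int = 0
    n_missed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    def plot(self, ax=None):
        """Area histograms per population (mirrors the instrument's report)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, (counts, edges) in self.histograms.items():
            ax.stairs(counts, edges, label=label, fill=True, alpha=0.5)
        ax.axvline(self.threshold, color="k", ls="--", label="gate threshold")
        ax.set_xlabel("blob area (μm²)")
        ax.set_ylabel("count")
        ax.legend()
        return ax
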