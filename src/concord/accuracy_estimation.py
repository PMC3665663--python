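"""Audit-sampling accuracy statistics for inferred correspondences.

Because correspondence algorithms are imperfect, the quality of a link table
is estimated by sampling: draw ``n`` unlinked entities and adjudicate how
many actually have a counterpart (false negatives), draw ``n`` linked
entities and adjudicate how many links are wrong (false positives).  The
sample size comes from the normal approximation to the binomial —
``n = ceil(z^2 p0 (1 - p0) / h^2)`` at confidence ``1 - alpha`` and
half-width ``h`` with the conservative ``p0 = 0.5`` (90% confidence and 10%
half-width give n = 68) — and the observed error proportions get exact
Clopper–Pearson confidence intervals.

The overall accuracy summary subtracts the one-decimal-rounded percentage
error rates from 100 (e.g. FN 9/68 -> 13.2%, FP 1/68 -> 1.5%, accuracy
85.3%), with lower/upper bounds obtained the same way from the interval
endpoints; an unrounded variant is carried alongside.

On synthetic data the manual adjudication step is replaced by exact
evaluation against the generator's ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import GroundTruth


@dataclass
class SamplingDesign:
    confidence: float = 0.90
    half_width: float = 0.10
    p0: float = 0.5

    @property
    def n(self) -> int:
        return required_sample_size(self.confidence, self.half_width, self.p0)


@dataclass
class RateEstimate:
    x: int  # errors found
    n: int  # sample size
    rate: float
    ci_low: float
    ci_high: float
    method: str = "clopper-pearson"

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.ci_high <= 1):
            raise ValueError("interval endpoints must satisfy 0 <= low <= high <= 1")


@dataclass
class AccuracySummary:
    fn: RateEstimate
    fp: RateEstimate
    accuracy_pct: float
    lower_pct: float
    upper_pct: float
    accuracy_pct_unrounded: float
    lower_pct_unrounded: float
    upper_pct_unrounded: float


def required_sample_size(
    confidence: float, half_width: float, p0: float = 0.5
) -> int:
    """Binomial sample-size design, normal approximation at worst-case p0."""
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    if not (0 < half_width <= 0.5):
        raise ValueError("half_width must lie in (0, 0.5]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.ceil(z * z * p0 * (1.0 - p0) / (half_width * half_width))


def draw_audit_samples(ids: list[str], n: int, seed: int) -> list[str]:
    """Uniform sample without replacement, deterministic in the seed."""
    if n > len(ids):
        raise ValueError(f"cannot sample {n} from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    ordered = sorted(ids)
    picked = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[int(i)] for i in picked]


def estimate_rate(x: int, n: int, confidence: float = 0.90) -> RateEstimate:
    """Observed proportion with an exact Clopper–Pearson interval."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    if not (0 <= x <= n):
        raise ValueError("x must lie in [0, n]")
    alpha = 1.0 - confidence
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return RateEstimate(x, n, x / n, low, high)


def _round1(x: float) -> float:
    return round(x, 1)


def accuracy_summary(fn: RateEstimate, fp: RateEstimate) -> AccuracySummary:
    """Overall accuracy from the two error-rate estimates.

    The headline figures subtract one-decimal-rounded percentage rates so
    printed tables are internally consistent; the unrounded variants use the
    raw proportions.
    """
    acc = 100.0 - _round1(100.0 * fn.rate) - _round1(100.0 * fp.rate)
    lower = 100.0 - _round1(100.0 * fn.ci_high) - _round1(100.0 * fp.ci_high)
    upper = 100.0 - _round1(100.0 * fn.ci_low) - _round1(100.0 * fp.ci_low)
    return AccuracySummary(
        fn=fn,
        fp=fp,
        accuracy_pct=round(acc, 1),
        lower_pct=round(lower, 1),
        upper_pct=round(upper, 1),
        accuracy_pct_unrounded=100.0 * (1.0 - fn.rate - fp.rate),
        lower_pct_unrounded=100.0 * (1.0 - fn.ci_high - fp.ci_high),
        upper_pct_unrounded=100.0 * (1.0 - fn.ci_low - fp.ci_low),
    )


def extrapolate_error_count(rate_bound: float, population: int) -> int:
    """Scale a rate bound to a population count, rounded to nearest."""
    if not (0.0 <= rate_bound <= 1.0):
        raise ValueError("rate_bound must lie in [0, 1]")
    if population < 0:
        raise ValueError("population must be non-negative")
    return int(math.floor(rate_bound * population + 0.5))


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None


def evaluate_correspondences(
    predicted: set[tuple[str, str]],
    truth: GroundTruth,
    entity_type: str,
) -> EvaluationResult:
    """Exact evaluation of predicted pairs against synthetic ground truth."""
    if entity_type == "compound":
        true_pairs = truth.compound_pairs
    elif entity_type == "reaction":
        true_pairs = truth.reaction_pairs
    else:
        raise ValueError(f"unknown entity_type {entity_type!r}")
    tp = len(predicted & true_pairs)
    fp = len(predicted - true_pairs)
    fn = len(true_pairs - predicted)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return EvaluationResult(tp, fp, fn, precision, recall)


def audit_against_truth(
    predicted: set[tuple[str, str]],
    truth: GroundTruth,
    entity_type: str,
    a_population: list[str],
    n: int,
    seed: int,
    confidence: float = 0.90,
) -> AccuracySummary:
    """The full audit procedure with truth-based adjudication.

    Samples ``n`` unlinked DB-A entities (false-negative audit: does the
    truth pair them with something?) and ``n`` linked DB-A entities
    (false-positive audit: is the predicted partner the true one?), then
    summarizes overall accuracy.  Sample sizes are capped at the population
    when a stratum is smaller than ``n``.
    """
    true_pairs = (
        truth.compound_pairs if entity_type == "compound" else truth.reaction_pairs
    )
    a_true = dict(true_pairs)
    a_pred = dict(predicted)
    linked = sorted(a_pred)
    unlinked = sorted(set(a_population) - set(a_pred))
    n_fn = min(n, len(unlinked))
    n_fp = min(n, len(linked))
    fn_sample = draw_audit_samples(unlinked, n_fn, seed) if n_fn else []
    fp_sample = draw_audit_samples(linked, n_fp, seed + 1) if n_fp else []
    x_fn = sum(1 for a in fn_sample if a in a_true)
    x_fp = sum(1 for a in fp_sample if a_true.get(a) != a_pred[a])
    fn_est = estimate_rate(x_fn, max(n_fn, 1), confidence)
    fp_est = estimate_rate(x_fp, max(n_fp, 1), confidence)
    return accuracy_summary(fn_est, fp_est)
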