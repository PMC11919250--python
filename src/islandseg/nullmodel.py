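"""Null model for the captured-cell count.

A relay cell whose primary dendrites each independently connect to one of
two bouton classes (island with probability ``p``, surrounding field with
probability ``1 - p``) is *captured* — innervated by a single class — exactly
when all of its dendrites agree, which happens with probability

    q(k) = p**k + (1 - p)**k

for a cell with ``k`` innervated primary dendrites.  Across a cohort with
dendrite counts (k_1, ..., k_n) the captured-cell count is then a
Poisson-binomial random variable with success probabilities q(k_i).  This
module provides the Monte Carlo simulation of that null (dendrites assigned
classes at random, trials counted), the exact Poisson-binomial distribution
as a dynamic-programming oracle, percentile thresholds ("smallest count whose
CDF reaches the level"), and upper-tail p-values for an observed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "NullModel",
    "NullResult",
    "capture_probability",
    "exact_capture_distribution",
    "run_monte_carlo",
    "percentile_threshold",
    "tail_p_value",
]

#: Innervated-primary-dendrite counts of the nine relay cells with somata in
#: the exclusion zone of the reference reconstruction.
REFERENCE_DENDRITE_COUNTS = (2, 2, 3, 4, 4, 4, 5, 5, 7)


@dataclass(frozen=True)
class NullModel:
    """Specification of the capture null.

    Parameters
    ----------
    dendrite_counts
        Number of innervated primary dendrites per cell, all >= 1.
    class_prob
        Probability that a dendrite connects to the island class; 0.5 means
        both classes equally likely (the validated default).
    trials
        Monte Carlo trial count.
    seed
        Seed for the PCG64 generator used by :func:`run_monte_carlo`.
    """

    dendrite_counts: tuple[int, ...]
    class_prob: float = 0.5
    trials: int = 100_000
    seed: int = 0

    def __post_init__(self):
        counts = tuple(int(k) for k in self.dendrite_counts)
        object.__setattr__(self, "dendrite_counts", counts)
        if len(counts) < 1:
            raise InvalidParameterError("dendrite_counts must be non-empty")
        if any(k < 1 for k in counts):
            raise InvalidParameterError(
                "all dendrite counts must be >= 1 (a cell with no innervated "
                "dendrites is not in the cohort)"
            )
        if not (0.0 < self.class_prob < 1.0):
            raise InvalidParameterError(f"class_prob must be in (0, 1), got {self.class_prob}")
        if self.trials < 1:
            raise InvalidParameterError(f"trials must be >= 1, got {self.trials}")

    @property
    def n_cells(self) -> int:
        return len(self.dendrite_counts)

    def capture_probabilities(self) -> np.ndarray:
        p = self.class_prob
        k = np.asarray(self.dendrite_counts, dtype=float)
        return p**k + (1.0 - p) ** k


@dataclass
class NullResult:
    """Null distribution of the captured-cell count for one model.

    ``empirical_pmf`` and ``exact_pmf`` are indexed by captured count
    0..n_cells.  ``percentile_thresholds`` maps a CDF level to the smallest
    count reaching it on the exact distribution.  The seed and generator
    identity are recorded so Monte Carlo runs are bit-for-bit reproducible.
    """

    model: NullModel
    empirical_pmf: np.ndarray
    exact_pmf: np.ndarray
    expected_captured: float
    percentile_thresholds: dict[float, int] = field(default_factory=dict)
    rng: str = "numpy.random.Generator(PCG64)"
    observed: int | None = None
    tail_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "dendrite_counts": list(self.model.dendrite_counts),
            "class_prob": self.model.class_prob,
            "trials": self.model.trials,
            "seed": self.model.seed,
            "rng": self.rng,
            "empirical_pmf": self.empirical_pmf.tolist(),
            "exact_pmf": self.exact_pmf.tolist(),
            "expected_captured": self.expected_captured,
            "percentile_thresholds": {str(k): v for k, v in self.percentile_thresholds.items()},
            "observed": self.observed,
            "tail_p": self.tail_p,
        }


def capture_probability(k: int, p: float = 0.5) -> float:
    """Probability q(k) = p**k + (1-p)**k that a k-dendrite cell is captured."""
    if int(k) != k or k < 1:
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    if not (0.0 < p < 1.0):
        raise InvalidParameterError(f"p must be in (0, 1), got {p}")
    k = int(k)
    return p**k + (1.0 - p) ** k


def exact_capture_distribution(model: NullModel) -> np.ndarray:
    """Exact PMF of the captured-cell count (Poisson binomial, DP convolution).

    Sequentially convolves the Bernoulli(q_i) capture indicators; O(n^2) and
    exact to floating precision (sums to 1 within 1e-12).
    """
    pmf = np.array([1.0])
    for q in model.capture_probabilities():
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1.0 - q)
        nxt[1:] += pmf * q
        pmf = nxt
    return pmf


def run_monte_carlo(model: NullModel, levels: tuple[float, ...] = (0.99,)) -> NullResult:
    """Simulate the capture null and bundle it with the exact distribution.

    Each trial assigns every primary dendrite a class (island with
    probability ``class_prob``) and counts cells whose dendrites all agree.
    Reproducible bit-for-bit from ``model.seed`` (PCG64).
    """
    rng = np.random.default_rng(model.seed)
    counts = np.asarray(model.dendrite_counts)
    n = model.n_cells
    total_dendrites = int(counts.sum())
    offsets = np.concatenate([[0], np.cumsum(counts)])
    draws = rng.random((model.trials, total_dendrites)) < model.class_prob
    captured_per_trial = np.zeros(model.trials, dtype=np.int64)
    for i in range(n):
        cell = draws[:, offsets[i] : offsets[i + 1]]
        island = cell.sum(axis=1)
        captured_per_trial += (island == 0) | (island == counts[i])
    empirical = np.bincount(captured_per_trial, minlength=n + 1) / model.trials
    exact = exact_capture_distribution(model)
    result = NullResult(
        model=model,
        empirical_pmf=empirical,
        exact_pmf=exact,
        expected_captured=float(np.arange(n + 1) @ exact),
    )
    result.percentile_thresholds = {
        float(level): percentile_threshold(result, level) for level in levels
    }
    return result


def percentile_threshold(result: NullResult, level: float = 0.99, which: str = "exact") -> int:
    """Smallest count c with CDF(c) >= level on the requested PMF.

    With ``level=0.99`` this is the count such that the stated share of null
    trials produce that many or fewer captured cells.
    """
    if not (0.0 < level < 1.0):
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    pmf = result.exact_pmf if which == "exact" else result.empirical_pmf
    cdf = np.cumsum(pmf)
    idx = np.searchsorted(cdf, level - 1e-12)
    return int(min(idx, len(pmf) - 1))


def tail_p_value(observed: int, result: NullResult) -> float:
    """Upper-tail probability P(X >= observed) under the exact null."""
    n = result.model.n_cells
    if not (0 <= observed <= n):
        raise InvalidParameterError(f"observed must be in [0, {n}], got {observed}")
    return float(result.exact_pmf[observed:].sum())
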