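"""Chance-corrected agreement and rank correlation for validation studies.

Two readers grading the same lesions on an ordinal 0-3 scale are compared
with Cohen's kappa; imaging-versus-histology agreement on feature extent
uses Gwet's agreement coefficient with linear ordinal weights, which is
robust to the high feature prevalence typical of tumor series (kappa is
undefined or unstable when one category dominates). Ordinal grades collapse
to binary presence (grade >= 1) for binary comparisons, and feature-versus-
expression associations use two-tailed Spearman rank correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_CATEGORIES = (0, 1, 2, 3)


@dataclasses.dataclass
class RatingPair:
    """Paired ratings of the same items by two raters."""

    ratings_a: np.ndarray
    ratings_b: np.ndarray
    categories: tuple = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        self.ratings_a = np.asarray(self.ratings_a)
        self.ratings_b = np.asarray(self.ratings_b)
        if self.ratings_a.shape != self.ratings_b.shape:
            raise ValueError("rating lists must have equal length")
        if len(self.ratings_a) < 2:
            raise ValueError("need at least 2 rated items")
        cats = set(self.categories)
        observed = set(self.ratings_a) | set(self.ratings_b)
        if not observed <= cats:
            raise ValueError(f"ratings outside declared categories: "
                             f"{sorted(observed - cats)}")


def _contingency(pair: RatingPair) -> np.ndarray:
    cats = list(pair.categories)
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for a, b in zip(pair.ratings_a, pair.ratings_b):
        table[index[a], index[b]] += 1
    return table


def cohen_kappa(pair: RatingPair) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from marginal products.

    Returns 1.0 for identical ratings. When chance agreement p_e equals 1
    (both raters constant) while observed agreement is below 1, kappa is
    undefined and an error is raised.
    """
    table = _contingency(pair)
    n = table.sum()
    p_o = np.trace(table) / n
    if p_o == 1.0:
        return 1.0
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1 with imperfect observed "
                         "agreement; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def linear_weights(k: int) -> np.ndarray:
    """Linear ordinal agreement weights w(i, j) = 1 - |i - j| / (k - 1)."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def gwet_weighted(pair: RatingPair,
                  weights: np.ndarray | str = "linear") -> float:
    """Gwet's chance-corrected agreement coefficient with ordinal weights.

    With identity weights this is Gwet's AC1; with linear weights (the
    default) it is the weighted generalization crediting near-miss ordinal
    disagreements. Observed agreement is the mean weight of each rating
    pair; the chance term is ``T_w / (K * (K - 1)) * sum_k pi_k * (1 -
    pi_k)`` where ``T_w`` is the total weight mass and ``pi_k`` the mean
    propensity of category k across both raters. Two identical constant
    ratings return 1.0 (perfect agreement).
    """
    k = len(pair.categories)
    if isinstance(weights, str):
        if weights == "linear":
            w = linear_weights(k)
        elif weights == "identity":
            w = np.eye(k)
        else:
            raise ValueError("weights must be 'linear', 'identity', or a matrix")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k, k):
            raise ValueError(f"weight matrix must be {k} x {k}")
    table = _contingency(pair)
    n = table.sum()
    p_o = float((w * table).sum() / n)
    pi = (table.sum(axis=1) + table.sum(axis=0)) / (2.0 * n)
    t_w = w.sum()
    p_e = float(t_w / (k * (k - 1)) * (pi * (1.0 - pi)).sum())
    if p_e >= 1.0 or (1.0 - p_e) < 1e-12:
        # only reachable in degenerate weight configurations
        return 1.0 if p_o == 1.0 else float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def binarize_grades(grades: Sequence[int]) -> np.ndarray:
    """Collapse ordinal 0-3 grades to binary presence: 0 -> 0, >= 1 -> 1."""
    g = np.asarray(grades)
    if not set(np.unique(g)) <= {0, 1, 2, 3}:
        raise ValueError("grades must be in {0, 1, 2, 3}")
    return (g >= 1).astype(int)


def two_reader_average(ratings_a: Sequence[int],
                       ratings_b: Sequence[int]) -> np.ndarray:
    """Rounded mean of two readers' ordinal grades (half-up)."""
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    return np.floor((a + b) / 2.0 + 0.5).astype(int)


def spearman_correlation(x: Sequence[float],
                         y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Spearman rank correlation (ties average-ranked).

    Raises on fewer than 4 points or zero rank variance in either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 4:
        raise ValueError("Spearman correlation needs at least 4 points")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("zero rank variance; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
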