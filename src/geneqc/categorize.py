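"""Category cutoffs from a fitted mixture, gene categorization, and the
alternative likelihood s_d.

The boundaries between uncertainty levels are the intersections of adjacent
component density functions.  For Gaussian components the intersection solves
a quadratic in closed form; for Gamma components the crossing is estimated on
a grid between the two component modes.  Densities are *unweighted* by
default (as in the source method); mixture-weighted densities are available
via ``weighted=True``.

A gene whose D-score is d, categorized into component i, gets an alternative
likelihood s_d = max{1 − F_{i−1}(d), F_{i+1}(d)} — the strongest claim a
neighboring component can make on d via its tail probability.  Edge
components use their single available neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mixture import MixtureModel

__all__ = [
    "Cutoffs",
    "CategoryResult",
    "gaussian_cutoffs",
    "gamma_cutoffs",
    "cutoffs_for",
    "category_labels",
    "assign_category",
    "component_index",
    "alternative_likelihood",
]


@dataclass(frozen=True)
class Cutoffs:
    """Ordered category boundaries (k components -> k − 1 cutoffs)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if list(self.values) != sorted(self.values):
            raise ValueError(f"cutoffs must be ascending, got {self.values}")

    @property
    def c1(self) -> float:
        return self.values[0]

    @property
    def c2(self) -> float:
        return self.values[1]


@dataclass(frozen=True)
class CategoryResult:
    gene_id: str
    d_score: float
    category: str
    alt_likelihood: float


def _gaussian_pair_cutoff(
    mu1: float, var1: float, mu2: float, var2: float,
    logw1: float = 0.0, logw2: float = 0.0,
) -> float | None:
    """x with w1·N(x|μ1,σ1²) = w2·N(x|μ2,σ2²) inside (μ1, μ2), else None.

    Density equality is the quadratic A x² + B x + C = 0 with
    A = 1/(2σ1²) − 1/(2σ2²), B = μ2/σ2² − μ1/σ1²,
    C = μ1²/(2σ1²) − μ2²/(2σ2²) + ln(σ1/σ2) − (ln w1 − ln w2).
    Equal variances make A = 0 and the linear root is the (weight-shifted)
    midpoint.
    """
    a = 0.5 / var1 - 0.5 / var2
    b = mu2 / var2 - mu1 / var1
    c = (
        mu1**2 / (2.0 * var1)
        - mu2**2 / (2.0 * var2)
        + 0.5 * np.log(var1 / var2)
        - (logw1 - logw2)
    )
    if abs(a) < 1e-15:
        if abs(b) < 1e-15:
            return None
        root = float(-c / b)
        return root if mu1 < root < mu2 else None
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    for root in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
        if mu1 < root < mu2:
            return float(root)
    return None


def gaussian_cutoffs(model: MixtureModel, weighted: bool = False) -> Cutoffs:
    """Closed-form density-intersection cutoffs for a Gaussian mixture."""
    if model.family != "gaussian":
        raise ValueError("gaussian_cutoffs needs a gaussian mixture")
    cuts: list[float] = []
    for i in range(model.k - 1):
        mu1, var1 = model.params[i]
        mu2, var2 = model.params[i + 1]
        logw1 = float(np.log(model.weights[i])) if weighted else 0.0
        logw2 = float(np.log(model.weights[i + 1])) if weighted else 0.0
        root = _gaussian_pair_cutoff(mu1, var1, mu2, var2, logw1, logw2)
        if root is None:
            root = _grid_equal_density(model, i, mu1, mu2, weighted)
        cuts.append(root)
    return Cutoffs(tuple(cuts))


def _grid_equal_density(
    model: MixtureModel, i: int, lo: float, hi: float, weighted: bool,
    grid_points: int = 10_000,
) -> float:
    """Fallback: the grid point in (lo, hi) where the two densities are closest."""
    warnings.warn(
        f"no analytic intersection between components {i} and {i + 1};"
        " falling back to a grid search",
        stacklevel=2,
    )
    if hi <= lo:
        return 0.5 * (lo + hi)
    x = np.linspace(lo, hi, grid_points + 2)[1:-1]
    f1 = model.component_logpdf(i, x)
    f2 = model.component_logpdf(i + 1, x)
    if weighted:
        f1 = f1 + np.log(model.weights[i])
        f2 = f2 + np.log(model.weights[i + 1])
    return float(x[int(np.argmin(np.abs(f1 - f2)))])


def gamma_cutoffs(
    model: MixtureModel, grid_points: int = 10_000, weighted: bool = False
) -> Cutoffs:
    """Grid-estimated density-intersection cutoffs for a Gamma mixture.

    For each adjacent pair the densities are evaluated on a uniform grid
    between the two component modes; the cutoff is the mean of the last grid
    point where f_i > f_{i+1} and the first where f_i < f_{i+1}.
    """
    if model.family != "gamma":
        raise ValueError("gamma_cutoffs needs a gamma mixture")
    if grid_points < 1000:
        raise ValueError("grid_points must be >= 1000")
    cuts: list[float] = []
    for i in range(model.k - 1):
        mode_lo = model.component_mode(i)
        mode_hi = model.component_mode(i + 1)
        lo, hi = mode_lo, mode_hi
        if hi <= lo:  # degenerate modes (e.g. both shapes <= 1)
            lo, hi = model.component_mean(i), model.component_mean(i + 1)
        if hi <= lo:
            warnings.warn(
                f"degenerate gamma components {i}/{i + 1}; using midpoint of modes",
                stacklevel=2,
            )
            cuts.append(float(0.5 * (mode_lo + mode_hi)))
            continue
        x = np.linspace(lo, hi, grid_points)
        f1 = model.component_logpdf(i, x)
        f2 = model.component_logpdf(i + 1, x)
        if weighted:
            f1 = f1 + np.log(model.weights[i])
            f2 = f2 + np.log(model.weights[i + 1])
        above = np.nonzero(f1 > f2)[0]
        below = np.nonzero(f1 < f2)[0]
        if above.size == 0 or below.size == 0:
            warnings.warn(
                f"gamma densities {i}/{i + 1} never cross on the grid;"
                " using midpoint of modes",
                stacklevel=2,
            )
            cuts.append(0.5 * (lo + hi))
            continue
        cuts.append(float(0.5 * (x[above[-1]] + x[below[0]])))
    return Cutoffs(tuple(sorted(cuts)))


def cutoffs_for(
    model: MixtureModel, grid_points: int = 10_000, weighted: bool = False
) -> Cutoffs:
    """Dispatch on the mixture family (closed form vs grid estimation)."""
    if model.family == "gaussian":
        return gaussian_cutoffs(model, weighted=weighted)
    return gamma_cutoffs(model, grid_points=grid_points, weighted=weighted)


def category_labels(k: int) -> tuple[str, ...]:
    """Uncertainty level names for a k-component model."""
    if k >= 3:
        return ("Low", "Medium", "High")
    if k == 2:
        return ("Low", "High")
    return ("Low",)


def component_index(d: float, cutoffs: Cutoffs) -> int:
    """1-based index of the component whose interval contains d.

    A score exactly at a cutoff belongs to the upper component
    (left-closed intervals: Low d < c1, Medium c1 <= d < c2, High d >= c2).
    """
    return int(np.searchsorted(np.asarray(cutoffs.values), d, side="right")) + 1


def assign_category(d: float, cutoffs: Cutoffs) -> str:
    labels = category_labels(len(cutoffs.values) + 1)
    return labels[component_index(d, cutoffs) - 1]


def alternative_likelihood(d: float, i: int, model: MixtureModel) -> float:
    """s_d = max{1 − F_{i−1}(d), F_{i+1}(d)} with 1-based component index i.

    Edge components use only their existing neighbor; a single-component
    model has no alternative, s_d = 0.
    """
    if not 1 <= i <= model.k:
        raise ValueError(f"component index {i} out of range 1..{model.k}")
    terms: list[float] = []
    if i > 1:
        terms.append(1.0 - float(model.component_cdf(i - 2, d)))
    if i < model.k:
        terms.append(float(model.component_cdf(i, d)))
    if not terms:
        return 0.0
    return float(np.clip(max(terms), 0.0, 1.0))
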