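"""Distances between positive measures on an interval.

Concentration of densities onto Dirac atoms is invisible to norm (total
variation) convergence: a narrow bump and the atom it approaches keep TV
distance near twice the mass.  Weak* convergence of positive measures with
possibly different totals is instead metrised by the flat metric (bounded
Lipschitz distance)

    rho_F(mu, nu) = sup { int f d(mu - nu) : |f| <= 1, Lip(f) <= 1 },

computed here as a linear program over the test-function values at the atom
locations.  For equal-mass comparisons the Wasserstein-1 distance applies,
and the two are bridged by

    rho_F(mu, nu) <= min(|mu|, |nu|) * W1(mu/|mu|, nu/|nu|) + | |mu| - |nu| |.

All measures are finite sums of nonnegative atoms (gridded densities enter
via :func:`grid_to_measure` with their quadrature weights as atom masses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import wasserstein_distance

from .errors import DomainError, ShapeError
from .model_core import GridDiscretization

__all__ = [
    "DiscreteMeasure",
    "ConcentrationSummary",
    "grid_to_measure",
    "wasserstein1",
    "flat_metric",
    "total_variation",
    "concentration_summary",
]


@dataclass(frozen=True)
class DiscreteMeasure:
    """Finite positive measure given by atoms (locations, weights).

    Atoms are sorted by location on construction and exactly coincident
    locations are merged (their weights add)."""

    locations: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        loc = np.atleast_1d(np.asarray(self.locations, dtype=float))
        wts = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if loc.shape != wts.shape or loc.ndim != 1:
            raise ShapeError("locations and weights must be equal-length 1-D arrays")
        if np.any(wts < -1e-12 * max(1.0, float(np.abs(wts).max(initial=0.0)))):
            raise DomainError("atom weights must be nonnegative")
        wts = np.clip(wts, 0.0, None)
        uniq, inverse = np.unique(loc, return_inverse=True)
        merged = np.zeros(uniq.size)
        np.add.at(merged, inverse, wts)
        object.__setattr__(self, "locations", uniq)
        object.__setattr__(self, "weights", merged)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def n_atoms(self) -> int:
        return int(self.locations.size)

    def normalized(self) -> "DiscreteMeasure":
        if self.total <= 0:
            raise DomainError("cannot normalise a zero measure")
        return DiscreteMeasure(self.locations, self.weights / self.total)

    @classmethod
    def dirac(cls, x: float, mass: float = 1.0) -> "DiscreteMeasure":
        return cls(np.array([x]), np.array([mass]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiscreteMeasure":
        df = pd.read_csv(path)
        return cls(df["location"].to_numpy(), df["weight"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"location": self.locations, "weight": self.weights}).to_csv(path, index=False)


def grid_to_measure(density: np.ndarray, grid: GridDiscretization) -> DiscreteMeasure:
    """Atoms at the grid nodes weighted by density * quadrature weight, so
    the measure's total equals the trapezoid mass of the density."""
    density = np.asarray(density, dtype=float)
    if density.shape != grid.nodes.shape:
        raise ShapeError("density does not match the grid")
    tol = 1e-9 * max(1.0, float(np.abs(density).max(initial=0.0)))
    if np.any(density < -tol):
        raise DomainError("density has negative values beyond tolerance")
    return DiscreteMeasure(grid.nodes, np.clip(density, 0.0, None) * grid.weights)


def wasserstein1(mu: DiscreteMeasure, nu: DiscreteMeasure, normalize: bool = False) -> float:
    """W1 distance between the normalised measures (CDF formula on the line).

    Without ``normalize`` the totals must already agree (to 1e-9 relative);
    with it, each measure is rescaled to unit mass first.  Either way the
    returned value is the transport distance between probability measures.
    """
    tm, tn = mu.total, nu.total
    if tm <= 0 or tn <= 0:
        raise DomainError("wasserstein1 requires positive total masses")
    if not normalize and not math.isclose(tm, tn, rel_tol=1e-9, abs_tol=1e-12):
        raise DomainError(f"totals differ ({tm:g} vs {tn:g}); pass normalize=True to compare shapes")
    return float(wasserstein_distance(mu.locations, nu.locations, mu.weights, nu.weights))


def _signed_difference(mu: DiscreteMeasure, nu: DiscreteMeasure) -> tuple[np.ndarray, np.ndarray]:
    locations = np.unique(np.concatenate([mu.locations, nu.locations]))
    diff = np.zeros(locations.size)
    diff[np.searchsorted(locations, mu.locations)] += mu.weights
    diff[np.searchsorted(locations, nu.locations)] -= nu.weights
    return locations, diff


def flat_metric(mu: DiscreteMeasure, nu: DiscreteMeasure) -> float:
    """Bounded Lipschitz distance, via a linear program.

    Maximises sum_i f_i (mu_i - nu_i) over test-function values f_i at the
    union of atom locations with |f_i| <= 1 and, after sorting, the
    adjacent-pair constraints |f_{i+1} - f_i| <= x_{i+1} - x_i (sufficient
    for the 1-Lipschitz condition on the line).  Totals may differ; the mass
    mismatch is picked up by the bound |f| <= 1.
    """
    if mu.n_atoms == 0 and nu.n_atoms == 0:
        return 0.0
    locations, diff = _signed_difference(mu, nu)
    m = locations.size
    if m == 1:
        return float(abs(diff[0]))
    gaps = np.diff(locations)
    # rows: f_{i+1} - f_i <= gap_i and f_i - f_{i+1} <= gap_i
    rows = np.arange(m - 1)
    a_ub = np.zeros((2 * (m - 1), m))
    a_ub[rows, rows] = -1.0
    a_ub[rows, rows + 1] = 1.0
    a_ub[m - 1 + rows, rows] = 1.0
    a_ub[m - 1 + rows, rows + 1] = -1.0
    b_ub = np.concatenate([gaps, gaps])
    res = linprog(-diff, A_ub=a_ub, b_ub=b_ub, bounds=[(-1.0, 1.0)] * m, method="highs")
    if not res.success:  # pragma: no cover - HiGHS should not fail on this LP
        raise RuntimeError(f"flat-metric LP failed: {res.message}")
    return float(max(-res.fun, 0.0))


def total_variation(mu: DiscreteMeasure, nu: DiscreteMeasure) -> float:
    """Total variation distance; atoms are matched by exact location, so
    measures on disjoint supports are at distance |mu| + |nu| no matter how
    close the supports are -- the reason TV cannot see concentration."""
    if mu.n_atoms == 0 and nu.n_atoms == 0:
        return 0.0
    _, diff = _signed_difference(mu, nu)
    return float(np.abs(diff).sum())


@dataclass(frozen=True)
class ConcentrationSummary:
    """Mass fractions near prescribed centres plus a spread statistic."""

    centers: tuple[float, ...]
    eps: float
    fractions: np.ndarray
    interquantile_width: float  # q0.95 - q0.05 of the normalised measure


def _weighted_quantile(locations: np.ndarray, weights: np.ndarray, q: float) -> float:
    cum = np.cumsum(weights)
    target = q * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    return float(locations[min(idx, locations.size - 1)])


def concentration_summary(measure: DiscreteMeasure, centers, eps: float) -> ConcentrationSummary:
    """Per-centre mass fraction within +-eps, and the 5%-95% interquantile
    width of the measure (0 for a single atom)."""
    if measure.total <= 0:
        raise DomainError("concentration summary needs a measure with positive mass")
    centers = tuple(float(c) for c in np.atleast_1d(centers))
    fractions = np.array(
        [measure.weights[np.abs(measure.locations - c) <= eps].sum() / measure.total for c in centers]
    )
    q05 = _weighted_quantile(measure.locations, measure.weights, 0.05)
    q95 = _weighted_quantile(measure.locations, measure.weights, 0.95)
    return ConcentrationSummary(centers=centers, eps=eps, fractions=fractions, interquantile_width=q95 - q05)
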