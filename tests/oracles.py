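"""Independent brute-force oracles for the measure metrics.

These deliberately avoid the code paths of the library: the Wasserstein
oracle solves the full transport linear program over the coupling matrix,
and the flat-metric oracle maximises the test functional by dynamic
programming over a fine discretisation of the admissible f-values.
"""

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.optimize import linprog


def wasserstein1_transport_lp(mu, nu) -> float:
    """W1 between the normalised measures via the transport LP."""
    a = mu.weights / mu.total
    b = nu.weights / nu.total
    m, n = a.size, b.size
    cost = np.abs(mu.locations[:, None] - nu.locations[None, :]).ravel()
    # row-sum and column-sum equality constraints on the coupling
    a_eq = np.zeros((m + n, m * n))
    for i in range(m):
        a_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        a_eq[m + j, j::n] = 1.0
    res = linprog(cost, A_eq=a_eq, b_eq=np.concatenate([a, b]), bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def flat_metric_dp(mu, nu, step: float = 5e-4) -> tuple[float, float]:
    """Flat metric by discretised maximisation; returns (value, tolerance).

    f-values are restricted to a grid of spacing ``step`` on [-1, 1]; the
    chained Lipschitz constraints become windowed maxima solved by dynamic
    programming.  The discretisation error is bounded by step * sum|c|.
    """
    locations = np.unique(np.concatenate([mu.locations, nu.locations]))
    diff = np.zeros(locations.size)
    diff[np.searchsorted(locations, mu.locations)] += mu.weights
    diff[np.searchsorted(locations, nu.locations)] -= nu.weights
    values = np.arange(-1.0, 1.0 + step / 2, step)
    best = diff[0] * values
    for j in range(1, locations.size):
        gap = locations[j] - locations[j - 1]
        radius = int(np.floor(gap / step + 1e-9))
        window = maximum_filter1d(best, size=2 * radius + 1, mode="constant", cval=-np.inf)
        best = window + diff[j] * values
    tolerance = step * float(np.abs(diff).sum()) + 1e-9
    return float(best.max()), tolerance


def random_measure(rng, max_atoms: int = 5, scale: float = 1.0):
    from clonesel.measure_metrics import DiscreteMeasure

    n = int(rng.integers(1, max_atoms + 1))
    return DiscreteMeasure(rng.uniform(0.0, 1.0, n), scale * rng.uniform(0.05, 1.0, n))
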