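"""Paired comparison of mushroom-bearing vs mushroom-free soils.

For every element with enough uncensored site-date pairs the module reports the
per-pair depletion percentage (free - bearing)/free * 100, whether depletion was
unanimous, the Pearson correlation between the paired concentrations (with a
two-sided p from the t transform), an exact Mann-Whitney U test between the two
soil groups, and a systematic-depletion flag.

The Mann-Whitney test follows the small-sample exact convention: U is the smaller
of the two one-sided statistics, ties are handled with midranks, and for pooled
sizes up to 20 the two-sided p-value is computed by exhaustive enumeration of all
C(n_a + n_b, n_a) group assignments of the observed values, counting assignments
whose U deviates from the null mean n_a*n_b/2 at least as much as observed.  Ties
are thereby exact, not approximated.  Beyond 20 observations a normal
approximation with tie correction and continuity correction is used; the
enumeration path is the oracle the approximation is validated against.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats

from .data_io import Compartment, Dataset

_log = logging.getLogger(__name__)

__all__ = [
    "PairedSoilComparison",
    "pearson_r",
    "mann_whitney_exact",
    "paired_depletion",
    "depletion_table",
]

#: Largest pooled sample size for which the exact enumeration runs.
EXACT_ENUMERATION_LIMIT = 20


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value.

    The p-value comes from t = r * sqrt((n-2)/(1-r^2)) referred to a
    t-distribution with n-2 degrees of freedom.  Requires n >= 3, finite values
    and nonzero variance in both arguments (otherwise ``ValueError``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"pearson_r needs n >= 3, got n = {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson_r requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r requires nonzero variance in both arguments")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def mann_whitney_exact(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact by enumeration at small n.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)`` computed from midranks.  For
    ``len(a) + len(b) <= 20`` the p-value enumerates every assignment of the
    pooled observed values into groups of the given sizes and counts those with
    ``|U - n_a*n_b/2| >= |U_obs - n_a*n_b/2|``.  Larger samples use the normal
    approximation with tie and continuity corrections.  ``method`` may force
    ``"exact"`` or ``"normal"``; the default ``"auto"`` switches on pooled size.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    mean_u = n_a * n_b / 2.0

    n = n_a + n_b
    exact = n <= EXACT_ENUMERATION_LIMIT if method == "auto" else method == "exact"
    if exact:
        # |U_a - mean| == |R_a - n_a (n+1)/2|: enumerate rank-sum deviations
        center = n_a * (n + 1) / 2.0
        observed = abs(r_a - center) - 1e-9  # float guard for midrank sums
        hits = sum(
            1 for idx in combinations(range(n), n_a)
            if abs(sum(ranks[i] for i in idx) - center) >= observed
        )
        p = hits / comb(n, n_a)
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:  # all values identical
            return u, 1.0
        z = (u - mean_u + 0.5) / sqrt(var_u)  # continuity correction toward mean
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return u, p


@dataclass(frozen=True)
class PairedSoilComparison:
    """Per-element outcome of the bearing-vs-free soil comparison.

    ``systematic`` requires unanimous depletion together with a strong,
    significant correlation between the paired concentrations (defaults
    r >= 0.95 at p < 0.01); correlation fields are ``None`` when the pairs are
    degenerate (zero variance).
    """

    element: str
    n_pairs: int
    mean_depletion_pct: float
    all_depleted: bool
    pearson_r: float | None
    pearson_p: float | None
    mw_u: float
    mw_p: float
    systematic: bool


def _paired_values(dataset: Dataset, element: str, site: str | None
                   ) -> tuple[np.ndarray, np.ndarray]:
    by_sample: dict[str, dict[Compartment, float]] = {}
    for rec in dataset.records:
        if rec.element != element or rec.censored:
            continue
        if site is not None and rec.site != site:
            continue
        if rec.compartment in (Compartment.SOIL_BEARING, Compartment.SOIL_FREE):
            by_sample.setdefault(rec.sample_id, {})[rec.compartment] = rec.value
    pairs = [(v[Compartment.SOIL_FREE], v[Compartment.SOIL_BEARING])
             for v in by_sample.values()
             if Compartment.SOIL_FREE in v and Compartment.SOIL_BEARING in v]
    if not pairs:
        return np.empty(0), np.empty(0)
    free, bearing = map(np.asarray, zip(*pairs))
    return free, bearing


def paired_depletion(dataset: Dataset, element: str, *, site: str | None = None,
                     r_threshold: float = 0.95, alpha: float = 0.01,
                     min_pairs: int = 3) -> PairedSoilComparison:
    """Compare the two soil types for one element across site-date pairs.

    Pairs are matched by sample id (one id carries both soil compartments).  By
    default all sites are pooled; ``site`` restricts to one.  Raises
    ``ValueError`` when fewer than ``min_pairs`` complete uncensored pairs exist.
    """
    free, bearing = _paired_values(dataset, element, site)
    n = len(free)
    if n < min_pairs:
        raise ValueError(
            f"{element}: only {n} complete pairs, need >= {min_pairs}")
    if (free <= 0).any():
        raise ValueError(f"{element}: nonpositive mushroom-free concentration")
    depletion = (free - bearing) / free * 100.0
    all_depleted = bool((depletion > 0).all())
    try:
        r, p = pearson_r(bearing, free)
    except ValueError:
        r = p = None
    u, mw_p = mann_whitney_exact(bearing, free)
    systematic = bool(all_depleted and r is not None
                      and r >= r_threshold and p < alpha)
    return PairedSoilComparison(
        element=element, n_pairs=n,
        mean_depletion_pct=float(depletion.mean()), all_depleted=all_depleted,
        pearson_r=r, pearson_p=p, mw_u=float(u), mw_p=float(mw_p),
        systematic=systematic,
    )


def depletion_table(dataset: Dataset, elements=None, **kwargs):
    """:func:`paired_depletion` over many elements as a DataFrame; elements with
    too few pairs are skipped and logged."""
    import pandas as pd

    if elements is None:
        elements = sorted({r.element for r in dataset.records})
    rows = []
    for el in elements:
        try:
            cmp_ = paired_depletion(dataset, el, **kwargs)
        except ValueError as exc:
            _log.info("skipping %s: %s", el, exc)
            continue
        rows.append(cmp_.__dict__)
    return pd.DataFrame(rows)
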