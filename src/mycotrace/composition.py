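"""Dry-matter arithmetic and aggregation of part-wise concentrations.

Bulk fruiting-body concentrations are dry-mass-weighted means of the three part
concentrations, c_bulk = sum_p w_p * c_p with the weight fractions renormalised to
sum exactly to 1.  Group summaries report mean and sample SD over the uncensored
values of a group, with a configurable policy for left-censored members.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PARTS, Compartment, FruitingBody, ValidationError

_log = logging.getLogger(__name__)

__all__ = [
    "DM_FRACTIONS",
    "SummaryStat",
    "BulkConcentration",
    "dm_fraction",
    "bulk_fb_concentration",
    "group_summary",
]

#: Mean dry-matter fraction of fresh mass per fruiting-body part and season
#: (drying at 65 degC to constant weight).
DM_FRACTIONS: dict[int, dict[Compartment, float]] = {
    2021: {Compartment.STIPE: 0.096, Compartment.CAP: 0.064,
           Compartment.SPOROPHORE: 0.089},
    2022: {Compartment.STIPE: 0.126, Compartment.CAP: 0.078,
           Compartment.SPOROPHORE: 0.110},
}


def dm_fraction(fresh_mass_g: float, dry_mass_g: float) -> float:
    """Dry-matter fraction dry/fresh in (0, 1].

    Raises ``ValueError`` for a non-positive fresh mass and
    :class:`~mycotrace.data_io.ValidationError` if dry exceeds fresh.
    """
    if fresh_mass_g <= 0:
        raise ValueError(f"fresh mass must be positive, got {fresh_mass_g}")
    if dry_mass_g <= 0:
        raise ValueError(f"dry mass must be positive, got {dry_mass_g}")
    if dry_mass_g > fresh_mass_g:
        raise ValidationError(
            f"dry mass {dry_mass_g} g exceeds fresh mass {fresh_mass_g} g")
    return dry_mass_g / fresh_mass_g


@dataclass(frozen=True)
class SummaryStat:
    """Mean/SD summary of one group of measurements (mg kg^-1 DM)."""

    mean: float
    sd: float
    n: int
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("a reported mean needs n >= 1")
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")


@dataclass(frozen=True)
class BulkConcentration:
    """A weight-aggregated whole-fruiting-body concentration.

    ``status`` is ``ok`` for a fully uncensored aggregate, ``censored_part`` when a
    part was below detection and the strict policy declined to aggregate, and
    ``lower_bound`` when censored parts were counted as zero (the value then bounds
    the true bulk concentration from below).
    """

    element: str
    value: float | None
    status: str  # ok | censored_part | lower_bound

    @property
    def calculable(self) -> bool:
        return self.value is not None


def bulk_fb_concentration(fb: FruitingBody, element: str,
                          censored_policy: str = "strict") -> BulkConcentration:
    """Aggregate the three part concentrations of ``fb`` for ``element``.

    ``censored_policy="strict"`` (default) refuses to aggregate when any part is
    below detection; ``"zero"`` substitutes 0 for censored parts and flags the
    result as a lower bound.
    """
    if censored_policy not in ("strict", "zero"):
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    parts = fb.part_concentrations.get(element)
    if parts is None or any(p not in parts for p in PARTS):
        raise KeyError(f"{fb.sample_id}: incomplete part data for {element}")
    values = {p: parts[p] for p in PARTS}
    censored = [p for p, v in values.items() if v is None]
    if censored and censored_policy == "strict":
        return BulkConcentration(element, None, "censored_part")
    total = sum(fb.weight_fractions[p] * (values[p] or 0.0) for p in PARTS)
    status = "lower_bound" if censored else "ok"
    return BulkConcentration(element, total, status)


_CENSOR_POLICIES = ("omit", "half_dl", "dl")


def group_summary(frame: pd.DataFrame, group_keys: list[str] | str,
                  censored_policy: str = "omit", ddof: int = 1) -> pd.DataFrame:
    """Mean/SD/n per group over a long-format record frame.

    Input must have ``value``, ``censored`` and (for substitution policies)
    ``detection_limit`` columns, as produced by ``Dataset.to_frame()``.

    Censored members are excluded under ``"omit"`` (default; their count is
    reported as ``n_censored``), or substituted with DL/2 (``"half_dl"``) or the
    DL itself (``"dl"``).  SD uses the sample convention (``ddof=1``); groups of
    one report ``sd = 0``.  Groups with no usable value are dropped and logged.
    """
    if censored_policy not in _CENSOR_POLICIES:
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    if isinstance(group_keys, str):
        group_keys = [group_keys]
    rows = []
    for keys, group in frame.groupby(group_keys, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = group.loc[~group["censored"], "value"].astype(float)
        n_cens = int(group["censored"].sum())
        if censored_policy != "omit" and n_cens:
            dls = group.loc[group["censored"], "detection_limit"].astype(float)
            sub = dls / 2.0 if censored_policy == "half_dl" else dls
            vals = pd.concat([vals, sub])
            n_cens_excluded = 0
        else:
            n_cens_excluded = n_cens
        if vals.empty:
            _log.info("group %s: no usable values (all censored), dropped",
                      dict(zip(group_keys, keys)))
            continue
        n = len(vals)
        sd = float(vals.std(ddof=ddof)) if n > ddof else 0.0
        rows.append({**dict(zip(group_keys, keys)),
                     "mean": float(vals.mean()),
                     "sd": 0.0 if math.isnan(sd) else sd,
                     "n": n, "n_censored": n_cens_excluded})
    return pd.DataFrame(rows, columns=[*group_keys, "mean", "sd", "n", "n_censored"])


def summary_stat(values, censored_dls=(), censored_policy: str = "omit",
                 ddof: int = 1) -> SummaryStat:
    """Convenience scalar form of :func:`group_summary` for one group."""
    vals = list(map(float, values))
    n_cens = len(censored_dls)
    if censored_policy == "half_dl":
        vals += [dl / 2.0 for dl in censored_dls]
        n_cens = 0
    elif censored_policy == "dl":
        vals += list(map(float, censored_dls))
        n_cens = 0
    elif censored_policy != "omit":
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    if not vals:
        raise ValidationError("no uncensored values in group")
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
    return SummaryStat(mean=float(arr.mean()), sd=sd, n=len(arr), n_censored=n_cens)
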