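"""Bioaccumulation and translocation factors and their classifications.

The bioaccumulation factor BF = C_M / C_S compares an element's concentration in
mushroom tissue (stipe, cap, sporophore, or the weight-averaged bulk fruiting
body) with its concentration in the substrate soil, both on a dry-matter basis;
BF > 1 marks the mushroom as an accumulating biosystem for that element.  The
translocation factor TF = C_upper / C_lower (cap/stipe or sporophore/cap)
measures within-mushroom mobility; TF > 1 marks a mobile element.  Both
thresholds are strict: a ratio of exactly 1 classifies as excluder/immobile.

Censoring propagates as status, never as a number: a below-detection substrate
makes a BF not-calculable (the selenium case in soils), and a below-detection
numerator is either not-calculable or, under the optional upper-bound mode, the
detection limit is used as numerator and the result flagged as a bound.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .composition import SummaryStat, bulk_fb_concentration
from .data_io import Dataset

__all__ = [
    "FactorKind",
    "FactorStatus",
    "FactorResult",
    "ContrastSummary",
    "compute_bf",
    "compute_tf",
    "classify_translocation_profile",
    "contrast_ratio",
    "bf_table",
    "tf_table",
]


class FactorKind(str, Enum):
    BF_STIPE = "BF_stipe"
    BF_CAP = "BF_cap"
    BF_SPOR = "BF_spor"
    BF_BULK = "BF_bulk"
    TF_CAP_STIPE = "TF_cap_stipe"
    TF_SPOR_CAP = "TF_spor_cap"


class FactorStatus(str, Enum):
    OK = "ok"
    SUBSTRATE_CENSORED = "substrate_censored"
    MUSHROOM_CENSORED = "mushroom_censored"
    ZERO_DENOMINATOR = "zero_denominator"


_BF_KINDS = (FactorKind.BF_STIPE, FactorKind.BF_CAP,
             FactorKind.BF_SPOR, FactorKind.BF_BULK)
_TF_KINDS = (FactorKind.TF_CAP_STIPE, FactorKind.TF_SPOR_CAP)


@dataclass(frozen=True)
class FactorResult:
    """A BF or TF ratio with its calculability status and classification.

    ``value`` is present iff ``status == ok``; ``classification`` is
    accumulator/excluder for BF kinds and mobile/immobile for TF kinds, or
    ``None`` when the factor is not calculable.  ``is_bound`` marks upper-bound
    values obtained by substituting a detection limit for a censored numerator.
    """

    element: str
    kind: FactorKind
    value: float | None
    status: FactorStatus
    classification: str | None = None
    is_bound: bool = False

    @property
    def calculable(self) -> bool:
        return self.status is FactorStatus.OK


def _classify(kind: FactorKind, value: float) -> str:
    if kind in _BF_KINDS:
        return "accumulator" if value > 1.0 else "excluder"
    return "mobile" if value > 1.0 else "immobile"


def _ratio_factor(element: str, kind: FactorKind,
                  numerator: float | None, denominator: float | None,
                  numerator_censored: bool, denominator_censored: bool,
                  detection_limit: float | None,
                  censored_numerator_as_bound: bool) -> FactorResult:
    if denominator_censored:
        return FactorResult(element, kind, None, FactorStatus.SUBSTRATE_CENSORED)
    if numerator_censored:
        if censored_numerator_as_bound and detection_limit is not None:
            value = detection_limit / denominator if denominator else None
            if value is None:
                return FactorResult(element, kind, None, FactorStatus.ZERO_DENOMINATOR)
            return FactorResult(element, kind, value, FactorStatus.OK,
                                _classify(kind, value), is_bound=True)
        return FactorResult(element, kind, None, FactorStatus.MUSHROOM_CENSORED)
    if numerator is None or denominator is None:
        raise ValueError("uncensored factor inputs must carry values")
    if numerator < 0 or denominator < 0:
        raise ValueError("concentrations must be nonnegative")
    if denominator == 0:
        return FactorResult(element, kind, None, FactorStatus.ZERO_DENOMINATOR)
    value = numerator / denominator
    return FactorResult(element, kind, value, FactorStatus.OK, _classify(kind, value))


def compute_bf(c_mushroom: float | None, c_substrate: float | None,
               kind: FactorKind = FactorKind.BF_BULK, *, element: str = "",
               mushroom_censored: bool = False, substrate_censored: bool = False,
               detection_limit: float | None = None,
               censored_numerator_as_bound: bool = False) -> FactorResult:
    """Bioaccumulation factor C_mushroom / C_substrate (dimensionless, DM basis).

    Degenerate cases never raise: a censored substrate, censored mushroom value or
    zero substrate concentration are encoded in ``FactorResult.status``.
    """
    if kind not in _BF_KINDS:
        raise ValueError(f"{kind} is not a BF kind")
    return _ratio_factor(element, kind, c_mushroom, c_substrate,
                         mushroom_censored, substrate_censored,
                         detection_limit, censored_numerator_as_bound)


def compute_tf(c_upper: float | None, c_lower: float | None,
               kind: FactorKind = FactorKind.TF_CAP_STIPE, *, element: str = "",
               upper_censored: bool = False, lower_censored: bool = False,
               detection_limit: float | None = None,
               censored_numerator_as_bound: bool = False) -> FactorResult:
    """Translocation factor C_upper / C_lower (cap/stipe or sporophore/cap)."""
    if kind not in _TF_KINDS:
        raise ValueError(f"{kind} is not a TF kind")
    return _ratio_factor(element, kind, c_upper, c_lower,
                         upper_censored, lower_censored,
                         detection_limit, censored_numerator_as_bound)


def classify_translocation_profile(tf_cap_stipe: FactorResult,
                                   tf_spor_cap: FactorResult) -> str:
    """Four-way within-mushroom distribution profile from the two TFs.

    apical_accumulation  both TFs > 1 (element migrates to the sporophore);
    cap_accumulation     cap/stipe > 1 but sporophore/cap <= 1 (the K/Rb pattern);
    stipe_accumulation   both TFs <= 1 (element stays in the stipe);
    erratic              the remaining sign pattern, or any TF not calculable.
    """
    if not (tf_cap_stipe.calculable and tf_spor_cap.calculable):
        return "erratic"
    up1 = tf_cap_stipe.value > 1.0
    up2 = tf_spor_cap.value > 1.0
    if up1 and up2:
        return "apical_accumulation"
    if up1:
        return "cap_accumulation"
    if not up2:
        return "stipe_accumulation"
    return "erratic"


@dataclass(frozen=True)
class ContrastSummary:
    """A mean-level ratio between two groups (sites or sampling sessions)."""

    element: str
    contrast: str  # site_pairwise | temporal_pairwise
    ratio: float | None
    group_a: str
    group_b: str
    basis: str  # soil | mushroom_bulk | part

    @property
    def calculable(self) -> bool:
        return self.ratio is not None


def contrast_ratio(stat_a: SummaryStat, stat_b: SummaryStat, *, element: str = "",
                   contrast: str = "site_pairwise", group_a: str = "a",
                   group_b: str = "b", basis: str = "soil") -> ContrastSummary:
    """Ratio of two group means; not-calculable when either mean is zero."""
    if group_a == group_b:
        raise ValueError("contrast groups must be distinct")
    if stat_a.mean <= 0 or stat_b.mean <= 0:
        return ContrastSummary(element, contrast, None, group_a, group_b, basis)
    return ContrastSummary(element, contrast, stat_a.mean / stat_b.mean,
                           group_a, group_b, basis)


_SUBSTRATES = ("soil_bearing", "soil_free", "soil_mean")


def _substrate_value(summaries: pd.DataFrame, site: str, element: str,
                     substrate: str) -> tuple[float | None, bool]:
    comps = (["soil_bearing", "soil_free"] if substrate == "soil_mean"
             else [substrate])
    rows = summaries[(summaries["site"] == site)
                     & (summaries["element"] == element)
                     & (summaries["compartment"].isin(comps))]
    if rows.empty:
        return None, False
    if rows["censored"].any():
        return None, True
    return float(rows["mean"].mean()), False


_PART_TO_BF = {"stipe": FactorKind.BF_STIPE, "cap": FactorKind.BF_CAP,
               "sporophore": FactorKind.BF_SPOR, "fb_bulk": FactorKind.BF_BULK}


def bf_table(soils: Dataset, mushrooms: Dataset,
             substrate: str = "soil_bearing") -> pd.DataFrame:
    """Mean-level BF per site, element and mushroom compartment.

    ``substrate`` selects the denominator column: the mushroom-bearing soil
    (default, the substrate mushrooms actually draw from), the mushroom-free
    control, or the mean of the pair.
    """
    if substrate not in _SUBSTRATES:
        raise ValueError(f"substrate must be one of {_SUBSTRATES}")
    if soils.summaries is None or mushrooms.summaries is None:
        raise ValueError("bf_table needs summary-level datasets")
    rows = []
    for _, mrow in mushrooms.summaries.iterrows():
        site, element, part = mrow["site"], mrow["element"], mrow["part"]
        c_soil, soil_censored = _substrate_value(
            soils.summaries, site, element, substrate)
        if c_soil is None and not soil_censored:
            continue  # element not reported for this site's soil
        res = compute_bf(
            None if mrow["censored"] else float(mrow["mean"]), c_soil,
            _PART_TO_BF[part], element=element,
            mushroom_censored=bool(mrow["censored"]),
            substrate_censored=soil_censored,
        )
        rows.append({"site": site, "element": element, "kind": res.kind.value,
                     "value": res.value, "status": res.status.value,
                     "classification": res.classification})
    return pd.DataFrame(rows)


def tf_table(mushrooms: Dataset) -> pd.DataFrame:
    """Mean-level TFs and the translocation profile per site and element."""
    if mushrooms.summaries is None:
        raise ValueError("tf_table needs a summary-level dataset")
    summ = mushrooms.summaries
    rows = []
    for (site, element), group in summ.groupby(["site", "element"], sort=False):
        by_part = {r["part"]: r for _, r in group.iterrows()}
        if not {"stipe", "cap", "sporophore"} <= set(by_part):
            continue
        def val(part):
            row = by_part[part]
            return (None if row["censored"] else float(row["mean"]),
                    bool(row["censored"]))
        (c_stipe, stipe_c), (c_cap, cap_c), (c_spor, spor_c) = (
            val("stipe"), val("cap"), val("sporophore"))
        tf_cs = compute_tf(c_cap, c_stipe, FactorKind.TF_CAP_STIPE,
                           element=element, upper_censored=cap_c,
                           lower_censored=stipe_c)
        tf_sc = compute_tf(c_spor, c_cap, FactorKind.TF_SPOR_CAP,
                           element=element, upper_censored=spor_c,
                           lower_censored=cap_c)
        rows.append({"site": site, "element": element,
                     "tf_cap_stipe": tf_cs.value, "tf_spor_cap": tf_sc.value,
                     "profile": classify_translocation_profile(tf_cs, tf_sc)})
    return pd.DataFrame(rows)


def bulk_bf_for_fruiting_body(fb, c_substrate: float | None, element: str,
                              substrate_censored: bool = False) -> FactorResult:
    """BF of the weight-aggregated bulk concentration of one specimen."""
    bulk = bulk_fb_concentration(fb, element)
    return compute_bf(bulk.value, c_substrate, FactorKind.BF_BULK, element=element,
                      mushroom_censored=not bulk.calculable,
                      substrate_censored=substrate_censored)
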