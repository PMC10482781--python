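"""Synthetic datasets with the statistical structure the pipeline assumes.

Element concentrations in soils are positive and right-skewed (printed SDs
approach the means), so the generator draws them lognormally: each site-element
has a median substrate concentration and a geometric SD.  A site-date-replicate
sample is built as

* mushroom-free soil = (median / depletion_effect) x lognormal site noise,
* mushroom-bearing soil = free soil x depletion_effect x mean-one pairing noise,
* stipe = bearing soil x bf_target / (w_s + w_c g1 + w_sp g1 g2) x part noise,
* cap = stipe base x g1, sporophore = cap base x g2 (each with its own noise),

so that the weight-averaged bulk fruiting body targets ``bf_target`` times the
substrate and the part gradient follows the translocation multipliers g1
(stipe->cap) and g2 (cap->sporophore).  Scenario medians therefore describe the
substrate (mushroom-bearing) level, matching how soil tables are printed.

Pairing and part noises are mean-one lognormal (mu = -sigma^2/2), which makes
the expectation of bearing/free exactly the depletion effect: the pipeline's
mean per-pair depletion estimator is unbiased for 100 (1 - effect) by
construction, a property the recovery tests exercise.

Censoring is applied after noise, mirroring measurement reality: any value below
its element's detection limit is emitted as a left-censored record.  All draws
derive from one master seed; the same seed reproduces the dataset bitwise on a
given platform.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import numpy as np
import yaml

from .composition import DM_FRACTIONS
from .data_io import (
    DEFAULT_DATES,
    DEFAULT_DETECTION_LIMITS,
    Compartment,
    ConcentrationRecord,
    Dataset,
    FruitingBody,
    PARTS,
    load_fixture,
)

__all__ = ["SyntheticScenario", "generate", "paper_mimic_scenario"]

#: Study-wide mean part weight fractions (stipe, cap, sporophore) of FB dry mass.
DEFAULT_WEIGHT_FRACTIONS: dict[Compartment, float] = {
    Compartment.STIPE: 0.359, Compartment.CAP: 0.312, Compartment.SPOROPHORE: 0.329,
}

#: Elements injected with a mushroom-bearing-soil depletion in the mimic scenario.
MIMIC_DEPLETED_ELEMENTS = ("Ag", "Cd", "K", "Rb", "Al")


@dataclass
class SyntheticScenario:
    """Generative parameters of one synthetic study.

    ``sites`` maps site -> element -> (median, geometric SD) of the substrate
    soil concentration in mg kg^-1; ``translocation`` maps element -> (g1, g2)
    part-gradient multipliers; ``bf_target`` sets the bulk-FB/substrate ratio;
    ``depletion_effect`` <= 1 multiplies the bearing soil relative to the free
    soil (1 = unaffected).  ``n_dates`` sampling sessions x ``n_replicates``
    fruiting bodies per site-date, all reproducible from ``seed``.
    """

    sites: dict[str, dict[str, tuple[float, float]]]
    translocation: dict[str, tuple[float, float]] = field(default_factory=dict)
    bf_target: dict[str, float] = field(default_factory=dict)
    depletion_effect: dict[str, float] = field(default_factory=dict)
    detection_limits: dict[str, float] = field(default_factory=dict)
    weight_fractions: dict[Compartment, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_FRACTIONS))
    pair_noise_gsd: float = 1.05
    part_noise_gsd: float = 1.15
    n_dates: int = 5
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.weight_fractions = {Compartment(k): float(v)
                                 for k, v in self.weight_fractions.items()}
        for site, elements in self.sites.items():
            for el, (median, gsd) in elements.items():
                if not median > 0:
                    raise ValueError(f"{site}/{el}: median must be positive")
                if not gsd >= 1.0:
                    raise ValueError(f"{site}/{el}: geometric SD must be >= 1")
        for el, (g1, g2) in self.translocation.items():
            if not (g1 > 0 and g2 > 0):
                raise ValueError(f"{el}: translocation multipliers must be positive")
        for el, bf in self.bf_target.items():
            if not bf > 0:
                raise ValueError(f"{el}: bf_target must be positive")
        for el, eff in self.depletion_effect.items():
            if not 0.0 < eff <= 1.0:
                raise ValueError(f"{el}: depletion_effect must be in (0, 1]")
        for el, dl in self.detection_limits.items():
            if not dl > 0:
                raise ValueError(f"{el}: detection limit must be positive")
        if not (self.pair_noise_gsd >= 1.0 and self.part_noise_gsd >= 1.0):
            raise ValueError("noise geometric SDs must be >= 1")
        if self.n_dates < 1 or self.n_replicates < 1:
            raise ValueError("n_dates and n_replicates must be >= 1")

    def dates(self) -> list[str]:
        """Sampling sessions: the study's five year-months, extended monthly."""
        if self.n_dates <= len(DEFAULT_DATES):
            return list(DEFAULT_DATES[: self.n_dates])
        extra = []
        year, month = 2023, 6
        for _ in range(self.n_dates - len(DEFAULT_DATES)):
            extra.append(f"{year}-{month:02d}")
            month += 1
            if month > 12:
                year, month = year + 1, 1
        return list(DEFAULT_DATES) + extra

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["weight_fractions"] = {k.value: v for k, v in self.weight_fractions.items()}
        data["sites"] = {s: {el: list(mv) for el, mv in els.items()}
                         for s, els in self.sites.items()}
        data["translocation"] = {el: list(v) for el, v in self.translocation.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["sites"] = {s: {el: tuple(mv) for el, mv in els.items()}
                         for s, els in data["sites"].items()}
        data["translocation"] = {el: tuple(v)
                                 for el, v in data.get("translocation", {}).items()}
        return cls(**data)


def _mean_one_lognormal(rng: np.random.Generator, gsd: float, size=None):
    """Multiplicative noise with E[X] = 1 (mu = -sigma^2/2)."""
    sigma = math.log(gsd)
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate(scenario: SyntheticScenario) -> Dataset:
    """Draw one dataset from ``scenario``, deterministic under its seed."""
    rng = np.random.default_rng(scenario.seed)
    dls = {**DEFAULT_DETECTION_LIMITS, **scenario.detection_limits}
    w = scenario.weight_fractions
    records: list[ConcentrationRecord] = []
    fruiting_bodies: list[FruitingBody] = []

    def emit(sample_id, site, date, comp, element, value):
        dl = dls.get(element, 0.01)
        if value < dl:
            records.append(ConcentrationRecord(
                sample_id=sample_id, site=site, date=date, compartment=comp,
                element=element, censored=True, detection_limit=dl))
            return None
        records.append(ConcentrationRecord(
            sample_id=sample_id, site=site, date=date, compartment=comp,
            element=element, value=float(value)))
        return float(value)

    # sorted iteration: the draw sequence must not depend on dict insertion order
    for site in sorted(scenario.sites):
        elements = dict(sorted(scenario.sites[site].items()))
        for date in scenario.dates():
            year = int(date[:4])
            dm = DM_FRACTIONS.get(year, DM_FRACTIONS[2021])
            for rep in range(scenario.n_replicates):
                sample_id = f"{site}-{date}-{rep:02d}"
                part_conc: dict[str, dict[Compartment, float | None]] = {}
                for el, (median, gsd) in elements.items():
                    effect = scenario.depletion_effect.get(el, 1.0)
                    sigma = math.log(gsd)
                    free = (median / effect) * (
                        math.exp(sigma * rng.standard_normal()) if sigma else 1.0)
                    bearing = free * effect * _mean_one_lognormal(
                        rng, scenario.pair_noise_gsd)
                    emit(sample_id, site, date, Compartment.SOIL_FREE, el, free)
                    bearing_val = emit(sample_id, site, date,
                                       Compartment.SOIL_BEARING, el, bearing)
                    bf = scenario.bf_target.get(el)
                    if bf is None:
                        continue
                    g1, g2 = scenario.translocation.get(el, (1.0, 1.0))
                    weight_sum = (w[Compartment.STIPE] + w[Compartment.CAP] * g1
                                  + w[Compartment.SPOROPHORE] * g1 * g2)
                    base = bearing * bf / weight_sum
                    gradients = {Compartment.STIPE: 1.0, Compartment.CAP: g1,
                                 Compartment.SPOROPHORE: g1 * g2}
                    part_conc[el] = {}
                    for part in PARTS:
                        value = base * gradients[part] * _mean_one_lognormal(
                            rng, scenario.part_noise_gsd)
                        part_conc[el][part] = emit(sample_id, site, date,
                                                   part, el, value)
                if part_conc:
                    fruiting_bodies.append(FruitingBody(
                        sample_id=sample_id, site=site, date=date,
                        part_concentrations=part_conc,
                        weight_fractions=dict(w), dm_fractions=dict(dm)))
    return Dataset(records=records, fruiting_bodies=fruiting_bodies,
                   provenance=f"synthetic(seed={scenario.seed})")


def _ratio_or(default, num, den):
    if num is None or den is None or den == 0:
        return default
    return num / den


def paper_mimic_scenario(seed: int = 0, n_dates: int = 5,
                         n_replicates: int = 1) -> SyntheticScenario:
    """A scenario whose parameters are read off the packaged study tables.

    Substrate medians and geometric SDs come from the soil table's
    mushroom-bearing means and SDs (elements below detection get DL/2 and a
    moderate spread); bulk-FB targets and part gradients come from the mushroom
    table; the depletion effects for Ag, Cd, K and Rb are the bearing/free
    concentration ratios of the mass-balance table, with a mild effect for Al
    and none elsewhere.
    """
    soils = load_fixture("table1_soils").summaries
    mush = load_fixture("table2_mushrooms").summaries
    table3 = load_fixture("table3_massbalance").reported_amounts

    sites: dict[str, dict[str, tuple[float, float]]] = {}
    for (site, element), group in soils.groupby(["site", "element"], sort=False):
        bearing = group[group["compartment"] == "soil_bearing"].iloc[0]
        if bearing["censored"]:
            median = DEFAULT_DETECTION_LIMITS[element] / 2.0
            gsd = 1.3
        else:
            median = float(bearing["mean"])
            cv = float(bearing["sd"]) / median if median else 0.3
            gsd = min(max(math.exp(cv), 1.05), 2.0)
        sites.setdefault(site, {})[element] = (median, gsd)

    # cross-site mean gradients and BF targets from the mushroom table
    translocation: dict[str, tuple[float, float]] = {}
    bf_target: dict[str, float] = {}
    for element, group in mush.groupby("element", sort=False):
        g1s, g2s, bfs = [], [], []
        for site, sgroup in group.groupby("site", sort=False):
            by_part = {r["part"]: r for _, r in sgroup.iterrows()}
            def mean_of(part):
                row = by_part.get(part)
                if row is None or row["censored"]:
                    return None
                return float(row["mean"])
            stipe, cap, spor, bulk = map(mean_of,
                                         ("stipe", "cap", "sporophore", "fb_bulk"))
            g1s.append(_ratio_or(None, cap, stipe))
            g2s.append(_ratio_or(None, spor, cap))
            soil_median = sites.get(site, {}).get(element, (None,))[0]
            bfs.append(_ratio_or(None, bulk, soil_median))
        g1 = float(np.mean([g for g in g1s if g is not None] or [1.0]))
        g2 = float(np.mean([g for g in g2s if g is not None] or [1.0]))
        translocation[element] = (g1, g2)
        usable = [b for b in bfs if b is not None]
        if usable:
            bf_target[element] = float(np.mean(usable))
        else:
            # mushroom parts below detection: aim well under the limit
            soil_medians = [sites[s][element][0] for s in sites
                            if element in sites[s]]
            dl = DEFAULT_DETECTION_LIMITS[element]
            if soil_medians:
                bf_target[element] = 0.3 * dl / float(np.mean(soil_medians))

    depletion_effect = {el: 1.0 for el in translocation}
    for _, row in table3.iterrows():
        depletion_effect[row["element"]] = (
            float(row["conc_bearing"]) / float(row["conc_free"]))
    depletion_effect["Al"] = 0.95

    return SyntheticScenario(
        sites=sites, translocation=translocation, bf_target=bf_target,
        depletion_effect=depletion_effect,
        detection_limits=dict(DEFAULT_DETECTION_LIMITS),
        n_dates=n_dates, n_replicates=n_replicates, seed=seed,
    )
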