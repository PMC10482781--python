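"""Domain types, validation and I/O for long-format element-concentration tables.

The data model follows the design of field studies that pair fruiting-body samples
with their substrate: every measurement is one :class:`ConcentrationRecord` (a sample,
a site, a sampling month, a compartment, an element, and either a concentration in
mg kg^-1 dry matter or a left-censored below-detection-limit flag).  A
:class:`Dataset` bundles records with part-resolved :class:`FruitingBody` specimens
and an element registry.

Censoring is encoded the way geochemical tables print it: the literal token ``bdl``
in the value column plus a separate ``detection_limit`` column, so numeric cells
stay numeric.

Three packaged fixtures ship with the module: site-level soil summaries
(``table1_soils``), part-resolved mushroom summaries (``table2_mushrooms``) and the
four-element mass-balance table (``table3_massbalance``).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Mapping

import pandas as pd

_log = logging.getLogger(__name__)

__all__ = [
    "ELEMENT_REGISTRY",
    "DEFAULT_SITES",
    "DEFAULT_DETECTION_LIMITS",
    "Compartment",
    "PARTS",
    "ConcentrationRecord",
    "FruitingBody",
    "Dataset",
    "FormatError",
    "ValidationError",
    "read_long_csv",
    "write_long_csv",
    "load_fixture",
]

#: The 33 elements quantified by the reference ICP-OES protocol.
ELEMENT_REGISTRY: tuple[str, ...] = (
    "Ag", "Al", "As", "Ba", "Ca", "Cd", "Co", "Cr", "Cu", "Fe", "Ga",
    "K", "Li", "Mg", "Mn", "Mo", "Na", "Nb", "Ni", "P", "Pb", "Rb",
    "S", "Sb", "Se", "Sn", "Sr", "Ti", "V", "W", "Y", "Zn", "Zr",
)

#: Bedrock types of the three study sites.  Site labels are ordinary strings so the
#: pipeline is not study-locked; these are the defaults the fixtures use.
DEFAULT_SITES: tuple[str, ...] = ("granite", "amphibolite", "serpentinite")

#: The five sampling sessions (year-month) of the two-season field campaign.
DEFAULT_DATES: tuple[str, ...] = ("2021-07", "2021-08", "2021-09", "2022-08", "2022-09")


class Compartment(str, Enum):
    """Where a measurement was taken.

    ``soil_bearing`` is substrate sampled directly beneath a fruiting body,
    ``soil_free`` is the paired control 1.5-2 m away.  ``fb_bulk`` carries
    weight-averaged whole-fruiting-body concentrations so that published bulk
    columns are representable as records.
    """

    SOIL_BEARING = "soil_bearing"
    SOIL_FREE = "soil_free"
    STIPE = "stipe"
    CAP = "cap"
    SPOROPHORE = "sporophore"
    FB_BULK = "fb_bulk"


#: Fruiting-body parts, base to apex.
PARTS: tuple[Compartment, ...] = (
    Compartment.STIPE,
    Compartment.CAP,
    Compartment.SPOROPHORE,
)

_DATE_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


class FormatError(ValueError):
    """A file does not have the documented layout (missing columns, bad header)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (negative value, unknown element, ...)."""


def _load_dl_fixture() -> dict[str, float]:
    with resources.files("mycotrace.fixtures").joinpath("detection_limits.csv").open() as fh:
        frame = pd.read_csv(fh)
    return dict(zip(frame["element"], frame["detection_limit"].astype(float)))


#: Representative per-element detection limits (mg kg^-1 DM).  The reference method
#: states limits only as ranges per element group; one value inside each range is
#: adopted here (e.g. 0.20 for the As/P/Pb/S/Sb/Se/Sn/W group whose range is
#: 0.15-0.35).
DEFAULT_DETECTION_LIMITS: dict[str, float] = _load_dl_fixture()


@dataclass(frozen=True)
class ConcentrationRecord:
    """One element measurement in one compartment of one sample.

    Exactly one of ``value`` / ``censored`` carries information: an uncensored
    record has ``value >= 0`` and no detection limit requirement; a censored
    record has no value and a positive ``detection_limit``.
    """

    sample_id: str
    site: str
    date: str  # "YYYY-MM"
    compartment: Compartment
    element: str
    value: float | None = None
    censored: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not _DATE_RE.match(self.date):
            raise ValidationError(f"date {self.date!r} is not YYYY-MM")
        if not isinstance(self.compartment, Compartment):
            object.__setattr__(self, "compartment", Compartment(self.compartment))
        if self.censored:
            if self.value is not None:
                raise ValidationError(
                    f"{self.sample_id}/{self.element}: censored record carries a value"
                )
            if self.detection_limit is None or not self.detection_limit > 0:
                raise ValidationError(
                    f"{self.sample_id}/{self.element}: censored record needs a "
                    "positive detection_limit"
                )
        else:
            if self.value is None:
                raise ValidationError(
                    f"{self.sample_id}/{self.element}: uncensored record needs a value"
                )
            if self.value < 0:
                raise ValidationError(
                    f"{self.sample_id}/{self.element}: negative concentration "
                    f"{self.value}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.element, self.compartment.value)


# weight fractions must sum to 1 within this tolerance before renormalisation
_WEIGHT_SUM_TOL = 0.02


@dataclass
class FruitingBody:
    """A part-resolved specimen: stipe/cap/sporophore concentrations plus the part
    weight fractions (of fruiting-body dry mass) and dry-matter fractions (of fresh
    mass) needed to aggregate them.

    ``part_concentrations`` maps element -> {part -> value}; a ``None`` value marks
    a below-detection-limit part.  Weight fractions are renormalised to sum exactly
    to 1 on construction; raw sums outside ``1 +/- 0.02`` are rejected.
    """

    sample_id: str
    site: str
    date: str
    part_concentrations: dict[str, dict[Compartment, float | None]]
    weight_fractions: dict[Compartment, float]
    dm_fractions: dict[Compartment, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weight_fractions = {Compartment(k): float(v) for k, v in self.weight_fractions.items()}
        missing = [p for p in PARTS if p not in self.weight_fractions]
        if missing:
            raise ValidationError(f"{self.sample_id}: missing weight fractions {missing}")
        for part, w in self.weight_fractions.items():
            if not 0.0 < w < 1.0:
                raise ValidationError(
                    f"{self.sample_id}: weight fraction {part.value}={w} not in (0,1)"
                )
        total = sum(self.weight_fractions[p] for p in PARTS)
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ValidationError(
                f"{self.sample_id}: weight fractions sum to {total:.4f}, "
                f"outside 1 +/- {_WEIGHT_SUM_TOL}"
            )
        self.weight_fractions = {p: self.weight_fractions[p] / total for p in PARTS}
        self.dm_fractions = {Compartment(k): float(v) for k, v in self.dm_fractions.items()}
        for part, f in self.dm_fractions.items():
            if not 0.0 < f < 1.0:
                raise ValidationError(
                    f"{self.sample_id}: dry-matter fraction {part.value}={f} not in (0,1)"
                )
        self.part_concentrations = {
            el: {Compartment(p): v for p, v in parts.items()}
            for el, parts in self.part_concentrations.items()
        }

    def as_records(self, detection_limits: Mapping[str, float] | None = None
                   ) -> list[ConcentrationRecord]:
        """Represent the specimen's part values as plain records for uniform querying."""
        dls = detection_limits or DEFAULT_DETECTION_LIMITS
        out = []
        for el, parts in self.part_concentrations.items():
            for part, val in parts.items():
                out.append(ConcentrationRecord(
                    sample_id=self.sample_id, site=self.site, date=self.date,
                    compartment=part, element=el,
                    value=val, censored=val is None,
                    detection_limit=None if val is not None else dls.get(el, 0.01),
                ))
        return out


@dataclass
class Dataset:
    """A validated collection of records plus optional part-resolved specimens.

    ``summaries`` (mean/sd/n per group) and ``reported_amounts`` (published
    mass-balance amounts) are carried when a dataset originates from a summary-level
    table such as the packaged fixtures; they are ``None`` for sample-level data.
    """

    records: list[ConcentrationRecord] = field(default_factory=list)
    fruiting_bodies: list[FruitingBody] = field(default_factory=list)
    element_registry: tuple[str, ...] = ELEMENT_REGISTRY
    provenance: str = ""
    summaries: pd.DataFrame | None = None
    reported_amounts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.element not in self.element_registry:
                raise ValidationError(f"unknown element symbol {rec.element!r}")
            if rec.key in seen:
                raise ValidationError(f"duplicate record key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, sample_id: str, element: str, compartment: Compartment | str
            ) -> ConcentrationRecord | None:
        comp = Compartment(compartment).value
        for rec in self.records:
            if rec.key == (sample_id, element, comp):
                return rec
        return None

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per record, censored values as NaN + flag."""
        rows = [{
            "sample_id": r.sample_id, "site": r.site, "date": r.date,
            "compartment": r.compartment.value, "element": r.element,
            "value": r.value, "censored": r.censored,
            "detection_limit": r.detection_limit,
        } for r in self.records]
        return pd.DataFrame(rows, columns=[
            "sample_id", "site", "date", "compartment", "element",
            "value", "censored", "detection_limit"])

    def with_fruiting_body_records(self) -> "Dataset":
        """Return a copy whose record list also contains every fruiting-body part."""
        extra = []
        have = {r.key for r in self.records}
        for fb in self.fruiting_bodies:
            for rec in fb.as_records():
                if rec.key not in have:
                    extra.append(rec)
                    have.add(rec.key)
        return replace(self, records=self.records + extra)


_CSV_COLUMNS = ["sample_id", "site", "date", "compartment", "element",
                "value", "censored", "detection_limit"]
_TRUE_TOKENS = {"yes", "true", "1"}
_BDL_TOKEN = "bdl"


def read_long_csv(path, *, strict: bool = True) -> Dataset:
    """Read a long-format concentration table (one measurement per row).

    Documented header: ``sample_id,site,date,compartment,element,value,censored,
    detection_limit``.  A censored cell is the literal token ``bdl`` in the value
    column (or an empty value with censored=yes) plus a detection limit.

    With ``strict=True`` (default) any invalid row raises a :class:`ValidationError`
    naming the row; with ``strict=False`` invalid rows are logged and dropped.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    records: list[ConcentrationRecord] = []
    rejected = 0
    for i, row in frame.iterrows():
        try:
            raw_value = row["value"].strip()
            censored = (raw_value.lower() == _BDL_TOKEN
                        or row["censored"].strip().lower() in _TRUE_TOKENS)
            value = None
            if not censored:
                if raw_value == "":
                    raise ValidationError("empty value on uncensored row")
                value = float(raw_value)
            dl_raw = row["detection_limit"].strip()
            dl = float(dl_raw) if dl_raw else None
            records.append(ConcentrationRecord(
                sample_id=row["sample_id"].strip(), site=row["site"].strip(),
                date=row["date"].strip(),
                compartment=Compartment(row["compartment"].strip()),
                element=row["element"].strip(),
                value=value, censored=censored, detection_limit=dl,
            ))
        except (ValueError, ValidationError) as exc:
            if strict:
                raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
            rejected += 1
            _log.warning("%s: rejected row %d: %s", path, i + 2, exc)
    if rejected:
        _log.info("%s: %d rows rejected, %d kept", path, rejected, len(records))
    ds = Dataset(records=records, provenance=f"read_long_csv({path})")
    unknown = {r.element for r in records} - set(ds.element_registry)
    if unknown:
        raise ValidationError(f"{path}: unknown element symbols {sorted(unknown)}")
    return ds


def write_long_csv(dataset: Dataset, path) -> None:
    """Write a dataset in the documented long format; round-trips exactly through
    :func:`read_long_csv` (censored cells written as ``bdl`` with their limit)."""
    frame = dataset.to_frame()
    frame["value"] = [
        _BDL_TOKEN if r.censored else _format_number(r.value) for r in dataset.records
    ]
    frame["censored"] = ["yes" if r.censored else "no" for r in dataset.records]
    frame["detection_limit"] = [
        "" if r.detection_limit is None else _format_number(r.detection_limit)
        for r in dataset.records
    ]
    frame.to_csv(path, index=False)


def _format_number(x: float) -> str:
    """repr-based formatting: shortest string that round-trips the float exactly."""
    return repr(float(x))


_FIXTURE_NAMES = ("table1_soils", "table2_mushrooms", "table3_massbalance")


def _read_fixture_csv(name: str) -> pd.DataFrame:
    with resources.files("mycotrace.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def load_fixture(name: str) -> Dataset:
    """Load one of the packaged study tables cell-for-cell.

    ``table1_soils``
        Site-level mean/SD soil concentrations, both paired soil types, n=4 each.
    ``table2_mushrooms``
        Site-level mean/SD concentrations per fruiting-body part plus the bulk
        column and the part weight percentages (attached as fruiting bodies).
    ``table3_massbalance``
        The four-element mass-balance inputs; the published amount columns are
        carried in ``Dataset.reported_amounts``.

    Summary-level means are represented as records with synthetic sample ids
    ``<site>-mean``; the full printed table (means and SDs) is carried in
    ``Dataset.summaries``.
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {_FIXTURE_NAMES}")
    if name == "table1_soils":
        return _load_table1()
    if name == "table2_mushrooms":
        return _load_table2()
    return _load_table3()


def _summary_records(frame: pd.DataFrame, comp_col: str) -> list[ConcentrationRecord]:
    recs = []
    for _, row in frame.iterrows():
        censored = row["censored"] == "yes"
        recs.append(ConcentrationRecord(
            sample_id=f"{row['site']}-mean", site=row["site"], date="2021-07",
            compartment=Compartment(row[comp_col]), element=row["element"],
            value=None if censored else float(row["mean"]),
            censored=censored,
            detection_limit=float(row["detection_limit"]) if censored else None,
        ))
    return recs


def _numeric_summary(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in ("mean", "sd", "detection_limit"):
        out[col] = pd.to_numeric(out[col].replace({"": None, "bdl": None}))
    out["n"] = out["n"].astype(int)
    out["censored"] = out["censored"] == "yes"
    return out


def _load_table1() -> Dataset:
    raw = _read_fixture_csv("table1_soils.csv")
    return Dataset(
        records=_summary_records(raw, "compartment"),
        provenance="fixture:table1_soils",
        summaries=_numeric_summary(raw),
    )


def _load_table2() -> Dataset:
    raw = _read_fixture_csv("table2_mushrooms.csv")
    parts = _read_fixture_csv("table2_parts.csv")
    fbs = []
    for site, group in raw.groupby("site", sort=False):
        conc: dict[str, dict[Compartment, float | None]] = {}
        for _, row in group.iterrows():
            part = Compartment(row["part"])
            if part == Compartment.FB_BULK:
                continue
            conc.setdefault(row["element"], {})[part] = (
                None if row["censored"] == "yes" else float(row["mean"]))
        w = parts[parts["site"] == site]
        weight = {Compartment(r["part"]): float(r["weight_pct"]) / 100.0
                  for _, r in w.iterrows()}
        fbs.append(FruitingBody(
            sample_id=f"{site}-mean", site=site, date="2021-07",
            part_concentrations=conc, weight_fractions=weight,
            dm_fractions={},
        ))
    return Dataset(
        records=_summary_records(raw, "part"),
        fruiting_bodies=fbs,
        provenance="fixture:table2_mushrooms",
        summaries=_numeric_summary(raw),
    )


def _load_table3() -> Dataset:
    raw = _read_fixture_csv("table3_massbalance.csv")
    amounts = raw.copy()
    for col in amounts.columns[1:]:
        amounts[col] = amounts[col].astype(float)
    recs = []
    for _, row in raw.iterrows():
        for comp, col in ((Compartment.SOIL_FREE, "conc_free"),
                          (Compartment.SOIL_BEARING, "conc_bearing"),
                          (Compartment.FB_BULK, "conc_fb")):
            recs.append(ConcentrationRecord(
                sample_id="study-mean", site="pooled", date="2021-07",
                compartment=comp, element=row["element"],
                value=float(row[col]),
            ))
    return Dataset(records=recs, provenance="fixture:table3_massbalance",
                   reported_amounts=amounts)
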