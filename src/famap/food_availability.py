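"""Household food-availability (FA) indicator and livelihood contributions.

FA approximates the potential daily food energy available per male adult
equivalent (kcal cap-1 d-1):

    FA = (E_consumed + E_income) / (365 * n_hh_mae)

``E_consumed`` is the energy of farm produce kept for the household
(produced minus sold, converted via product energy densities) and
``E_income`` converts all cash income (product sales plus off-farm
income) to the energy of the staple food it could buy. Household size is
standardised to male adult equivalents (MAE) with a sex x age weight
table (adult male = 1, 2500 kcal d-1).

Each energy source is attributed to a livelihood activity (crop,
livestock, off-farm) and, within the on-farm activities, to a crop or
livestock group; relative contributions to FA are proportions in [0, 1]
that sum to one whenever FA > 0. Sales income of a product counts toward
that product's own category, in staple-energy terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ProductRecord", "HouseholdSurveyRecord", "EnergyConversionTable",
    "MAEWeights", "FAResult", "ContributionVector",
    "compute_mae", "compute_energy_consumed", "compute_energy_income",
    "compute_fa", "compute_contributions", "filter_households",
    "fa_table", "write_households_csv", "read_households_csv",
    "CROP_GROUPS", "LIVESTOCK_GROUPS", "ACTIVITIES",
]

ACTIVITIES = ("crop", "livestock", "offfarm")
CROP_GROUPS = ("banana", "sorghum", "maize", "cassava", "beans", "coffee", "other")
LIVESTOCK_GROUPS = ("cattle", "poultry", "other")


class EnergyLookupError(KeyError):
    """A product has no entry in the energy conversion table."""


class HouseholdDataError(ValueError):
    """A household record violates a computation precondition."""


@dataclass
class ProductRecord:
    """One product line of a household: production, sales, farm-gate price."""
    product: str
    produced_kg: float
    sold_kg: float
    price_per_kg: float = 0.0

    def __post_init__(self):
        if self.produced_kg < 0 or self.sold_kg < 0 or self.price_per_kg < 0:
            raise HouseholdDataError(
                f"negative quantity/price for product {self.product!r}")


@dataclass
class HouseholdSurveyRecord:
    """One surveyed household with a point location (lon, lat, WGS84)."""
    household_id: str
    lon: float
    lat: float
    members: list[tuple[float, str]]          # (age in years, sex)
    crop_records: list[ProductRecord] = field(default_factory=list)
    livestock_records: list[ProductRecord] = field(default_factory=list)
    offfarm_income: float = 0.0
    land_area_ha: float = 0.0
    herd_size_tlu: float = 0.0

    @property
    def household_size(self) -> int:
        return len(self.members)

    def has_production(self) -> bool:
        return any(r.produced_kg > 0 or r.sold_kg > 0
                   for r in self.crop_records + self.livestock_records)


@dataclass
class EnergyConversionTable:
    """Product energy densities (kcal/kg) plus the staple-food conversion."""
    energy: dict[str, float]                  # product -> kcal/kg
    category: dict[str, str]                  # product -> crop | livestock
    group: dict[str, str]                     # product -> reporting group
    staple: str = "maize"
    staple_price: float = 1.0                 # currency per kg

    def __post_init__(self):
        if self.staple not in self.energy:
            raise HouseholdDataError(f"staple {self.staple!r} missing from table")
        if any(e <= 0 for e in self.energy.values()):
            raise HouseholdDataError("energy densities must be positive")

    @classmethod
    def default(cls, staple_price: float = 1.0) -> "EnergyConversionTable":
        with resources.files("famap.data").joinpath("energy_table.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df, staple="maize", staple_price=staple_price)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, staple: str = "maize",
                   staple_price: float = 1.0) -> "EnergyConversionTable":
        return cls(energy=dict(zip(df["product"], df["energy_kcal_per_kg"].astype(float))),
                   category=dict(zip(df["product"], df["category"])),
                   group=dict(zip(df["product"], df["group"])),
                   staple=staple, staple_price=staple_price)

    @classmethod
    def from_csv(cls, path: str | Path, staple: str = "maize",
                 staple_price: float = 1.0) -> "EnergyConversionTable":
        return cls.from_frame(pd.read_csv(path), staple, staple_price)

    def density(self, product: str) -> float:
        try:
            return self.energy[product]
        except KeyError:
            raise EnergyLookupError(
                f"product {product!r} has no energy-density entry") from None

    @property
    def staple_energy(self) -> float:
        return self.energy[self.staple]


@dataclass
class MAEWeights:
    """Sex x age-band weights relative to an adult male (weight 1)."""
    reference_energy_kcal: float
    bands: list[dict]                         # {sex, age_min, age_max, weight}

    @classmethod
    def default(cls) -> "MAEWeights":
        with resources.files("famap.data").joinpath("mae_weights.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(reference_energy_kcal=float(raw["reference_energy_kcal"]),
                   bands=raw["bands"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MAEWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(reference_energy_kcal=float(raw["reference_energy_kcal"]),
                   bands=raw["bands"])

    def weight(self, age: float, sex: str) -> float:
        sex = sex.lower()
        for band in self.bands:
            bsex = band["sex"].lower()
            if bsex not in ("any", sex):
                continue
            if band["age_min"] <= age <= band["age_max"]:
                return float(band["weight"])
        raise HouseholdDataError(
            f"no MAE weight band covers member (age={age}, sex={sex!r})")


@dataclass
class FAResult:
    FA: float                                 # kcal per MAE per day
    E_consumed: float                         # kcal/yr
    E_income: float                           # kcal/yr
    n_hh_mae: float


@dataclass
class ContributionVector:
    """Relative contributions to FA at three nested levels."""
    activities: dict[str, float]              # crop, livestock, offfarm
    crops: dict[str, float]                   # sums to activities['crop']
    livestock: dict[str, float]               # sums to activities['livestock']
    defined: bool = True                      # False when FA == 0

    def as_flat_dict(self) -> dict[str, float]:
        out = {f"act_{k}": v for k, v in self.activities.items()}
        out.update({f"crop_{k}": v for k, v in self.crops.items()})
        out.update({f"livestock_{k}": v for k, v in self.livestock.items()})
        return out


def compute_mae(members: list[tuple[float, str]], weights: MAEWeights) -> float:
    """Household size in male adult equivalents: sum of member weights."""
    return float(sum(weights.weight(age, sex) for age, sex in members))


def _effective_records(records: list[ProductRecord], strict: bool
                       ) -> list[ProductRecord]:
    out = []
    for rec in records:
        if rec.sold_kg > rec.produced_kg:
            if strict:
                raise HouseholdDataError(
                    f"sold > produced for product {rec.product!r}")
            warnings.warn(
                f"sold > produced for {rec.product!r}; clipping sales to "
                "production", stacklevel=3)
            rec = ProductRecord(rec.product, rec.produced_kg, rec.produced_kg,
                                rec.price_per_kg)
        out.append(rec)
    return out


def compute_energy_consumed(crop_records: list[ProductRecord],
                            livestock_records: list[ProductRecord],
                            energy_table: EnergyConversionTable,
                            strict: bool = False) -> float:
    """Annual energy (kcal/yr) of farm produce kept: sum (produced - sold) * density."""
    total = 0.0
    for rec in _effective_records(crop_records + livestock_records, strict):
        total += (rec.produced_kg - rec.sold_kg) * energy_table.density(rec.product)
    return total


def compute_energy_income(crop_records: list[ProductRecord],
                          livestock_records: list[ProductRecord],
                          offfarm_income: float,
                          energy_table: EnergyConversionTable,
                          strict: bool = False) -> float:
    """Annual income converted to staple energy it could purchase (kcal/yr)."""
    if energy_table.staple_price <= 0:
        raise HouseholdDataError("staple price must be positive")
    sales = sum(rec.sold_kg * rec.price_per_kg
                for rec in _effective_records(crop_records + livestock_records,
                                              strict))
    return (sales + offfarm_income) / energy_table.staple_price \
        * energy_table.staple_energy


def compute_fa(E_consumed: float, E_income: float, n_hh_mae: float) -> FAResult:
    """FA = (E_consumed + E_income) / (365 * n_hh_mae), kcal per MAE per day."""
    if n_hh_mae <= 0:
        raise HouseholdDataError("n_hh_mae must be positive")
    fa = (E_consumed + E_income) / (365.0 * n_hh_mae)
    return FAResult(FA=fa, E_consumed=E_consumed, E_income=E_income,
                    n_hh_mae=n_hh_mae)


def _group_key(product: str, table: EnergyConversionTable) -> tuple[str, str]:
    cat = table.category.get(product)
    grp = table.group.get(product)
    if cat is None or grp is None:
        raise EnergyLookupError(f"product {product!r} has no category/group entry")
    groups = CROP_GROUPS if cat == "crop" else LIVESTOCK_GROUPS
    return cat, (grp if grp in groups else "other")


def compute_contributions(record: HouseholdSurveyRecord,
                          energy_table: EnergyConversionTable,
                          strict: bool = False) -> ContributionVector:
    """Energy-share attribution of FA to activities and product groups.

    Consumed energy of a product and its sales income (in staple-kcal
    terms) both count toward the product's own group; off-farm income
    counts toward the off-farm activity. Shares are energies divided by
    the household's total energy; when total energy is zero the vector
    is all-zero and flagged undefined.
    """
    if energy_table.staple_price <= 0:
        raise HouseholdDataError("staple price must be positive")
    kcal_per_currency = energy_table.staple_energy / energy_table.staple_price

    crops = {g: 0.0 for g in CROP_GROUPS}
    livestock = {g: 0.0 for g in LIVESTOCK_GROUPS}
    for kind, records in (("crop", record.crop_records),
                          ("livestock", record.livestock_records)):
        for rec in _effective_records(records, strict):
            cat, grp = _group_key(rec.product, energy_table)
            energy = (rec.produced_kg - rec.sold_kg) * energy_table.density(rec.product)
            energy += rec.sold_kg * rec.price_per_kg * kcal_per_currency
            (crops if cat == "crop" else livestock)[grp] += energy

    offfarm_energy = record.offfarm_income * kcal_per_currency
    total = sum(crops.values()) + sum(livestock.values()) + offfarm_energy
    if total <= 0:
        return ContributionVector(
            activities={a: 0.0 for a in ACTIVITIES},
            crops={g: 0.0 for g in CROP_GROUPS},
            livestock={g: 0.0 for g in LIVESTOCK_GROUPS},
            defined=False)

    crops = {g: v / total for g, v in crops.items()}
    livestock = {g: v / total for g, v in livestock.items()}
    activities = {"crop": sum(crops.values()),
                  "livestock": sum(livestock.values()),
                  "offfarm": offfarm_energy / total}
    return ContributionVector(activities=activities, crops=crops,
                              livestock=livestock)


def filter_households(records: list[HouseholdSurveyRecord]
                      ) -> tuple[list[HouseholdSurveyRecord], pd.DataFrame]:
    """Apply the study inclusion rules.

    Retained: households with land holdings (land_area > 0) AND at least
    one livelihood activity (any production record or off-farm income).
    Returns the retained records and an exclusion log (one row per
    excluded household with the reason).
    """
    retained, log = [], []
    for rec in records:
        if rec.land_area_ha <= 0:
            log.append({"household_id": rec.household_id,
                        "reason": "no land holdings"})
        elif not rec.has_production() and rec.offfarm_income <= 0:
            log.append({"household_id": rec.household_id,
                        "reason": "no livelihood activities"})
        else:
            retained.append(rec)
    return retained, pd.DataFrame(log, columns=["household_id", "reason"])


def fa_table(records: list[HouseholdSurveyRecord],
             energy_table: EnergyConversionTable | None = None,
             weights: MAEWeights | None = None,
             strict: bool = False) -> pd.DataFrame:
    """Per-household FA and contribution shares as one tidy DataFrame."""
    energy_table = energy_table or EnergyConversionTable.default()
    weights = weights or MAEWeights.default()
    rows = []
    for rec in records:
        n_mae = compute_mae(rec.members, weights)
        e_cons = compute_energy_consumed(rec.crop_records, rec.livestock_records,
                                         energy_table, strict)
        e_inc = compute_energy_income(rec.crop_records, rec.livestock_records,
                                      rec.offfarm_income, energy_table, strict)
        fa = compute_fa(e_cons, e_inc, n_mae)
        contrib = compute_contributions(rec, energy_table, strict)
        row = {"household_id": rec.household_id, "lon": rec.lon, "lat": rec.lat,
               "FA": fa.FA, "E_consumed": e_cons, "E_income": e_inc,
               "n_hh_mae": n_mae, "land_area_ha": rec.land_area_ha,
               "herd_size_tlu": rec.herd_size_tlu,
               "household_size": rec.household_size}
        row.update(contrib.as_flat_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round-trip (households table + child tables for roster and production)

def write_households_csv(records: list[HouseholdSurveyRecord],
                         directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hh_rows, member_rows, prod_rows = [], [], []
    for rec in records:
        hh_rows.append({"household_id": rec.household_id, "lon": rec.lon,
                        "lat": rec.lat, "offfarm_income": rec.offfarm_income,
                        "land_area_ha": rec.land_area_ha,
                        "herd_size_tlu": rec.herd_size_tlu})
        for age, sex in rec.members:
            member_rows.append({"household_id": rec.household_id,
                                "age": age, "sex": sex})
        for kind, recs in (("crop", rec.crop_records),
                           ("livestock", rec.livestock_records)):
            for pr in recs:
                prod_rows.append({"household_id": rec.household_id, "kind": kind,
                                  "product": pr.product,
                                  "produced_kg": pr.produced_kg,
                                  "sold_kg": pr.sold_kg,
                                  "price_per_kg": pr.price_per_kg})
    paths = {"households": directory / "households.csv",
             "members": directory / "members.csv",
             "production": directory / "production.csv"}
    pd.DataFrame(hh_rows).to_csv(paths["households"], index=False)
    pd.DataFrame(member_rows, columns=["household_id", "age", "sex"]) \
        .to_csv(paths["members"], index=False)
    pd.DataFrame(prod_rows, columns=["household_id", "kind", "product",
                                     "produced_kg", "sold_kg", "price_per_kg"]) \
        .to_csv(paths["production"], index=False)
    return paths


def read_households_csv(directory: str | Path) -> list[HouseholdSurveyRecord]:
    directory = Path(directory)
    hh = pd.read_csv(directory / "households.csv",
                     dtype={"household_id": str})
    members = pd.read_csv(directory / "members.csv", dtype={"household_id": str})
    prod = pd.read_csv(directory / "production.csv", dtype={"household_id": str})
    members_by_id = {k: list(zip(g["age"], g["sex"]))
                     for k, g in members.groupby("household_id")}
    prod_by_id = dict(tuple(prod.groupby("household_id"))) if len(prod) else {}
    records = []
    for _, row in hh.iterrows():
        hid = row["household_id"]
        crop_recs, ls_recs = [], []
        if hid in prod_by_id:
            for _, p in prod_by_id[hid].iterrows():
                pr = ProductRecord(p["product"], float(p["produced_kg"]),
                                   float(p["sold_kg"]), float(p["price_per_kg"]))
                (crop_recs if p["kind"] == "crop" else ls_recs).append(pr)
        records.append(HouseholdSurveyRecord(
            household_id=hid, lon=float(row["lon"]), lat=float(row["lat"]),
            members=members_by_id.get(hid, []),
            crop_records=crop_recs, livestock_records=ls_recs,
            offfarm_income=float(row["offfarm_income"]),
            land_area_ha=float(row["land_area_ha"]),
            herd_size_tlu=float(row["herd_size_tlu"])))
    return records
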