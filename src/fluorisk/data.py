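"""Domain types, CSV I/O and bundled reference tables for brewed-tea fluoride data.

The measurement unit throughout is mg fluoride per litre of infusion. Values
below the assay's detection limit are carried as first-class censored
measurements (the stored number is the detection limit, a flag marks the
censoring); how a censored value enters an analysis is decided at analysis
time, never here.

The bundled reference tables describe the brewing study the package models:
sixteen commercial products across five types (five black, three green, three
oolong, three herbal, two white teas), brewed for 5, 10 and 20 minutes in
triplicate, plus the chemistry of six brewing waters and the mean infusible
fluoride that crushed black tea released into each of them.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PRODUCT_TYPES",
    "BREW_TIMES_MIN",
    "LEAF_STATES",
    "WATER_TYPES",
    "DETECTION_LIMIT_MG_PER_L",
    "Measurement",
    "InfusionRecord",
    "InfusionDataset",
    "GroupSummary",
    "WaterProfile",
    "read_infusion_csv",
    "write_infusion_csv",
    "reference_group_summaries",
    "reference_water_profiles",
    "reference_infusible_means_by_water",
]

PRODUCT_TYPES = ("black", "green", "oolong", "herbal", "white")
BREW_TIMES_MIN = (5.0, 10.0, 20.0)
LEAF_STATES = ("uncrushed", "crushed")
WATER_TYPES = ("distilled", "ultrapure", "RO", "tap", "bottled", "bottled_mineral")

#: Assay detection limit for fluoride in water, mg/L.
DETECTION_LIMIT_MG_PER_L = 0.02

#: Column schema of the long-format infusion CSV, one row per replicate.
INFUSION_COLUMNS = (
    "product_type",
    "brand_id",
    "brew_time_min",
    "replicate",
    "leaf_state",
    "fluoride_mg_per_L",
)


@dataclass(frozen=True)
class Measurement:
    """A concentration that may be left-censored at a detection limit.

    When ``censored`` is true, ``value`` holds the detection limit and the
    true concentration is known only to lie below it.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(f"concentration must be finite and >= 0, got {self.value}")

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.censored else f"{self.value:g}"


@dataclass(frozen=True)
class InfusionRecord:
    """One replicate measurement of infusible fluoride from one brand."""

    product_type: str
    brand_id: str
    brew_time_min: float
    replicate: int
    fluoride_mg_per_L: float
    censored: bool = False
    leaf_state: str = "uncrushed"

    def __post_init__(self) -> None:
        if self.product_type not in PRODUCT_TYPES:
            raise ValidationError(
                f"unknown product_type {self.product_type!r}; expected one of {PRODUCT_TYPES}"
            )
        if self.leaf_state not in LEAF_STATES:
            raise ValidationError(
                f"unknown leaf_state {self.leaf_state!r}; expected one of {LEAF_STATES}"
            )
        if not self.brew_time_min > 0:
            raise ValidationError(f"brew_time_min must be positive, got {self.brew_time_min}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not math.isfinite(self.fluoride_mg_per_L) or self.fluoride_mg_per_L < 0:
            raise ValidationError(
                f"fluoride_mg_per_L must be finite and >= 0, got {self.fluoride_mg_per_L}"
            )


@dataclass
class InfusionDataset:
    """An ordered collection of :class:`InfusionRecord`."""

    records: list[InfusionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InfusionRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame; censored values appear as their detection limit
        with a boolean ``censored`` column alongside."""
        return pd.DataFrame(
            {
                "product_type": [r.product_type for r in self.records],
                "brand_id": [r.brand_id for r in self.records],
                "brew_time_min": [r.brew_time_min for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "leaf_state": [r.leaf_state for r in self.records],
                "fluoride_mg_per_L": [r.fluoride_mg_per_L for r in self.records],
                "censored": [r.censored for r in self.records],
            }
        )

    def values(
        self,
        product_type: str | None = None,
        brew_time_min: float | None = None,
        leaf_state: str | None = None,
    ) -> list[float]:
        """Uncensored concentration values matching the given filters."""
        out = []
        for r in self.records:
            if product_type is not None and r.product_type != product_type:
                continue
            if brew_time_min is not None and r.brew_time_min != brew_time_min:
                continue
            if leaf_state is not None and r.leaf_state != leaf_state:
                continue
            if not r.censored:
                out.append(r.fluoride_mg_per_L)
        return out


@dataclass(frozen=True)
class GroupSummary:
    """Per product-type x brew-time digest: brand count, mean and sample SD
    of the brand-level fluoride concentrations (mg/L)."""

    product_type: str
    brew_time_min: float
    n_brands: int
    mean_mg_per_L: float
    sd_mg_per_L: float

    def __post_init__(self) -> None:
        if self.n_brands < 1:
            raise ValidationError(f"n_brands must be >= 1, got {self.n_brands}")
        if self.sd_mg_per_L < 0:
            raise ValidationError(f"sd_mg_per_L must be >= 0, got {self.sd_mg_per_L}")


@dataclass(frozen=True)
class WaterProfile:
    """Chemistry of one brewing water (means of triplicate analyses).

    ``ions`` maps ion name to a :class:`Measurement`, or to None where the ion
    was not detected at all.
    """

    water_type: str
    pH: float
    conductivity_uS_per_cm: float
    fluoride: Measurement
    doc_mg_per_L: float
    ions: Mapping[str, Measurement | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.water_type not in WATER_TYPES:
            raise ValidationError(
                f"unknown water_type {self.water_type!r}; expected one of {WATER_TYPES}"
            )
        if not 0 < self.pH < 14:
            raise ValidationError(f"pH must lie in (0, 14), got {self.pH}")
        if self.conductivity_uS_per_cm < 0 or self.doc_mg_per_L < 0:
            raise ValidationError("conductivity and DOC must be >= 0")


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_fluoride(cell: str, row_number: int) -> tuple[float, bool]:
    cell = cell.strip()
    if cell.startswith("<"):
        rest = cell[1:].strip()
        if rest in ("", "DL"):
            return DETECTION_LIMIT_MG_PER_L, True
        try:
            return float(rest), True
        except ValueError:
            raise SchemaError(
                f"row {row_number}: cannot parse censored fluoride value {cell!r}"
            ) from None
    try:
        value = float(cell)
    except ValueError:
        raise SchemaError(f"row {row_number}: cannot parse fluoride value {cell!r}") from None
    return value, False


def read_infusion_csv(path: str | Path) -> InfusionDataset:
    """Read a long-format infusion CSV into a validated :class:`InfusionDataset`.

    The file must carry exactly the documented header
    ``product_type,brand_id,brew_time_min,replicate,leaf_state,fluoride_mg_per_L``.
    Fluoride cells are plain numbers, or ``<0.02``-style markers (``<DL``
    accepted) for values censored below a detection limit; censoring survives a
    write/read round trip unchanged.

    Raises
    ------
    SchemaError
        If required columns are missing or unexpected columns are present.
    ValidationError
        If any row violates a record invariant (e.g. negative concentration);
        the message names the offending row.
    """
    path = Path(path)
    records: list[InfusionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = tuple(reader.fieldnames or ())
        missing = [c for c in INFUSION_COLUMNS if c not in header]
        extra = [c for c in header if c not in INFUSION_COLUMNS]
        if missing or extra:
            raise SchemaError(
                f"{path}: infusion CSV schema mismatch; missing columns {missing}, "
                f"unexpected columns {extra}"
            )
        for i, row in enumerate(reader, start=2):
            value, censored = _parse_fluoride(row["fluoride_mg_per_L"], i)
            try:
                records.append(
                    InfusionRecord(
                        product_type=row["product_type"].strip(),
                        brand_id=row["brand_id"].strip(),
                        brew_time_min=float(row["brew_time_min"]),
                        replicate=int(row["replicate"]),
                        leaf_state=row["leaf_state"].strip(),
                        fluoride_mg_per_L=value,
                        censored=censored,
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path}, row {i}: {err}") from None
    return InfusionDataset(records)


def write_infusion_csv(
    dataset: InfusionDataset, path: str | Path, provenance: Sequence[str] = ()
) -> None:
    """Write a dataset in the standard long format. Censored values are written
    as ``<limit`` so that read-back reproduces the dataset exactly. Optional
    ``provenance`` lines are emitted as leading ``#`` comments."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(INFUSION_COLUMNS)
        for r in dataset:
            fluoride = (
                f"<{float(r.fluoride_mg_per_L):g}" if r.censored else repr(float(r.fluoride_mg_per_L))
            )
            writer.writerow(
                [r.product_type, r.brand_id, f"{r.brew_time_min:g}", r.replicate, r.leaf_state, fluoride]
            )


# ---------------------------------------------------------------------------
# Bundled reference tables

# (product_type, n_brands, {brew_time: (mean, sd)}), uncrushed leaves.
_REFERENCE_GROUPS: tuple[tuple[str, int, dict[float, tuple[float, float]]], ...] = (
    ("black", 5, {5.0: (2.54, 1.10), 10.0: (2.55, 0.95), 20.0: (2.55, 0.99)}),
    ("green", 3, {5.0: (1.19, 0.22), 10.0: (1.45, 0.28), 20.0: (1.54, 0.44)}),
    ("oolong", 3, {5.0: (0.86, 0.35), 10.0: (0.91, 0.45), 20.0: (0.99, 0.29)}),
    ("herbal", 3, {5.0: (0.40, 0.35), 10.0: (0.36, 0.40), 20.0: (0.41, 0.39)}),
    ("white", 2, {5.0: (0.21, 0.04), 10.0: (0.21, 0.04), 20.0: (0.20, 0.04)}),
)


def reference_group_summaries() -> list[GroupSummary]:
    """The study's type-level fluoride summaries: 5 product types x 3 brewing
    times, with brand counts n = (5, 3, 3, 3, 2) summing to 16 products."""
    return [
        GroupSummary(ptype, t, n, mean, sd)
        for ptype, n, by_time in _REFERENCE_GROUPS
        for t, (mean, sd) in by_time.items()
    ]


def _m(value: float) -> Measurement:
    return Measurement(value)


def _cens() -> Measurement:
    return Measurement(DETECTION_LIMIT_MG_PER_L, censored=True)


def reference_water_profiles() -> list[WaterProfile]:
    """Chemistry of the six brewing waters. Fluoride in distilled, ultrapure
    and reverse-osmosis water sat below the 0.02 mg/L detection limit and is
    returned censored; ions reported as not detected are None."""
    rows = [
        ("distilled", 6.28, 1.50, _cens(), 0.18,
         {"sodium": _m(0.261), "potassium": None, "calcium": None, "magnesium": _m(0.031),
          "chloride": _m(0.55), "bromide": None, "nitrate": None, "sulfate": _m(0.24),
          "phosphate": None}),
        ("ultrapure", 5.94, 2.50, _cens(), 0.30,
         {"sodium": _m(0.280), "potassium": _m(0.015), "calcium": _m(0.024),
          "magnesium": _m(0.087), "chloride": _m(0.63), "bromide": None, "nitrate": None,
          "sulfate": _m(0.15), "phosphate": None}),
        ("RO", 6.02, 70.0, _cens(), 0.13,
         {"sodium": _m(8.091), "potassium": _m(0.458), "calcium": _m(1.285),
          "magnesium": _m(0.547), "chloride": _m(28.85), "bromide": _m(0.032),
          "nitrate": _m(0.640), "sulfate": _m(1.74), "phosphate": None}),
        ("tap", 7.11, 354.0, _m(0.176), 2.72,
         {"sodium": _m(138.72), "potassium": _m(7.616), "calcium": _m(34.379),
          "magnesium": _m(20.009), "chloride": _m(326.75), "bromide": _m(0.576),
          "nitrate": _m(5.144), "sulfate": _m(112.84), "phosphate": None}),
        ("bottled", 7.78, 642.0, _m(0.534), 0.26,
         {"sodium": _m(113.39), "potassium": _m(1.672), "calcium": _m(3.006),
          "magnesium": _m(0.714), "chloride": _m(21.229), "bromide": _m(0.077),
          "nitrate": _m(0.469), "sulfate": _m(39.46), "phosphate": None}),
        ("bottled_mineral", 8.02, 551.0, _m(1.084), 0.20,
         {"sodium": _m(86.55), "potassium": _m(0.976), "calcium": _m(10.753),
          "magnesium": _m(2.756), "chloride": _m(6.390), "bromide": _m(0.050),
          "nitrate": _m(0.537), "sulfate": _m(31.150), "phosphate": None}),
    ]
    return [
        WaterProfile(wt, ph, cond, fluoride, doc, ions)
        for wt, ph, cond, fluoride, doc, ions in rows
    ]


def reference_infusible_means_by_water() -> dict[str, float]:
    """Mean infusible fluoride (mg/L) that crushed black tea released after a
    5-minute brew in each water type."""
    return {
        "distilled": 4.78,
        "ultrapure": 4.51,
        "RO": 4.77,
        "tap": 4.86,
        "bottled": 5.68,
        "bottled_mineral": 5.79,
    }
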