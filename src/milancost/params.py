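"""Model inputs: tariffs, Milan category distributions, risks of malignancy.

The package ships three built-in parameter sets mirroring the three cohort
models commonly compared in salivary-gland FNAC cost analyses:

* ``1a`` — Milan System (MSRSGC) literature estimates, US CPT tariffs,
* ``1b`` — MSRSGC literature estimates, German DRG/OPS + EBM tariffs,
* ``1c`` — a real-world single-center cohort (n = 1289), German tariffs.

Category frequencies for the literature models are published only as ranges
(e.g. "10-20 %", "< 10 %"); the built-ins use range midpoints (open bounds
"< x" taken as x/2, "> x" as the midpoint of (x, 100)) renormalized to sum
to one.  The real-world model uses raw category counts, which are exact.

All probabilities are unit-interval floats; all costs are carried at full
precision in a single fixed currency per table — no currency conversion is
ever performed.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from pathlib import Path
from typing import Annotated, Dict, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "MilanCategory",
    "Procedure",
    "Currency",
    "CostTable",
    "ModelParameters",
    "builtin_parameters",
    "builtin_cost_table",
    "weighted_rom",
    "load_parameters",
    "save_parameters",
    "cost_table_to_csv",
    "cost_table_from_csv",
    "category_table_to_csv",
    "BUILTIN_MODEL_IDS",
    "SUM_TOL",
]

#: tolerance for "probabilities sum to one" structural checks
SUM_TOL = 1e-9

BUILTIN_MODEL_IDS = ("1a", "1b", "1c")

Probability = Annotated[float, Field(ge=0.0, le=1.0)]
Money = Annotated[float, Field(ge=0.0)]


class MilanCategory(str, Enum):
    """The seven MSRSGC reporting categories."""

    I = "I"
    II = "II"
    III = "III"
    IVa = "IVa"
    IVb = "IVb"
    V = "V"
    VI = "VI"

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS = {
    MilanCategory.I: "Non-diagnostic",
    MilanCategory.II: "Non-neoplastic",
    MilanCategory.III: "AUS",
    MilanCategory.IVa: "Neoplasm: benign",
    MilanCategory.IVb: "Neoplasm: SUMP",
    MilanCategory.V: "Suspicious for malignancy",
    MilanCategory.VI: "Malignant",
}


class Procedure(str, Enum):
    """Billable procedures entering the decision pathways."""

    partial_parotidectomy = "partial_parotidectomy"
    submandibulectomy = "submandibulectomy"
    total_parotidectomy_nd = "total_parotidectomy_nd"
    submandibulectomy_nd = "submandibulectomy_nd"
    neck_dissection = "neck_dissection"
    fnac = "fnac"
    frozen_section = "frozen_section"
    repeat_fnac = "repeat_fnac"
    follow_up = "follow_up"


class Currency(str, Enum):
    USD = "USD"
    EUR = "EUR"


class CostTable(BaseModel):
    """Per-procedure monetary costs in one fixed currency.

    All arithmetic downstream stays within a single table; mixing tables of
    different currencies is rejected by the arm builders.
    """

    model_config = ConfigDict(frozen=True)

    currency: Currency
    entries: Dict[Procedure, Money]

    @model_validator(mode="after")
    def _complete(self) -> "CostTable":
        missing = [p.value for p in Procedure if p not in self.entries]
        if missing:
            raise ValueError(f"entries: missing procedures {missing}")
        return self

    def __getitem__(self, procedure: Procedure) -> float:
        return self.entries[procedure]


def _distribution_ok(dist: Dict[MilanCategory, float]) -> bool:
    return (
        set(dist) == set(MilanCategory)
        and abs(sum(dist.values()) - 1.0) <= SUM_TOL
    )


class ModelParameters(BaseModel):
    """Probabilistic inputs of one cohort model.

    ``category_dist`` is the marginal Milan-category distribution of a first
    FNAC; ``rom`` the per-category risk of malignancy on final histology;
    ``site_mix`` the probability that a lesion is parotid (vs submandibular);
    ``iva_surgery_rate`` the fraction of category-IVa (benign neoplasm)
    lesions managed surgically; ``second_fnac_dist`` the category
    distribution of a repeat FNAC after an initial I/III result;
    ``upfront_malignancy_rate`` the malignancy prevalence applied in the
    upfront-surgery arm, where no cytologic stratification exists.
    """

    model_config = ConfigDict(frozen=True)

    model_id: str
    category_dist: Dict[MilanCategory, Probability]
    rom: Dict[MilanCategory, Probability]
    site_mix: Probability
    iva_surgery_rate: Probability
    second_fnac_dist: Dict[MilanCategory, Probability]
    upfront_malignancy_rate: Probability

    @field_validator("rom")
    @classmethod
    def _rom_complete(cls, v: Dict[MilanCategory, float]) -> Dict[MilanCategory, float]:
        if set(v) != set(MilanCategory):
            raise ValueError("rom: must define all seven Milan categories")
        return v

    @model_validator(mode="after")
    def _distributions(self) -> "ModelParameters":
        for name in ("category_dist", "second_fnac_dist"):
            dist = getattr(self, name)
            if set(dist) != set(MilanCategory):
                raise ValueError(f"{name}: must define all seven Milan categories")
            total = sum(dist.values())
            if abs(total - 1.0) > SUM_TOL:
                raise ValueError(
                    f"{name}: probabilities sum to {total!r}, not 1 within {SUM_TOL}"
                )
        return self


def weighted_rom(params: ModelParameters) -> float:
    """Category-weighted mean risk of malignancy, sum(dist * rom).

    The malignancy prevalence implied by the FNAC arm's own inputs; an
    alternative to the calibrated ``upfront_malignancy_rate`` default.
    """
    return sum(params.category_dist[c] * params.rom[c] for c in MilanCategory)


# ---------------------------------------------------------------------------
# Built-in tariffs (2025 US CPT fees; German DRG/OPS groupings, FNAC per EBM)
# ---------------------------------------------------------------------------

_USD_COSTS: Dict[Procedure, float] = {
    Procedure.partial_parotidectomy: 13316.0,
    Procedure.submandibulectomy: 8707.0,
    Procedure.total_parotidectomy_nd: 18456.0,
    Procedure.submandibulectomy_nd: 24103.0,
    Procedure.neck_dissection: 15396.0,
    Procedure.fnac: 141.0,
    # intraoperative frozen section is bundled into the surgical fee
    Procedure.frozen_section: 0.0,
    Procedure.repeat_fnac: 141.0,
    # clinical/radiological follow-up carries no incremental tariff here
    Procedure.follow_up: 0.0,
}

_EUR_COSTS: Dict[Procedure, float] = {
    Procedure.partial_parotidectomy: 5047.34,
    Procedure.submandibulectomy: 3808.19,
    Procedure.total_parotidectomy_nd: 11931.02,
    Procedure.submandibulectomy_nd: 11931.02,
    Procedure.neck_dissection: 9864.74,
    Procedure.fnac: 15.37,
    Procedure.frozen_section: 0.0,
    Procedure.repeat_fnac: 15.37,
    Procedure.follow_up: 0.0,
}


def builtin_cost_table(currency: Union[Currency, str]) -> CostTable:
    """Return the built-in tariff for ``currency`` (``USD`` or ``EUR``)."""
    currency = Currency(currency)
    entries = _USD_COSTS if currency is Currency.USD else _EUR_COSTS
    return CostTable(currency=currency, entries=dict(entries))


# ---------------------------------------------------------------------------
# Built-in probability sets
# ---------------------------------------------------------------------------

# MSRSGC 2nd-edition category frequencies, published as percentage ranges.
# Open bounds: "< x" -> (0, x), "> x" -> (x, 100).
_MSRSGC_FREQ_RANGES: Dict[MilanCategory, tuple] = {
    MilanCategory.I: (10.0, 20.0),
    MilanCategory.II: (15.0, 25.0),
    MilanCategory.III: (0.0, 10.0),
    MilanCategory.IVa: (30.0, 40.0),
    MilanCategory.IVb: (0.0, 10.0),
    MilanCategory.V: (0.0, 5.0),
    MilanCategory.VI: (10.0, 15.0),
}

# MSRSGC per-category risk of malignancy; point estimates where published,
# otherwise midpoints of open bounds ("< 3" -> 1.5, "> 98" -> 99).
_MSRSGC_ROM: Dict[MilanCategory, float] = {
    MilanCategory.I: 0.15,
    MilanCategory.II: 0.11,
    MilanCategory.III: 0.30,
    MilanCategory.IVa: 0.015,
    MilanCategory.IVb: 0.35,
    MilanCategory.V: 0.83,
    MilanCategory.VI: 0.99,
}

# Real-world cohort (n = 1289): category counts and observed ROM.
_RWD_COUNTS: Dict[MilanCategory, int] = {
    MilanCategory.I: 314,
    MilanCategory.II: 182,
    MilanCategory.III: 113,
    MilanCategory.IVa: 501,
    MilanCategory.IVb: 72,
    MilanCategory.V: 54,
    MilanCategory.VI: 53,
}

_RWD_ROM: Dict[MilanCategory, float] = {
    MilanCategory.I: 0.239,
    MilanCategory.II: 0.044,
    MilanCategory.III: 0.345,
    MilanCategory.IVa: 0.010,
    MilanCategory.IVb: 0.153,
    MilanCategory.V: 0.741,
    MilanCategory.VI: 0.962,
}

#: default parotid share of lesions; the published sources do not state the
#: parotid/submandibular split, so this is an explicit, overridable default
DEFAULT_SITE_MIX = 0.8

#: malignancy prevalence of the upfront-surgery arm.  The sources publish no
#: overall prevalence; this default was calibrated once against the published
#: upfront-arm mean costs of all three cohort models (see docs/methods.md)
#: and sits inside the 20-30 % malignancy range reported for salivary gland
#: tumors.  Overridable; ``weighted_rom`` gives the rule-based alternative.
DEFAULT_UPFRONT_MALIGNANCY_RATE = 0.28


def _normalized(weights: Dict[MilanCategory, float]) -> Dict[MilanCategory, float]:
    total = sum(weights.values())
    dist = {c: w / total for c, w in weights.items()}
    # absorb the float residual into the largest cell so the sum is exact
    top = max(dist, key=dist.get)
    dist[top] += 1.0 - sum(dist.values())
    return dist


def _msrsgc_dist() -> Dict[MilanCategory, float]:
    mids = {c: (lo + hi) / 2.0 for c, (lo, hi) in _MSRSGC_FREQ_RANGES.items()}
    return _normalized(mids)


def _rwd_dist() -> Dict[MilanCategory, float]:
    return _normalized({c: float(n) for c, n in _RWD_COUNTS.items()})


def builtin_parameters(model_id: str) -> ModelParameters:
    """Return the built-in parameter set ``1a``, ``1b`` or ``1c``.

    ``1a`` and ``1b`` share the MSRSGC-estimate probabilities (they differ
    only in the tariff applied downstream); ``1c`` uses the real-world
    cohort's category counts and observed per-category malignancy.
    """
    if model_id not in BUILTIN_MODEL_IDS:
        raise ValueError(
            f"unknown model_id {model_id!r}; valid ids: {list(BUILTIN_MODEL_IDS)}"
        )
    if model_id in ("1a", "1b"):
        dist, rom = _msrsgc_dist(), dict(_MSRSGC_ROM)
    else:
        dist, rom = _rwd_dist(), dict(_RWD_ROM)
    return ModelParameters(
        model_id=model_id,
        category_dist=dist,
        rom=rom,
        site_mix=DEFAULT_SITE_MIX,
        iva_surgery_rate=1.0,
        second_fnac_dist=dict(dist),
        upfront_malignancy_rate=DEFAULT_UPFRONT_MALIGNANCY_RATE,
    )


def builtin_currency(model_id: str) -> Currency:
    """Tariff currency conventionally paired with a built-in model."""
    return Currency.USD if model_id == "1a" else Currency.EUR


# ---------------------------------------------------------------------------
# Serialization: JSON / YAML configs, CSV tables
# ---------------------------------------------------------------------------


def _to_plain(obj: Union[CostTable, ModelParameters]) -> dict:
    data = obj.model_dump()
    # enum keys/values -> plain strings for portable configs
    return json.loads(json.dumps(data, default=str))


def save_parameters(obj: Union[CostTable, ModelParameters], path: Union[str, Path]) -> Path:
    """Serialize a cost table or parameter set to JSON or YAML (by suffix)."""
    path = Path(path)
    data = _to_plain(obj)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
    return path


def load_parameters(path: Union[str, Path], schema: str) -> Union[CostTable, ModelParameters]:
    """Load and validate a config file.

    Parameters
    ----------
    path
        JSON or YAML file produced by :func:`save_parameters` (or written by
        hand in the same shape).
    schema
        ``"cost"`` for a :class:`CostTable`, ``"model"`` for
        :class:`ModelParameters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if schema == "cost":
        return CostTable.model_validate(data)
    if schema == "model":
        return ModelParameters.model_validate(data)
    raise ValueError(f"unknown schema {schema!r}; expected 'cost' or 'model'")


def cost_table_to_csv(table: CostTable, path: Union[str, Path]) -> Path:
    """Write a cost table as CSV with columns procedure, cost, currency."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["procedure", "cost", "currency"])
        for proc in Procedure:
            writer.writerow([proc.value, repr(table.entries[proc]), table.currency.value])
    return path


def cost_table_from_csv(path: Union[str, Path]) -> CostTable:
    path = Path(path)
    entries: Dict[Procedure, float] = {}
    currencies = set()
    with path.open() as fh:
        for row in csv.DictReader(fh):
            entries[Procedure(row["procedure"])] = float(row["cost"])
            currencies.add(row["currency"])
    if len(currencies) != 1:
        raise ValueError(f"currency: expected one currency, found {sorted(currencies)}")
    return CostTable(currency=Currency(currencies.pop()), entries=entries)


def category_table_to_csv(params: ModelParameters, path: Union[str, Path]) -> Path:
    """Write the category frequency/ROM table as CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "frequency", "rom"])
        for cat in MilanCategory:
            writer.writerow(
                [cat.value, repr(params.category_dist[cat]), repr(params.rom[cat])]
            )
    return path
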