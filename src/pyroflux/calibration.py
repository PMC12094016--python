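"""Turn batch-culture endpoint measurements into exchange-flux constraints.

Fluxes default to a *batch-yield* basis: one flux unit is one mM of the
compound over the whole batch, so model outputs compare directly to
measured endpoint concentrations.  A specific-rate basis (mmol/gDW/h)
is available via :class:`CalibrationPolicy`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cobra import Model

__all__ = [
    "MeasurementSet",
    "CalibrationPolicy",
    "CalibrationError",
    "read_measurements",
    "write_measurements",
    "apply_culture_mode",
    "calibrate_exchanges",
    "DEFAULT_EXCHANGE_MAP",
]

#: measured compound -> exchange reaction id, for the synthetic core naming
DEFAULT_EXCHANGE_MAP = {
    "cellobiose": "EX_cellb_e",
    "1-propanol": "EX_ppoh_e",
    "propionate": "EX_ppa_c",
    "ethanol": "EX_etoh_c",
    "acetate": "EX_ac_c",
    "acetoin": "EX_actn_c",
}


class CalibrationError(ValueError):
    """Measured compounds could not be mapped onto model exchanges."""


@dataclass(frozen=True)
class MeasurementSet:
    """Endpoint measurements for one strain under one culture condition.

    Concentrations are endpoint mM over the batch; ``protein_yield`` is
    whole-culture protein in ug/mL, the growth proxy used to constrain
    biomass.
    """

    strain: str
    condition: str = "temperature-shift"
    duration_h: float = 112.0
    cellobiose_consumed: float = 0.0
    protein_yield: float = 0.0
    endpoint_products: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    replicates: int | None = None

    def __post_init__(self) -> None:
        if self.cellobiose_consumed < 0:
            raise ValueError("cellobiose_consumed must be >= 0")
        bad = {k: v for k, v in self.endpoint_products.items() if v < 0}
        if bad:
            raise ValueError(f"negative endpoint concentrations: {bad}")

    def product(self, compound: str, default: float = 0.0) -> float:
        return self.endpoint_products.get(compound, default)


@dataclass(frozen=True)
class CalibrationPolicy:
    """How measured quantities become flux bounds.

    ``flux_basis``
        ``"batch-yield"`` (mM per batch, the default reporting basis) or
        ``"specific-rate"`` (mmol/gDW/h; divides every measured quantity by
        ``duration_h``; the gDW normalisation is left to the model's units).
    ``protein_to_dryweight``
        dry weight per protein mass; default 2.0 (protein ~ half of dry
        weight).
    ``biomass_formula_weight``
        ug of dry biomass per umol of the model's biomass unit; converts
        ug/mL dry weight into the batch-yield flux basis (mM).
    """

    flux_basis: str = "batch-yield"
    protein_to_dryweight: float = 2.0
    biomass_formula_weight: float = 50.0
    biomass_treatment: str = "fix"  # "fix" | "upper-bound"
    product_treatment: str = "fix"  # "fix" | "lower-bound"

    def __post_init__(self) -> None:
        if self.flux_basis not in ("batch-yield", "specific-rate"):
            raise ValueError(f"unknown flux_basis {self.flux_basis!r}")
        if self.protein_to_dryweight <= 0 or self.biomass_formula_weight <= 0:
            raise ValueError("conversion factors must be > 0")
        if self.biomass_treatment not in ("fix", "upper-bound"):
            raise ValueError(f"unknown biomass_treatment {self.biomass_treatment!r}")
        if self.product_treatment not in ("fix", "lower-bound"):
            raise ValueError(f"unknown product_treatment {self.product_treatment!r}")

    def scale(self, meas: MeasurementSet) -> float:
        if self.flux_basis == "batch-yield":
            return 1.0
        if meas.duration_h <= 0:
            raise ValueError("specific-rate basis needs duration_h > 0")
        return 1.0 / meas.duration_h

    def biomass_flux(self, meas: MeasurementSet) -> float:
        dry = meas.protein_yield * self.protein_to_dryweight  # ug/mL
        return dry / self.biomass_formula_weight * self.scale(meas)  # mM basis


# ---------------------------------------------------------------------------
# measurement I/O (long CSV: strain, condition, compound, value, unit, se, n)

_CSV_FIELDS = ["strain", "condition", "compound", "value", "unit", "se", "n"]
_SPECIAL = {"cellobiose_consumed": "mM", "protein_yield": "ug/mL",
            "duration": "h"}


def write_measurements(sets: Iterable[MeasurementSet], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for ms in sets:
            rows = [
                ("cellobiose_consumed", ms.cellobiose_consumed, "mM"),
                ("protein_yield", ms.protein_yield, "ug/mL"),
                ("duration", ms.duration_h, "h"),
            ] + [(c, v, "mM") for c, v in ms.endpoint_products.items()]
            for compound, value, unit in rows:
                writer.writerow({
                    "strain": ms.strain, "condition": ms.condition,
                    "compound": compound, "value": value, "unit": unit,
                    "se": ms.standard_errors.get(compound, ""),
                    "n": ms.replicates or "",
                })
    return path


def read_measurements(path: str | Path) -> list[MeasurementSet]:
    """Read one MeasurementSet per (strain, condition) from a long CSV."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        return [MeasurementSet(**entry) for entry in doc]
    grouped: dict[tuple[str, str], dict] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["strain"], row["condition"])
            acc = grouped.setdefault(key, {
                "strain": row["strain"], "condition": row["condition"],
                "endpoint_products": {}, "standard_errors": {},
            })
            compound, value = row["compound"], float(row["value"])
            if row.get("se"):
                acc["standard_errors"][compound] = float(row["se"])
            if row.get("n"):
                acc["replicates"] = int(row["n"])
            if compound == "cellobiose_consumed":
                acc["cellobiose_consumed"] = value
            elif compound == "protein_yield":
                acc["protein_yield"] = value
            elif compound == "duration":
                acc["duration_h"] = value
            else:
                acc["endpoint_products"][compound] = value
    return [MeasurementSet(**acc) for acc in grouped.values()]


# ---------------------------------------------------------------------------
# culture-mode and exchange calibration

def apply_culture_mode(
    model: Model,
    mode: str,
    hydrogenase_ids: tuple[str, str] = ("SHI", "SHII"),
) -> Model:
    """Apply the open/closed culture convention.

    Open cultures lose H2 to the headspace, so the cytoplasmic
    (H2-recapturing) soluble hydrogenases SHI and SHII are constrained to
    zero; closed cultures leave the model untouched.
    """
    if mode not in ("open", "closed"):
        raise ValueError(f"mode must be 'open' or 'closed', got {mode!r}")
    out = model.copy()
    if mode == "closed":
        return out
    missing = [rid for rid in hydrogenase_ids if rid not in out.reactions]
    if missing:
        raise KeyError(
            "open culture mode needs hydrogenase reactions: missing "
            + ", ".join(missing)
        )
    for rid in hydrogenase_ids:
        rxn = out.reactions.get_by_id(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


def calibrate_exchanges(
    model: Model,
    meas: MeasurementSet,
    policy: CalibrationPolicy | None = None,
    exchange_map: Mapping[str, str] | None = None,
    biomass_id: str = "BIOMASS",
    exclude: tuple[str, ...] = (),
) -> Model:
    """Constrain exchanges (and biomass) to the measured batch yields.

    * cellobiose uptake magnitude is upper-bounded at the measured
      consumption (uptake is the negative direction of the exchange);
    * each measured product's exchange is fixed at (default) or
      lower-bounded by its endpoint value, per ``policy.product_treatment``;
    * biomass is fixed at (default) or upper-bounded by
      ``protein_yield x protein_to_dryweight / biomass_formula_weight``;
    * compounds named in ``exclude`` keep their original bounds — used by
      the pipeline to leave the maximisation target unclamped.

    Only tightens bounds; never relaxes them.
    """
    policy = policy or CalibrationPolicy()
    exmap = dict(DEFAULT_EXCHANGE_MAP)
    if exchange_map:
        exmap.update(exchange_map)
    scale = policy.scale(meas)

    wanted = {"cellobiose": meas.cellobiose_consumed}
    wanted.update(meas.endpoint_products)
    missing = [
        c for c in wanted
        if c not in exclude and (c not in exmap or exmap[c] not in model.reactions)
    ]
    if missing:
        raise CalibrationError(
            "no exchange reaction for measured compounds: " + ", ".join(sorted(missing))
        )
    if biomass_id not in model.reactions:
        raise CalibrationError(f"no biomass reaction {biomass_id!r} in model")

    out = model.copy()
    for compound, value in wanted.items():
        if compound in exclude:
            continue
        rxn = out.reactions.get_by_id(exmap[compound])
        flux = value * scale
        if compound == "cellobiose":
            rxn.lower_bound = max(rxn.lower_bound, -flux)  # uptake cap
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
        elif policy.product_treatment == "fix":
            rxn.lower_bound = flux
            rxn.upper_bound = flux
        else:
            rxn.lower_bound = max(rxn.lower_bound, flux)
    bio = out.reactions.get_by_id(biomass_id)
    bflux = policy.biomass_flux(meas)
    if policy.biomass_treatment == "fix":
        bio.lower_bound = bflux
        bio.upper_bound = bflux
    else:
        bio.upper_bound = min(bio.upper_bound, bflux)
    return out
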