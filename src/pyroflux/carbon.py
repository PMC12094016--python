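"""Atom-based carbon-closure accounting for batch fermentations.

Consumed cellobiose carbon (12 C per molecule) is the 100% basis.  Measured
products contribute concentration x carbon atoms; CO2 is calculated from
the fermentation stoichiometry (one CO2 per acetate, one per ethanol, two
per acetoin — the 1-propanol route is CO2-neutral because its carboxylation
re-fixes the CO2 released by pyruvate oxidation); further sinks (compatible
solutes, alanine, EPS, biomass) are estimated from growth data when
coefficients are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .calibration import MeasurementSet

__all__ = [
    "CarbonSpec",
    "EstimationCoefficients",
    "CarbonLedger",
    "LedgerEntry",
    "AccountingError",
    "co2_from_products",
    "carbon_ledger",
]


class AccountingError(ValueError):
    """A measured compound has no carbon-atom entry."""


_DEFAULT_ATOMS = {
    "cellobiose": 12,
    "1-propanol": 3,
    "propionate": 3,
    "ethanol": 2,
    "acetate": 2,
    "acetoin": 4,
    "isoamyl alcohol": 5,
    "CO2": 1,
    "alanine": 3,
    "mannosylglycerate": 9,
    "di-myo-inositol phosphate": 12,
}


@dataclass(frozen=True)
class CarbonSpec:
    """Carbon atoms per molecule for every accounted compound."""

    atoms: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ATOMS))

    def __post_init__(self) -> None:
        bad = {c: n for c, n in self.atoms.items()
               if not isinstance(n, int) or n <= 0}
        if bad:
            raise ValueError(f"carbon counts must be positive integers: {bad}")

    def atoms_of(self, compound: str) -> int:
        try:
            return self.atoms[compound]
        except KeyError:
            raise AccountingError(
                f"no carbon-atom count for compound {compound!r}"
            ) from None


@dataclass(frozen=True)
class EstimationCoefficients:
    """Factors converting growth data into estimated carbon sinks.

    All default to zero: the source factors for the compatible solutes,
    alanine, EPS and biomass are literature-derived and must be supplied
    explicitly by the user — no invented defaults are shipped as truth.

    Units: ``*_per_protein`` are mM solute per ug/mL protein;
    ``alanine_per_cellobiose`` is mM alanine per mM cellobiose consumed;
    ``eps_carbon_per_cellobiose`` is mM-C EPS per mM cellobiose consumed;
    ``biomass_carbon_per_protein`` is mM-C biomass per ug/mL protein.
    """

    mannosylglycerate_per_protein: float = 0.0
    dip_per_protein: float = 0.0
    alanine_per_cellobiose: float = 0.0
    eps_carbon_per_cellobiose: float = 0.0
    biomass_carbon_per_protein: float = 0.0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in asdict(self).items() if v < 0}
        if bad:
            raise ValueError(f"estimation coefficients must be >= 0: {bad}")


@dataclass(frozen=True)
class LedgerEntry:
    compound: str
    source: str  # "measured" | "calculated"
    mm_carbon: float
    percent: float


@dataclass
class CarbonLedger:
    strain: str
    consumed_mm_carbon: float  # cellobiose consumed x 12, the 100% basis
    entries: list[LedgerEntry]

    @property
    def total_percent(self) -> float:
        return sum(e.percent for e in self.entries)

    def percent_of(self, compound: str) -> float:
        for e in self.entries:
            if e.compound == compound:
                return e.percent
        raise KeyError(compound)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(e) for e in self.entries])
        df.insert(0, "strain", self.strain)
        return df

    def to_json(self) -> str:
        return json.dumps({
            "strain": self.strain,
            "consumed_mm_carbon": self.consumed_mm_carbon,
            "total_percent": self.total_percent,
            "entries": [asdict(e) for e in self.entries],
        }, indent=2)

    def __str__(self) -> str:  # display rounds to 1 decimal
        lines = [f"carbon ledger for {self.strain} "
                 f"(basis {self.consumed_mm_carbon:.1f} mM-C consumed)"]
        for e in self.entries:
            lines.append(
                f"  {e.compound:<28s} {e.source:<10s} "
                f"{e.mm_carbon:7.2f} mM-C  {e.percent:5.1f}%"
            )
        lines.append(f"  {'total recovered':<28s} {'':<10s} "
                     f"{'':>7s}       {self.total_percent:5.1f}%")
        return "\n".join(lines)


def co2_from_products(acetate: float, ethanol: float, acetoin: float = 0.0) -> float:
    """CO2 (mM) released alongside the measured fermentation products.

    One CO2 per acetate, one per ethanol, two per acetoin; 1-propanol and
    propionate contribute nothing (their carboxylation re-fixes the CO2
    released upstream, making the route CO2-neutral).
    """
    if acetate < 0 or ethanol < 0 or acetoin < 0:
        raise ValueError("concentrations must be >= 0")
    return acetate + ethanol + 2.0 * acetoin


def carbon_ledger(
    meas: MeasurementSet,
    spec: CarbonSpec | None = None,
    coeffs: EstimationCoefficients | None = None,
) -> CarbonLedger:
    """Full-precision per-compound carbon accounting for one measurement set.

    Measured entries come from the endpoint concentrations; the CO2 entry
    is calculated with :func:`co2_from_products` (absent acetoin and
    isoamyl alcohol default to 0); estimated sinks appear only when their
    coefficients are non-zero.
    """
    spec = spec or CarbonSpec()
    coeffs = coeffs or EstimationCoefficients()
    if meas.cellobiose_consumed <= 0:
        raise ValueError("cellobiose_consumed must be > 0 for a ledger basis")
    basis = meas.cellobiose_consumed * spec.atoms_of("cellobiose")

    entries: list[LedgerEntry] = []

    def add(compound: str, source: str, mm_carbon: float) -> None:
        entries.append(LedgerEntry(
            compound=compound, source=source, mm_carbon=mm_carbon,
            percent=mm_carbon / basis * 100.0,
        ))

    for compound, conc in meas.endpoint_products.items():
        add(compound, "measured", conc * spec.atoms_of(compound))

    co2 = co2_from_products(
        meas.product("acetate"), meas.product("ethanol"), meas.product("acetoin"),
    )
    add("CO2", "calculated", co2 * spec.atoms_of("CO2"))

    protein = meas.protein_yield
    consumed = meas.cellobiose_consumed
    if coeffs.mannosylglycerate_per_protein:
        add("mannosylglycerate", "calculated",
            coeffs.mannosylglycerate_per_protein * protein
            * spec.atoms_of("mannosylglycerate"))
    if coeffs.dip_per_protein:
        add("di-myo-inositol phosphate", "calculated",
            coeffs.dip_per_protein * protein
            * spec.atoms_of("di-myo-inositol phosphate"))
    if coeffs.alanine_per_cellobiose:
        add("alanine", "calculated",
            coeffs.alanine_per_cellobiose * consumed * spec.atoms_of("alanine"))
    if coeffs.eps_carbon_per_cellobiose:
        add("EPS", "calculated", coeffs.eps_carbon_per_cellobiose * consumed)
    if coeffs.biomass_carbon_per_protein:
        add("biomass", "calculated", coeffs.biomass_carbon_per_protein * protein)

    return CarbonLedger(
        strain=meas.strain, consumed_mm_carbon=basis, entries=entries,
    )
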