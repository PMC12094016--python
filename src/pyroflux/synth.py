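"""Desk-scale synthetic inputs: a reduced archaeal fermentation core model
and noisy endpoint measurement sets.

The core is a deliberate caricature of saccharolytic *Thermococcales*
fermentation, small enough for exhaustive LP oracles yet carrying the
couplings the analyses probe: cellobiose hydrolysis, an ATP-neutral
ferredoxin-reducing glycolysis (GAPOR), pyruvate ferredoxin oxidoreductase,
ADP-forming acetyl-CoA synthetase (the host's ATP-yielding step), the
AOR/AdhF route to ethanol, acetolactate synthase to acetoin, the
ferredoxin -> membrane-bound hydrogenase -> ion gradient -> ATP synthase
energy backbone, the Nfn transhydrogenase and soluble hydrogenase I as
NADPH supplies, an acetyl-CoA/ATP-consuming biomass drain, a free
compatible-solute carbon sink, and AMP-yielding maintenance turnover
(which, with adenylate kinase, also recycles the AMP released by the
1-propanol pathway's CoA ligase).

Stoichiometric coefficients are small integers so optima are hand-checkable;
every generated model passes carbon validation with zero findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from cobra import Metabolite, Model, Reaction

from .calibration import MeasurementSet
from .model import DEFAULT_BOUND, validate_model
from .pathway import CofactorPolicy, augment, build_propanol_pathway, add_free_energy_reaction

__all__ = [
    "CoreModelParams",
    "SyntheticMeasurementParams",
    "GenerationError",
    "build_core_model",
    "build_prop_model",
    "random_core_params",
    "simulate_measurements",
    "mean_measurements",
]

REGIMES = ("substrate-limited", "ATP-limited", "redox-limited")

#: Batch-yield endpoint concentrations per mM cellobiose consumed in the
#: bottled temperature-shift reference cultures; these are the conditions
#: the measurement generator emulates.
REFERENCE_YIELDS = {
    "1-propanol": 0.40 / 6.8,
    "propionate": 0.63 / 6.8,
    "ethanol": 9.36 / 6.8,
    "acetate": 6.26 / 6.8,
    "acetoin": 0.0,
}

_REFERENCE_CONSUMED = 6.8  # mM cellobiose over the batch
_REFERENCE_PROTEIN_PER_CELLOBIOSE = 93.65 / 6.87  # ug/mL protein per mM


class GenerationError(RuntimeError):
    """The requested regime could not be verified on the generated model."""


@dataclass(frozen=True)
class CoreModelParams:
    """Knobs of the reduced fermentation core.

    ``regime`` names which resource is meant to cap 1-propanol production
    once the pathway is spliced in; it is enforced by parameter choice and
    verified by LP at build time:

    * ``substrate-limited`` — acetate (the native product) is capped purely
      by the cellobiose bound, at the hand-derivable 4 acetate/cellobiose;
    * ``ATP-limited`` — headspace H2 may be recaptured by SHI, so reductant
      is free and a free-ATP generator strictly raises the 1-propanol
      maximum while free NADPH leaves it flat;
    * ``redox-limited`` — SHI is off and H2 only leaves, so NADPH carries a
      ferredoxin opportunity cost and a free-NADPH generator strictly
      raises the maximum.
    """

    cellobiose_bound: float = 10.22  # mM in the reference medium
    mbh_ions_per_fd: int = 1
    atps_ions_per_atp: int = 3
    biomass_atp: float = 2.0  # ATP per biomass unit (one acetyl equivalent)
    gapor: bool = True  # False -> NADP-dependent GAPN variant
    nfn1: bool = True
    shi: bool = True
    adhf: bool = True
    als: bool = True
    solute_sink: bool = True
    h2_uptake: bool | None = None  # None -> decided by regime
    regime: str = "substrate-limited"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.cellobiose_bound <= 0:
            raise ValueError("cellobiose_bound must be > 0")
        if self.mbh_ions_per_fd < 1 or self.atps_ions_per_atp < 1:
            raise ValueError("ion stoichiometries must be positive integers")

    def resolved(self) -> "CoreModelParams":
        """Fill regime-dependent defaults (H2 recapture, SHI availability)."""
        p = self
        if p.regime == "ATP-limited":
            if p.h2_uptake is None:
                p = replace(p, h2_uptake=True)
            if not p.shi:
                raise ValueError("ATP-limited regime needs SHI for H2 recapture")
        elif p.regime == "redox-limited":
            p = replace(p, shi=False, h2_uptake=False)
        elif p.h2_uptake is None:
            p = replace(p, h2_uptake=False)
        return p


_CORE_METABOLITES = [
    # (id, name, compartment, formula) — carbon-only pseudo-formulas except
    # for carbon-free species, whose formulas simply carry no C.
    ("cellb_e", "cellobiose", "e", "C12"),
    ("glc_c", "glucose", "c", "C6"),
    ("pyr_c", "pyruvate", "c", "C3"),
    ("accoa_c", "acetyl-CoA", "c", "C23"),
    ("coa_c", "coenzyme A", "c", "C21"),
    ("ac_c", "acetate", "c", "C2"),
    ("acald_c", "acetaldehyde", "c", "C2"),
    ("etoh_c", "ethanol", "c", "C2"),
    ("actn_c", "acetoin", "c", "C4"),
    ("co2_c", "carbon dioxide", "c", "C1"),
    ("h2_c", "dihydrogen", "c", "H2"),
    ("fdox_c", "oxidized ferredoxin", "c", "Fe8S8"),
    ("fdred_c", "reduced ferredoxin", "c", "Fe8S8H2"),
    ("nadp_c", "NADP+", "c", "C21"),
    ("nadph_c", "NADPH", "c", "C21"),
    ("atp_c", "ATP", "c", "C10"),
    ("adp_c", "ADP", "c", "C10"),
    ("amp_c", "AMP", "c", "C10"),
    ("pi_c", "phosphate", "c", "HO4P"),
    ("ion_c", "pumped sodium ion (gradient charge)", "c", "Na"),
    ("h2o_c", "water", "c", "H2O"),
    ("biomass_c", "biomass (acetyl-equivalent unit)", "c", "C2"),
    ("sol_c", "compatible solutes / EPS (acetyl-equivalent)", "c", "C2"),
]


def build_core_model(params: CoreModelParams | None = None, verify: bool = True) -> Model:
    """Construct (and, by default, LP-verify) the 25-reaction core."""
    p = (params or CoreModelParams()).resolved()
    model = Model("synthetic_core")
    model.notes["flux_units"] = "mM_per_batch"
    mets = {
        mid: Metabolite(mid, name=name, compartment=comp, formula=formula)
        for mid, name, comp, formula in _CORE_METABOLITES
    }
    model.add_metabolites(list(mets.values()))

    def rxn(rid, name, stoich, lb=0.0, ub=DEFAULT_BOUND, **ann):
        r = Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        model.add_reactions([r])
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        r.annotation.update(ann)
        return r

    off = (0.0, 0.0)
    glyc_red = ("fdox_c", "fdred_c") if p.gapor else ("nadp_c", "nadph_c")
    ox, red = glyc_red

    # substrate uptake and glycolysis
    rxn("EX_cellb_e", "cellobiose exchange", {"cellb_e": -1},
        lb=-p.cellobiose_bound, ub=0.0)
    rxn("CELLB_HYD", "cellobiose uptake and hydrolysis",
        {"cellb_e": -1, "h2o_c": -1, "glc_c": 2})
    rxn("GAPOR" if p.gapor else "GAPN",
        "glycolysis via GAP ferredoxin oxidoreductase (lumped, ATP-neutral)"
        if p.gapor else
        "glycolysis via non-phosphorylating NADP-GAPDH (lumped, ATP-neutral)",
        {"glc_c": -1, ox: -2, "pyr_c": 2, red: 2})
    rxn("POR", "pyruvate ferredoxin oxidoreductase",
        {"pyr_c": -1, "coa_c": -1, "fdox_c": -1,
         "accoa_c": 1, "co2_c": 1, "fdred_c": 1}, ec="1.2.7.1")

    # fermentation branches
    rxn("ACS_acetate", "acetyl-CoA synthetase (ADP-forming)",
        {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
         "ac_c": 1, "atp_c": 1, "coa_c": 1})
    rxn("AOR_acetate", "aldehyde ferredoxin oxidoreductase (acetate)",
        {"ac_c": -1, "fdred_c": -1, "acald_c": 1, "fdox_c": 1, "h2o_c": 1})
    rxn("AdhF", "alcohol dehydrogenase F (acetaldehyde -> ethanol)",
        {"acald_c": -1, "nadph_c": -1, "etoh_c": 1, "nadp_c": 1})
    if not p.adhf:
        model.reactions.AdhF.bounds = off
    rxn("ALS", "acetolactate synthase (lumped to acetoin + CO2)",
        {"pyr_c": -2, "actn_c": 1, "co2_c": 2})
    if not p.als:
        model.reactions.ALS.bounds = off

    # energy backbone
    rxn("MBH", "membrane-bound hydrogenase (ion-pumping)",
        {"fdred_c": -1, "fdox_c": 1, "h2_c": 1, "ion_c": p.mbh_ions_per_fd})
    rxn("ATPS", "ATP synthase (ion-gradient driven)",
        {"ion_c": -p.atps_ions_per_atp, "adp_c": -1, "pi_c": -1,
         "atp_c": 1, "h2o_c": 1})
    rxn("SHI", "soluble hydrogenase I (NADP-reducing)",
        {"h2_c": -1, "nadp_c": -1, "nadph_c": 1})
    if not p.shi:
        model.reactions.SHI.bounds = off
    # SHII is NADH-specific in vivo; the core tracks a single NADPH pool,
    # so it ships closed and exists for the open/closed culture convention.
    rxn("SHII", "soluble hydrogenase II (closed in core)",
        {"h2_c": -1, "nadp_c": -1, "nadph_c": 1}, lb=0.0, ub=0.0)
    rxn("NFN1", "ferredoxin-dependent NADP+ reductase (Nfn, forward)",
        {"fdred_c": -1, "nadp_c": -1, "fdox_c": 1, "nadph_c": 1})
    if not p.nfn1:
        model.reactions.NFN1.bounds = off

    # nucleotide recycling and maintenance
    rxn("ADK", "adenylate kinase", {"amp_c": -1, "atp_c": -1, "adp_c": 2})
    rxn("AMP_MAINT", "AMP-yielding maintenance turnover (lumped)",
        {"atp_c": -1, "h2o_c": -2, "amp_c": 1, "pi_c": 2})

    # biomass and auxiliary sinks
    rxn("BIOMASS", "biomass synthesis (acetyl-equivalent)",
        {"accoa_c": -1, "atp_c": -p.biomass_atp,
         "biomass_c": 1, "coa_c": 1, "adp_c": p.biomass_atp,
         "pi_c": p.biomass_atp})
    rxn("SOLUTES", "compatible solute / EPS synthesis (lumped)",
        {"accoa_c": -1, "atp_c": -1, "sol_c": 1, "coa_c": 1,
         "adp_c": 1, "pi_c": 1})
    if not p.solute_sink:
        model.reactions.SOLUTES.bounds = off

    # exchanges
    rxn("EX_ac_c", "acetate exchange", {"ac_c": -1})
    rxn("EX_etoh_c", "ethanol exchange", {"etoh_c": -1})
    rxn("EX_actn_c", "acetoin exchange", {"actn_c": -1})
    rxn("EX_h2_c", "dihydrogen exchange", {"h2_c": -1},
        lb=-DEFAULT_BOUND if p.h2_uptake else 0.0)
    rxn("EX_co2_c", "carbon dioxide exchange", {"co2_c": -1})
    rxn("EX_h2o_c", "water exchange", {"h2o_c": -1}, lb=-DEFAULT_BOUND)
    rxn("EX_biomass_c", "biomass drain", {"biomass_c": -1})
    rxn("EX_sol_c", "compatible solute drain", {"sol_c": -1})

    model.objective = "EX_ac_c"

    report = validate_model(model)
    if not report.is_clean:
        raise GenerationError(
            "generated core failed validation:\n" + report.to_text()
        )
    if verify:
        _verify_regime(model, p)
    return model


def build_prop_model(
    params: CoreModelParams | None = None,
    policy: CofactorPolicy | None = None,
    e1_cap: float | None = None,
    verify: bool = True,
) -> Model:
    """Core + 1-propanol pathway; optionally throttle the E1 entry step."""
    core = build_core_model(params, verify=verify)
    model = augment(core, build_propanol_pathway(policy))
    if e1_cap is not None:
        model.reactions.E1.upper_bound = e1_cap
    model.objective = "EX_ppoh_e"
    return model


def _verify_regime(core: Model, p: CoreModelParams) -> None:
    from .analysis import maximize, perturbation_sweep  # local: avoid cycle

    if p.regime == "substrate-limited":
        opt, _ = maximize(core, "EX_ac_c")
        expected = 4.0 * p.cellobiose_bound
        if abs(opt - expected) > 1e-6 * max(1.0, expected):
            raise GenerationError(
                f"substrate-limited check failed: max acetate {opt:g} != "
                f"4 x cellobiose bound {expected:g}"
            )
        return

    prop = augment(core, build_propanol_pathway())
    baseline, _ = maximize(prop, "EX_ppoh_e")
    probe = max(baseline, 1.0) * 0.25
    kinds = {"ATP-limited": ("ATP", "NADPH"), "redox-limited": ("NADPH", None)}
    rising, flat = kinds[p.regime]
    m = add_free_energy_reaction(prop, rising)
    curve = perturbation_sweep(m, rising, [0.0, probe])
    if curve.gain_at_origin() <= 1e-6:
        raise GenerationError(
            f"{p.regime} check failed: free {rising} did not raise the "
            f"1-propanol maximum at the origin (baseline {baseline:g})"
        )
    if flat is not None:
        m = add_free_energy_reaction(prop, flat)
        curve = perturbation_sweep(m, flat, [0.0, probe])
        if not curve.is_flat:
            raise GenerationError(
                f"{p.regime} check failed: free {flat} changed the "
                f"1-propanol maximum"
            )


def random_core_params(seed: int, regime: str | None = None) -> CoreModelParams:
    """Draw a random but valid switch configuration (for oracle batteries)."""
    rng = np.random.default_rng(seed)
    regime = regime or str(rng.choice(REGIMES))
    kwargs = dict(
        cellobiose_bound=float(rng.uniform(1.0, 12.0)),
        atps_ions_per_atp=int(rng.integers(1, 5)),
        biomass_atp=float(rng.integers(1, 4)),
        gapor=bool(rng.random() < 0.8),
        nfn1=bool(rng.random() < 0.8),
        adhf=bool(rng.random() < 0.5),
        als=bool(rng.random() < 0.5),
        solute_sink=bool(rng.random() < 0.5),
        regime=regime,
        seed=seed,
    )
    if regime == "ATP-limited":
        kwargs["shi"] = True
    elif regime == "substrate-limited":
        kwargs["shi"] = bool(rng.random() < 0.5)
    return CoreModelParams(**kwargs)


# ---------------------------------------------------------------------------
# measurement simulation

@dataclass(frozen=True)
class SyntheticMeasurementParams:
    """Noise model for emulated endpoint measurement sets.

    Endpoints are ``yield x consumed`` perturbed by independent Gaussian
    noise with the given coefficient of variation, truncated at zero —
    the simplest model consistent with reported standard errors.
    """

    yields: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_YIELDS))
    cellobiose_consumed: float = _REFERENCE_CONSUMED
    protein_per_cellobiose: float = _REFERENCE_PROTEIN_PER_CELLOBIOSE
    cv: float = 0.05
    replicates: int = 3
    duration_h: float = 112.0
    strain: str = "SYN-PROP"
    seed: int = 0

    _CARBON = {"1-propanol": 3, "propionate": 3, "ethanol": 2,
               "acetate": 2, "acetoin": 4, "isoamyl alcohol": 5}

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if any(y < 0 for y in self.yields.values()):
            raise ValueError("yields must be >= 0")
        carbon = sum(
            y * self._CARBON.get(c, 0) for c, y in self.yields.items()
        )
        if carbon > 12.0:
            raise ValueError(
                f"carbon yields sum to {carbon:.2f} C per cellobiose (> 12); "
                "not conservable"
            )


def simulate_measurements(
    params: SyntheticMeasurementParams | None = None,
) -> list[MeasurementSet]:
    """One MeasurementSet per replicate, deterministic given the seed."""
    p = params or SyntheticMeasurementParams()
    rng = np.random.default_rng(p.seed)
    out = []
    for i in range(p.replicates):
        consumed = p.cellobiose_consumed
        endpoints = {}
        for compound, y in p.yields.items():
            mean = y * consumed
            value = mean * (1.0 + p.cv * rng.standard_normal()) if p.cv else mean
            endpoints[compound] = max(value, 0.0)
        protein = p.protein_per_cellobiose * consumed
        if p.cv:
            protein = max(protein * (1.0 + p.cv * rng.standard_normal()), 0.0)
        out.append(MeasurementSet(
            strain=p.strain,
            condition=f"synthetic-replicate-{i + 1}",
            duration_h=p.duration_h,
            cellobiose_consumed=consumed,
            protein_yield=protein,
            endpoint_products=endpoints,
            replicates=p.replicates,
        ))
    return out


def mean_measurements(sets: list[MeasurementSet], strain: str | None = None) -> MeasurementSet:
    """Replicate-averaged MeasurementSet (the calibration input)."""
    if not sets:
        raise ValueError("need at least one measurement set")
    compounds = sorted({c for ms in sets for c in ms.endpoint_products})
    n = len(sets)
    return MeasurementSet(
        strain=strain or sets[0].strain,
        condition="replicate-mean",
        duration_h=float(np.mean([ms.duration_h for ms in sets])),
        cellobiose_consumed=float(np.mean([ms.cellobiose_consumed for ms in sets])),
        protein_yield=float(np.mean([ms.protein_yield for ms in sets])),
        endpoint_products={
            c: float(np.mean([ms.product(c) for ms in sets])) for c in compounds
        },
        replicates=n,
    )
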