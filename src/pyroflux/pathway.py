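"""The heterologous 1-propanol pathway and energy/redox perturbation reactions.

The route runs from acetyl-CoA through the first six enzymes of the archaeal
3-HP/4-HB carbon-fixation cycle (E1-E6) to propionyl-CoA, is cashed out to
propionate by an ADP-forming acetyl-CoA synthetase (regenerating one ATP),
and finished by the native AOR/ADH couple: aldehyde ferredoxin oxidoreductase
reduces propionate to propionaldehyde and an alcohol dehydrogenase reduces
that to 1-propanol.  Accessory reactions: carbonic anhydrase (CO2 <-> HCO3-,
feeding the E1 carboxylation) and inorganic pyrophosphatase (PPi -> 2 Pi,
pulling the E4 ligation).

The carboxylation fixes exactly one CO2 per 1-propanol, cancelling the CO2
released by pyruvate ferredoxin oxidoreductase upstream, so the
pyruvate -> 1-propanol route is CO2-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cobra import Metabolite, Model, Reaction

from .model import DEFAULT_BOUND

__all__ = [
    "CofactorPolicy",
    "ReactionDef",
    "PathwaySpec",
    "SpliceError",
    "build_propanol_pathway",
    "augment",
    "add_free_energy_reaction",
    "PATHWAY_REACTION_IDS",
    "PROPANOL_EXCHANGE_ID",
]

#: Reaction ids of the full pathway in traversal order, then accessories.
PATHWAY_REACTION_IDS = (
    "E1", "E2", "E3", "E4", "E5", "E6",
    "ACS_prop", "AOR_prop", "AdhA", "PROPOHt", "CA", "PPase",
)

PROPANOL_EXCHANGE_ID = "EX_ppoh_e"
PROPIONATE_EXCHANGE_ID = "EX_ppa_c"

#: redox carrier name -> (reduced metabolite id, oxidised metabolite id)
CARRIER_COUPLES = {
    "NADPH": ("nadph_c", "nadp_c"),
    "NADH": ("nadh_c", "nad_c"),
}


class SpliceError(ValueError):
    """Pathway insertion failed (missing metabolites or duplicate ids)."""


@dataclass(frozen=True)
class CofactorPolicy:
    """Which redox couple each reductive step draws on.

    The reductases default to NADPH and the AOR step to reduced ferredoxin,
    matching the host's NADPH-centred anabolic redox pool; each reductase
    can be switched to NADH independently.
    """

    e2: str = "NADPH"
    e3: str = "NADPH"
    e6: str = "NADPH"
    adha: str = "NADPH"
    aor: str = "ferredoxin"

    def couple(self, step: str) -> tuple[str, str]:
        carrier = getattr(self, step)
        if carrier not in CARRIER_COUPLES:
            raise ValueError(f"unknown redox carrier {carrier!r} for {step}")
        return CARRIER_COUPLES[carrier]


@dataclass(frozen=True)
class ReactionDef:
    id: str
    name: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    role: str = ""
    annotation: dict = field(default_factory=dict)


# metabolites the pathway itself introduces (merged by id when present)
_PATHWAY_METABOLITES: dict[str, tuple[str, str, str]] = {
    # id: (name, compartment, carbon-only formula)
    "malcoa_c": ("malonyl-CoA", "c", "C24"),
    "msa_c": ("malonate semialdehyde", "c", "C3"),
    "hp3_c": ("3-hydroxypropionate", "c", "C3"),
    "hp3coa_c": ("3-hydroxypropionyl-CoA", "c", "C24"),
    "acrcoa_c": ("acryloyl-CoA", "c", "C24"),
    "ppcoa_c": ("propionyl-CoA", "c", "C24"),
    "ppa_c": ("propionate", "c", "C3"),
    "ppal_c": ("propionaldehyde", "c", "C3"),
    "ppoh_c": ("1-propanol", "c", "C3"),
    "ppoh_e": ("1-propanol (extracellular)", "e", "C3"),
    "hco3_c": ("bicarbonate", "c", "C1"),
    "ppi_c": ("pyrophosphate", "c", "HO7P2"),
}

# metabolites the host must already provide
_HOST_REQUIRED = (
    "accoa_c", "coa_c", "co2_c", "h2o_c",
    "atp_c", "adp_c", "amp_c", "pi_c",
    "fdred_c", "fdox_c",
)


@dataclass(frozen=True)
class PathwaySpec:
    """Ordered reaction definitions plus the metabolites they introduce."""

    reactions: tuple[ReactionDef, ...]
    metabolites: dict[str, tuple[str, str, str]]
    policy: CofactorPolicy

    def reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def net_stoichiometry(self, ids: tuple[str, ...] | None = None) -> dict[str, float]:
        """Symbolic sum of the named reactions at unit flux."""
        net: dict[str, float] = {}
        for r in self.reactions:
            if ids is not None and r.id not in ids:
                continue
            for met, coef in r.stoichiometry.items():
                net[met] = net.get(met, 0.0) + coef
        return {m: c for m, c in net.items() if abs(c) > 1e-12}

    def to_dict(self) -> dict:
        return {
            "metabolites": [
                {"id": mid, "name": name, "compartment": comp, "formula": formula}
                for mid, (name, comp, formula) in self.metabolites.items()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(r.stoichiometry),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    **({"annotation": dict(r.annotation)} if r.annotation else {}),
                }
                for r in self.reactions
            ],
        }


def load_pathway(path) -> PathwaySpec:
    """Read a PathwaySpec from a YAML fragment in the model schema.

    The file carries ``metabolites`` (id/name/compartment/formula) and
    ``reactions`` (id/name/stoichiometry/bounds) lists; the cofactor policy
    is recovered as the default (it is already baked into the written
    stoichiometries).
    """
    import yaml
    from pathlib import Path

    doc = yaml.safe_load(Path(path).read_text())
    mets = {
        m["id"]: (m.get("name", m["id"]), m.get("compartment", "c"),
                  m.get("formula", ""))
        for m in doc.get("metabolites", [])
    }
    defs = tuple(
        ReactionDef(
            id=r["id"], name=r.get("name", r["id"]),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
            annotation=r.get("annotation", {}),
        )
        for r in doc["reactions"]
    )
    return PathwaySpec(reactions=defs, metabolites=mets, policy=CofactorPolicy())


def build_propanol_pathway(policy: CofactorPolicy | None = None) -> PathwaySpec:
    """The twelve-reaction 1-propanol pathway under a cofactor policy."""
    policy = policy or CofactorPolicy()
    red2, ox2 = policy.couple("e2")
    red3, ox3 = policy.couple("e3")
    red6, ox6 = policy.couple("e6")
    reda, oxa = policy.couple("adha")
    if policy.aor != "ferredoxin":
        raise ValueError("AOR is ferredoxin-dependent; other couples unsupported")

    defs = (
        ReactionDef(
            "E1", "acetyl-CoA/propionyl-CoA carboxylase",
            {"accoa_c": -1, "hco3_c": -1, "atp_c": -1,
             "malcoa_c": 1, "adp_c": 1, "pi_c": 1},
            role="carboxylase", annotation={"ec": "6.4.1.2"},
        ),
        ReactionDef(
            "E2", "malonyl-CoA reductase",
            {"malcoa_c": -1, red2: -1, "msa_c": 1, "coa_c": 1, ox2: 1},
            role="reductase",
        ),
        ReactionDef(
            "E3", "malonate semialdehyde reductase",
            {"msa_c": -1, red3: -1, "hp3_c": 1, ox3: 1},
            role="reductase",
        ),
        ReactionDef(
            "E4", "3-HP-CoA ligase (AMP-forming)",
            {"hp3_c": -1, "coa_c": -1, "atp_c": -1,
             "hp3coa_c": 1, "amp_c": 1, "ppi_c": 1},
            role="ligase",
        ),
        ReactionDef(
            "E5", "3-HP-CoA dehydratase",
            {"hp3coa_c": -1, "acrcoa_c": 1, "h2o_c": 1},
            role="dehydratase",
        ),
        ReactionDef(
            "E6", "acryloyl-CoA reductase",
            {"acrcoa_c": -1, red6: -1, "ppcoa_c": 1, ox6: 1},
            role="reductase",
        ),
        ReactionDef(
            "ACS_prop", "acetyl-CoA synthetase (propionyl-CoA, ADP-forming)",
            {"ppcoa_c": -1, "adp_c": -1, "pi_c": -1,
             "ppa_c": 1, "atp_c": 1, "coa_c": 1},
            role="synthetase",
        ),
        ReactionDef(
            "AOR_prop", "aldehyde ferredoxin oxidoreductase (propionate)",
            {"ppa_c": -1, "fdred_c": -1,
             "ppal_c": 1, "fdox_c": 1, "h2o_c": 1},
            role="aor",
        ),
        ReactionDef(
            "AdhA", "alcohol dehydrogenase A (propionaldehyde)",
            {"ppal_c": -1, reda: -1, "ppoh_c": 1, oxa: 1},
            role="adh",
        ),
        ReactionDef(
            "PROPOHt", "1-propanol diffusion (cytoplasm -> extracellular)",
            {"ppoh_c": -1, "ppoh_e": 1},
            lower_bound=-DEFAULT_BOUND,  # passive diffusion
            role="transport",
        ),
        ReactionDef(
            "CA", "carbonic anhydrase (non-enzymatic CO2 hydration included)",
            {"co2_c": -1, "h2o_c": -1, "hco3_c": 1},
            lower_bound=-DEFAULT_BOUND,
            role="accessory", annotation={"ec": "4.2.1.1"},
        ),
        ReactionDef(
            "PPase", "inorganic pyrophosphatase",
            {"ppi_c": -1, "h2o_c": -1, "pi_c": 2},
            role="accessory", annotation={"ec": "3.6.1.1"},
        ),
    )
    return PathwaySpec(reactions=defs, metabolites=dict(_PATHWAY_METABOLITES),
                       policy=policy)


def augment(model: Model, pathway: PathwaySpec) -> Model:
    """Splice the pathway into a copy of ``model``.

    Adds the pathway's own intermediates (merging by id when the host
    already has them), the twelve reactions, an extracellular 1-propanol
    exchange, and a propionate exchange (propionate is excreted and
    measured extracellularly).  The input model is left untouched.
    """
    needed_carriers = set()
    for step in ("e2", "e3", "e6", "adha"):
        needed_carriers.update(pathway.policy.couple(step))
    missing = [
        mid for mid in (*_HOST_REQUIRED, *sorted(needed_carriers))
        if mid not in model.metabolites and mid not in pathway.metabolites
    ]
    if missing:
        raise SpliceError(
            "host model lacks metabolites required by the pathway: "
            + ", ".join(sorted(set(missing)))
        )
    duplicates = [r.id for r in pathway.reactions if r.id in model.reactions]
    if duplicates:
        raise SpliceError(
            "reaction ids already present in host: " + ", ".join(duplicates)
        )

    out = model.copy()
    new_mets = [
        Metabolite(mid, name=name, compartment=comp, formula=formula)
        for mid, (name, comp, formula) in pathway.metabolites.items()
        if mid not in out.metabolites
    ]
    out.add_metabolites(new_mets)

    rxns = []
    for rdef in pathway.reactions:
        rxn = Reaction(rdef.id, name=rdef.name,
                       lower_bound=rdef.lower_bound, upper_bound=rdef.upper_bound)
        rxns.append((rxn, rdef))
    out.add_reactions([r for r, _ in rxns])
    for rxn, rdef in rxns:
        rxn.add_metabolites({
            out.metabolites.get_by_id(mid): coef
            for mid, coef in rdef.stoichiometry.items()
        })
        rxn.annotation.update(rdef.annotation)

    if PROPANOL_EXCHANGE_ID not in out.reactions:
        ex = Reaction(PROPANOL_EXCHANGE_ID, name="1-propanol exchange",
                      lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        out.add_reactions([ex])
        ex.add_metabolites({out.metabolites.get_by_id("ppoh_e"): -1})
    if PROPIONATE_EXCHANGE_ID not in out.reactions:
        ex = Reaction(PROPIONATE_EXCHANGE_ID, name="propionate exchange",
                      lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        out.add_reactions([ex])
        ex.add_metabolites({out.metabolites.get_by_id("ppa_c"): -1})
    return out


_FREE_REACTIONS = {
    "ATP": ("FREE_ATP", {"pi_c": -1, "adp_c": -1, "atp_c": 1, "h2o_c": 1}),
    "NADPH": ("FREE_NADPH", {"nadp_c": -1, "h2o_c": -1, "nadph_c": 1}),
}


def add_free_energy_reaction(model: Model, kind: str, cap: float = DEFAULT_BOUND) -> Model:
    """Add an artificial generator of ATP or NADPH with bounds (0, cap).

    ``ATP``:   Pi + ADP -> ATP + H2O   (id ``FREE_ATP``)
    ``NADPH``: NADP+ + H2O -> NADPH    (id ``FREE_NADPH``; the released
    proton is not tracked, consistent with carbon-only bookkeeping)
    """
    if kind not in _FREE_REACTIONS:
        raise ValueError(f"kind must be 'ATP' or 'NADPH', got {kind!r}")
    rid, stoich = _FREE_REACTIONS[kind]
    missing = [m for m in stoich if m not in model.metabolites]
    if missing:
        raise SpliceError(
            f"cannot add {rid}: host lacks " + ", ".join(sorted(missing))
        )
    if rid in model.reactions:
        raise SpliceError(f"{rid} already present")
    out = model.copy()
    rxn = Reaction(rid, name=f"free {kind} generator",
                   lower_bound=0.0, upper_bound=cap)
    out.add_reactions([rxn])
    rxn.add_metabolites({out.metabolites.get_by_id(m): c for m, c in stoich.items()})
    return out
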