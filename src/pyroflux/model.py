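"""Load, validate, edit and serialise stoichiometric models.

The in-memory model is a :class:`cobra.Model`; this module adds the I/O
dialects, validation and editing surface shared by every analysis in the
package.  Two dialects are supported:

* SBML Level 3 with FBC flux bounds, via cobrapy's reader/writer;
* a minimal YAML schema (documented in :data:`YAML_SCHEMA_DOC`) convenient
  for hand-written and generated desk-scale models.

Carbon accounting is done per atom from each metabolite's ``formula``;
carbon-only pseudo-formulas (e.g. ``C23`` for acetyl-CoA) are sufficient
and are what the synthetic generator emits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
import numpy as np
import yaml
from cobra import Metabolite, Model, Reaction

__all__ = [
    "DEFAULT_BOUND",
    "FEASIBILITY_TOL",
    "ModelFormatError",
    "ModelValidationError",
    "ValidationFinding",
    "ValidationReport",
    "load_model",
    "write_model",
    "validate_model",
    "knock_out",
    "carbon_atoms",
    "check_flux_vector",
    "stoichiometric_matrix",
]

#: Default magnitude for unspecified flux bounds, in model units.
DEFAULT_BOUND = 1000.0

#: Steady-state / bound feasibility tolerance, in model units.
FEASIBILITY_TOL = 1e-6

YAML_SCHEMA_DOC = """\
name: <model name>
flux_units: <unit label, e.g. mM_per_batch>
objective: <reaction id>
metabolites:
  - id: <token>        # unique
    name: <free text>  # optional
    compartment: c|e
    formula: C3        # optional; carbon-only pseudo-formulas accepted
reactions:
  - id: <token>        # unique
    name: <free text>  # optional
    stoichiometry: {met_id: coeff, ...}   # negative = consumed
    lower_bound: 0     # optional
    upper_bound: 1000  # optional
    reversible: false  # optional; only consulted when bounds are absent
    annotation: {ec: "1.2.7.1"}  # optional
"""


class ModelFormatError(ValueError):
    """A model file failed to parse under the requested dialect."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant (e.g. dangling ids)."""


def carbon_atoms(met: Metabolite) -> int | None:
    """Carbon atoms per molecule, from the formula; ``None`` if unknown."""
    if not met.formula:
        return None
    return int(met.elements.get("C", 0))


def _infer_dialect(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix in {".yaml", ".yml"}:
        return "yaml"
    raise ModelFormatError(
        f"cannot infer model dialect from suffix {suffix!r}; pass dialect="
    )


def load_model(path: str | Path, dialect: str | None = None) -> Model:
    """Read a stoichiometric model from ``path``.

    Parameters
    ----------
    path:
        Model file (SBML ``.xml``/``.sbml`` or YAML ``.yaml``/``.yml``).
    dialect:
        ``"sbml"`` or ``"yaml"``; inferred from the suffix when omitted.

    Exchange reactions are auto-detected as single-metabolite boundary
    reactions.  YAML reactions lacking explicit bounds default to
    ``(0, 1000)``, or ``(-1000, 1000)`` when flagged ``reversible``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises heterogeneous errors
            raise ModelFormatError(f"SBML parse failure in {path}: {exc}") from exc
    elif dialect == "yaml":
        model = _read_yaml_model(path)
    else:
        raise ModelFormatError(f"unknown dialect {dialect!r}")
    _check_structure(model)
    return model


def _read_yaml_model(path: Path) -> Model:
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ModelFormatError(f"YAML parse failure in {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ModelFormatError(f"{path}: top level must be a mapping")
    model = Model(str(doc.get("name", path.stem)))
    if "flux_units" in doc:
        model.notes["flux_units"] = str(doc["flux_units"])

    mets: dict[str, Metabolite] = {}
    for entry in doc.get("metabolites", []):
        try:
            mid = entry["id"]
        except (TypeError, KeyError):
            raise ModelFormatError(f"{path}: metabolite entry without id: {entry!r}")
        if mid in mets:
            raise ModelValidationError(f"{path}: duplicate metabolite id {mid!r}")
        met = Metabolite(
            mid,
            name=entry.get("name", mid),
            compartment=entry.get("compartment", "c"),
            formula=entry.get("formula"),
        )
        mets[mid] = met
    model.add_metabolites(list(mets.values()))

    dangling: list[str] = []
    reactions = []
    seen: set[str] = set()
    for entry in doc.get("reactions", []):
        try:
            rid = entry["id"]
            stoich = entry["stoichiometry"]
        except (TypeError, KeyError):
            raise ModelFormatError(
                f"{path}: reaction entry missing id/stoichiometry: {entry!r}"
            )
        if rid in seen:
            raise ModelValidationError(f"{path}: duplicate reaction id {rid!r}")
        seen.add(rid)
        if not stoich:
            raise ModelValidationError(f"{path}: reaction {rid!r} has empty stoichiometry")
        lb = entry.get("lower_bound")
        ub = entry.get("upper_bound")
        if lb is None:
            lb = -DEFAULT_BOUND if entry.get("reversible", False) else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        rxn = Reaction(rid, name=entry.get("name", rid), lower_bound=float(lb),
                       upper_bound=float(ub))
        missing = [m for m in stoich if m not in mets]
        if missing:
            dangling.extend(f"{rid}:{m}" for m in missing)
            continue
        rxn.add_metabolites({mets[m]: float(c) for m, c in stoich.items()})
        if "annotation" in entry:
            rxn.annotation.update(entry["annotation"])
        reactions.append(rxn)
    if dangling:
        raise ModelValidationError(
            f"{path}: dangling metabolite references: {', '.join(sorted(dangling))}"
        )
    model.add_reactions(reactions)
    objective = doc.get("objective")
    if objective:
        if objective not in model.reactions:
            raise ModelValidationError(f"{path}: objective {objective!r} not a reaction")
        model.objective = objective
    return model


def write_model(model: Model, path: str | Path, dialect: str | None = None) -> Path:
    """Serialise ``model`` to ``path`` in the named (or inferred) dialect."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif dialect == "yaml":
        path.write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))
    else:
        raise ModelFormatError(f"unknown dialect {dialect!r}")
    return path


def model_to_dict(model: Model) -> dict:
    """The model as a plain dict in the YAML schema."""
    objective = None
    for rxn in model.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    doc: dict = {"name": model.id or "model"}
    if model.notes.get("flux_units"):
        doc["flux_units"] = model.notes["flux_units"]
    if objective:
        doc["objective"] = objective
    doc["metabolites"] = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment or "c",
            **({"formula": m.formula} if m.formula else {}),
        }
        for m in model.metabolites
    ]
    doc["reactions"] = [
        {
            "id": r.id,
            "name": r.name,
            "stoichiometry": {m.id: float(c) for m, c in r.metabolites.items()},
            "lower_bound": float(r.lower_bound),
            "upper_bound": float(r.upper_bound),
            **({"annotation": dict(r.annotation)} if r.annotation else {}),
        }
        for r in model.reactions
    ]
    return doc


def _check_structure(model: Model) -> None:
    problems = []
    for rxn in model.reactions:
        if not rxn.metabolites:
            problems.append(f"reaction {rxn.id} has empty stoichiometry")
    if problems:
        raise ModelValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# validation report

@dataclass(frozen=True)
class ValidationFinding:
    kind: str  # "carbon_imbalance" | "bound_violation" | "orphan_metabolite"
    subject: str  # reaction or metabolite id
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[ValidationFinding]:
        return [f for f in self.findings if f.kind == kind]

    def to_json(self) -> str:
        return json.dumps(
            [f.__dict__ for f in self.findings], indent=2, sort_keys=True
        )

    def to_text(self) -> str:
        if self.is_clean:
            return "model is internally consistent\n"
        return "".join(
            f"{f.kind}\t{f.subject}\t{f.message}\n" for f in self.findings
        )


def validate_model(model: Model, carbon_tol: float = 1e-9) -> ValidationReport:
    """Check per-reaction carbon balance, bound sanity and orphan metabolites.

    Exchange (single-metabolite boundary) reactions are exempt from the
    carbon balance — they *are* the system boundary.  Reactions whose
    metabolites all lack formulas are skipped rather than flagged.
    """
    report = ValidationReport()
    boundary = {r.id for r in model.boundary}
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            report.findings.append(ValidationFinding(
                "bound_violation", rxn.id,
                f"lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}",
            ))
        if rxn.id in boundary:
            continue
        atoms = {m: carbon_atoms(m) for m in rxn.metabolites}
        if all(a is None for a in atoms.values()):
            continue
        balance = sum(
            coef * (atoms[m] or 0) for m, coef in rxn.metabolites.items()
        )
        if abs(balance) > carbon_tol:
            report.findings.append(ValidationFinding(
                "carbon_imbalance", rxn.id,
                f"net carbon {balance:+g} atoms per unit flux",
            ))
    for met in model.metabolites:
        if not met.reactions:
            report.findings.append(ValidationFinding(
                "orphan_metabolite", met.id, "referenced by no reaction",
            ))
    return report


def knock_out(model: Model, reaction_id: str) -> Model:
    """Return a copy of ``model`` with both bounds of ``reaction_id`` at 0."""
    if reaction_id not in model.reactions:
        raise KeyError(f"no reaction {reaction_id!r} in model {model.id!r}")
    out = model.copy()
    rxn = out.reactions.get_by_id(reaction_id)
    rxn.lower_bound = 0.0
    rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# flux-vector checks shared by the analyses and the sampler

def stoichiometric_matrix(model: Model) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense S (metabolites x reactions) with row and column id lists."""
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    mi = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[mi[met.id], j] = coef
    return S, mets, rxns


def check_flux_vector(
    model: Model,
    fluxes: Mapping[str, float],
    tol: float = FEASIBILITY_TOL,
) -> tuple[bool, float, float]:
    """Verify S.v = 0 and bound satisfaction for a flux vector.

    Returns ``(ok, max_steady_state_residual, max_bound_violation)``.
    Reactions absent from ``fluxes`` are treated as zero flux.
    """
    S, _, rxns = stoichiometric_matrix(model)
    v = np.array([float(fluxes.get(r, 0.0)) for r in rxns])
    residual = float(np.max(np.abs(S @ v))) if len(v) else 0.0
    bound_violation = 0.0
    for rxn, val in zip(model.reactions, v):
        bound_violation = max(
            bound_violation, rxn.lower_bound - val, val - rxn.upper_bound
        )
    bound_violation = float(max(bound_violation, 0.0))
    return residual <= tol and bound_violation <= tol, residual, bound_violation
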