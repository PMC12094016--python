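"""Linear-programming analyses: FBA, FVA, yield sweeps and perturbations.

All solves go through cobrapy's optlang layer (GLPK).  Optima are
contractual; optimal vertices are solver-dependent and reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cobra import Model
from cobra.flux_analysis import flux_variability_analysis

from .model import FEASIBILITY_TOL

__all__ = [
    "InfeasibleModelError",
    "UnboundedModelError",
    "YieldSweepResult",
    "PerturbationCurve",
    "maximize",
    "flux_variability",
    "yield_sweep",
    "perturbation_sweep",
]


class InfeasibleModelError(RuntimeError):
    """The constraint set admits no steady-state flux vector."""


class UnboundedModelError(RuntimeError):
    """The objective is unbounded over the feasible polytope."""


def _solve(model: Model, objective: str | None, sense: str = "max"):
    with model as m:
        if objective is not None:
            if objective not in m.reactions:
                raise KeyError(f"no reaction {objective!r}")
            m.objective = objective
        m.objective_direction = "max" if sense == "max" else "min"
        obj = m.slim_optimize(error_value=float("nan"))  # probe, no raise
        status = m.solver.status
        if status == "infeasible":
            tight = [
                r.id for r in m.reactions
                if r.lower_bound == r.upper_bound and r.lower_bound != 0
            ]
            raise InfeasibleModelError(
                "model infeasible; equality-constrained reactions to inspect: "
                + (", ".join(tight[:10]) or "none")
            )
        if status == "unbounded":
            free = [
                r.id for r in m.reactions
                if r.upper_bound >= 1e3 and r.id == (objective or "")
            ] or [objective or "objective"]
            raise UnboundedModelError(
                f"objective unbounded; candidate ray member: {free[0]}"
            )
        if status != "optimal":
            raise RuntimeError(f"solver returned status {status!r}")
        return m.optimize()


def maximize(model: Model, objective: str | None = None) -> tuple[float, pd.Series]:
    """LP maximum of ``objective`` (or the model's objective) and one vertex."""
    solution = _solve(model, objective, "max")
    return float(solution.objective_value), solution.fluxes.copy()


def flux_variability(
    model: Model,
    reactions: str | list[str],
    fixed: dict[str, float] | None = None,
) -> tuple[float, float] | pd.DataFrame:
    """Feasible flux range(s) with optional reactions fixed at given values.

    A single reaction id returns ``(min, max)``; a list returns a DataFrame
    with ``minimum``/``maximum`` columns indexed by reaction id.
    """
    single = isinstance(reactions, str)
    rxn_list = [reactions] if single else list(reactions)
    with model as m:
        for rid, value in (fixed or {}).items():
            m.reactions.get_by_id(rid).bounds = (value, value)
        try:
            _solve(m, None, "max")  # feasibility gate with a clear error
        except UnboundedModelError:
            pass
        df = flux_variability_analysis(
            m, reaction_list=rxn_list, fraction_of_optimum=0.0,
        )
    if single:
        row = df.loc[rxn_list[0]]
        return float(row["minimum"]), float(row["maximum"])
    return df.astype(float)


@dataclass
class YieldSweepResult:
    """Per-reaction feasible ranges as the target is stepped 0 -> max."""

    target: str
    steps: np.ndarray  # imposed target fluxes, strictly increasing
    minimum: pd.DataFrame  # steps x reactions
    maximum: pd.DataFrame
    scaled_minimum: pd.DataFrame
    scaled_maximum: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, step in enumerate(self.steps):
            for rid in self.minimum.columns:
                rows.append({
                    "reaction": rid, "step": float(step),
                    "min": self.minimum.iloc[i][rid],
                    "max": self.maximum.iloc[i][rid],
                    "scaled_min": self.scaled_minimum.iloc[i][rid],
                    "scaled_max": self.scaled_maximum.iloc[i][rid],
                })
        return pd.DataFrame(rows)


def yield_sweep(
    model: Model,
    target: str,
    reactions: list[str],
    n_steps: int = 40,
) -> YieldSweepResult:
    """FVA of ``reactions`` at ``n_steps`` imposed target fluxes in [0, max].

    The upper endpoint is the model's own maximum for ``target``.  Scaled
    ranges divide each reaction by its largest absolute range endpoint over
    all steps (zero-range reactions scale to 0), landing in [-1, 1].
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    top, _ = maximize(model, target)
    steps = np.linspace(0.0, top, n_steps)
    mins, maxs = [], []
    for i, step in enumerate(steps):
        try:
            df = flux_variability(model, reactions, fixed={target: float(step)})
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(
                f"sweep infeasible at step {i} (target={step:g}): {exc}"
            ) from exc
        mins.append(df["minimum"])
        maxs.append(df["maximum"])
    minimum = pd.DataFrame(mins, index=range(n_steps))
    maximum = pd.DataFrame(maxs, index=range(n_steps))
    denom = pd.concat([minimum.abs(), maximum.abs()]).max()
    denom = denom.where(denom > FEASIBILITY_TOL, 1.0)  # zero-range -> 0/1 = 0
    return YieldSweepResult(
        target=target, steps=steps, minimum=minimum, maximum=maximum,
        scaled_minimum=minimum / denom, scaled_maximum=maximum / denom,
    )


@dataclass
class PerturbationCurve:
    """Maximum target yield as a free ATP/NADPH generator is dialled up."""

    free_reaction: str
    target: str
    grid: np.ndarray
    optimum: np.ndarray

    @property
    def is_flat(self) -> bool:
        return bool(np.max(self.optimum) - np.min(self.optimum) <= 1e-6)

    def gain_at_origin(self) -> float:
        """Optimum increase from the first to the second grid point."""
        if len(self.grid) < 2:
            return 0.0
        return float(self.optimum[1] - self.optimum[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "imposed_flux": self.grid, "max_target": self.optimum,
        })


def perturbation_sweep(
    model: Model,
    kind: str,
    grid: np.ndarray | list[float],
    target: str = "EX_ppoh_e",
) -> PerturbationCurve:
    """Fix the FREE_ATP/FREE_NADPH flux at each grid value, maximize target.

    The model must already carry the corresponding free reaction (see
    :func:`pyroflux.pathway.add_free_energy_reaction`).
    """
    rid = {"ATP": "FREE_ATP", "NADPH": "FREE_NADPH"}.get(kind)
    if rid is None:
        raise ValueError(f"kind must be 'ATP' or 'NADPH', got {kind!r}")
    if rid not in model.reactions:
        raise KeyError(f"model lacks {rid}; augment it first")
    grid = np.asarray(grid, dtype=float)
    cap = model.reactions.get_by_id(rid).upper_bound
    over = grid[grid > cap + FEASIBILITY_TOL]
    if over.size:
        raise ValueError(f"grid values exceed the {rid} cap {cap:g}: {over[:3]}")
    optima = []
    for value in grid:
        with model as m:
            rxn = m.reactions.get_by_id(rid)
            rxn.lower_bound = float(value)
            rxn.upper_bound = float(value)
            opt, _ = maximize(m, target)
        optima.append(opt)
    return PerturbationCurve(
        free_reaction=rid, target=target, grid=grid,
        optimum=np.asarray(optima),
    )
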