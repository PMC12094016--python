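"""Uniform-like sampling of the steady-state flux polytope.

Sampling uses cobrapy's OptGP sampler (a multi-chain artery/hit-and-run
scheme).  Chains are run sequentially in one process with per-chain seeds
derived deterministically from the user seed, so a given seed reproduces
the sample matrix bit-for-bit regardless of CPU count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cobra import Model
from cobra.sampling import OptGPSampler

from .model import FEASIBILITY_TOL, stoichiometric_matrix

__all__ = ["FluxSample", "DegeneratePolytopeError", "sample_fluxes", "median_fluxes"]


class DegeneratePolytopeError(RuntimeError):
    """The flux polytope has an (essentially) empty interior."""


@dataclass
class FluxSample:
    """A matrix of sampled steady-state flux vectors.

    ``samples`` is n_samples x n_reactions with reaction-id columns; the
    parameters that produced it ride along for provenance.
    """

    samples: pd.DataFrame
    seed: int
    thinning: int
    chains: int
    feasibility_tol: float = FEASIBILITY_TOL

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.samples.columns)

    def metadata(self) -> dict:
        return {
            "n": self.n, "seed": self.seed, "thinning": self.thinning,
            "chains": self.chains, "feasibility_tol": self.feasibility_tol,
        }


def _derive_seeds(seed: int, chains: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) + 1 for s in ss.generate_state(chains)]


def sample_fluxes(
    model: Model,
    n: int = 5000,
    seed: int = 0,
    thinning: int = 100,
    chains: int = 4,
) -> FluxSample:
    """Draw ``n`` steady-state flux vectors (deterministic given ``seed``).

    Rows violating the feasibility tolerance after thinning are rejected
    and re-drawn (never projected); a polytope with no free direction
    raises :class:`DegeneratePolytopeError`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    free_dims = sum(
        1 for r in model.reactions
        if r.upper_bound - r.lower_bound > FEASIBILITY_TOL
    )
    if free_dims == 0:
        raise DegeneratePolytopeError(
            "all reactions are equality-constrained; relax bounds before sampling"
        )
    per_chain = [n // chains + (1 if i < n % chains else 0) for i in range(chains)]
    seeds = _derive_seeds(seed, chains)
    frames: list[pd.DataFrame] = []
    for chain_n, chain_seed in zip(per_chain, seeds):
        if chain_n == 0:
            continue
        frames.append(_sample_one_chain(model, chain_n, chain_seed, thinning))
    samples = pd.concat(frames, ignore_index=True)
    return FluxSample(samples=samples, seed=seed, thinning=thinning, chains=chains)


def _sample_one_chain(model: Model, n: int, seed: int, thinning: int) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler = OptGPSampler(model, processes=1, thinning=thinning, seed=seed)
        frame = sampler.sample(n)
        keep = _feasible_rows(model, frame)
        attempts = 0
        while not keep.all() and attempts < 10:
            bad = int((~keep).sum())
            redraw = sampler.sample(bad)
            frame = pd.concat([frame[keep], redraw], ignore_index=True)
            keep = _feasible_rows(model, frame)
            attempts += 1
    if not keep.all():
        raise RuntimeError(
            f"{int((~keep).sum())} sampled rows remained infeasible after rejection"
        )
    return frame.reset_index(drop=True)


def _feasible_rows(model: Model, frame: pd.DataFrame, tol: float = FEASIBILITY_TOL) -> np.ndarray:
    S, _, rxns = stoichiometric_matrix(model)
    V = frame[rxns].to_numpy().T  # reactions x samples
    residual = np.abs(S @ V).max(axis=0)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    low = (lb[:, None] - V).max(axis=0)
    high = (V - ub[:, None]).max(axis=0)
    violation = np.maximum(np.maximum(low, high), 0.0)
    return (residual <= tol) & (violation <= tol)


def median_fluxes(sample: FluxSample) -> pd.Series:
    """Per-reaction sample median (even n: mean of the central pair)."""
    if sample.n < 1:
        raise ValueError("need at least one sample")
    return sample.samples.median(axis=0)
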