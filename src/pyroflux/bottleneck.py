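"""Median-constrained bottleneck scan.

For each reaction independently, cap its flux at the median observed in
flux sampling under physiological (calibrated) conditions, maximize the
product target, and flag reactions whose cap collapses the attainable
yield below a threshold.  A reaction whose typical operating level already
supports a near-maximal yield is unlikely to be a bottleneck; one whose
typical level pins the product near zero is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from .analysis import InfeasibleModelError, maximize

__all__ = ["BottleneckResult", "scan", "flag", "histogram"]

#: Default flag threshold in model units (mM per batch).
DEFAULT_THRESHOLD = 2.0


@dataclass
class BottleneckResult:
    target: str
    baseline: float  # unconstrained maximum of the target
    constrained_max: pd.Series  # indexed by reaction id
    medians: pd.Series  # the imposed medians, same index
    threshold: float = DEFAULT_THRESHOLD
    infeasible: dict[str, str] = field(default_factory=dict)

    @property
    def flagged(self) -> frozenset[str]:
        return flag(self, self.threshold)

    def to_frame(self) -> pd.DataFrame:
        flagged = self.flagged
        return pd.DataFrame({
            "reaction": self.constrained_max.index,
            "median": self.medians.reindex(self.constrained_max.index).to_numpy(),
            "constrained_max": self.constrained_max.to_numpy(),
            "flagged": [r in flagged for r in self.constrained_max.index],
        })


def _scan_set(model: Model, target: str) -> list[str]:
    """All non-exchange reactions, plus the target's own exchange."""
    boundary = {r.id for r in model.boundary}
    ids = [r.id for r in model.reactions if r.id not in boundary]
    if target in boundary:
        ids.append(target)
    return ids


def scan(
    model: Model,
    medians: pd.Series,
    target: str,
    threshold: float = DEFAULT_THRESHOLD,
    reactions: list[str] | None = None,
) -> BottleneckResult:
    """Per-reaction median-capped maximum of ``target``.

    The cap is sign-aware: a non-negative median becomes the reaction's
    upper bound (original lower bound kept); a negative median becomes the
    lower bound — either way activity is capped at its typical level on
    the side the median lies.  Bounds are restored between iterations and
    after the scan.  A cap that renders the model infeasible records a
    constrained maximum of 0 with a note instead of raising.
    """
    scan_ids = reactions if reactions is not None else _scan_set(model, target)
    missing = [r for r in scan_ids if r not in medians.index]
    if missing:
        raise KeyError(
            "medians missing for scanned reactions: " + ", ".join(missing[:10])
        )
    baseline, _ = maximize(model, target)
    values: dict[str, float] = {}
    infeasible: dict[str, str] = {}
    for rid in scan_ids:
        med = float(medians[rid])
        with model as m:
            rxn = m.reactions.get_by_id(rid)
            if med >= 0:
                if rxn.lower_bound > med:
                    rxn.lower_bound = med
                rxn.upper_bound = med
            else:
                if rxn.upper_bound < med:
                    rxn.upper_bound = med
                rxn.lower_bound = med
            try:
                opt, _ = maximize(m, target)
            except InfeasibleModelError as exc:
                infeasible[rid] = str(exc)
                opt = 0.0
        values[rid] = opt
    return BottleneckResult(
        target=target, baseline=baseline,
        constrained_max=pd.Series(values), medians=medians.copy(),
        threshold=threshold, infeasible=infeasible,
    )


def flag(result: BottleneckResult, threshold: float = DEFAULT_THRESHOLD) -> frozenset[str]:
    """Reactions whose capped maximum falls strictly below ``threshold``."""
    cm = result.constrained_max
    return frozenset(cm.index[cm < threshold])


def histogram(
    result: BottleneckResult, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of constrained maxima over [0, baseline].

    Bins are right-open with the last bin closed (numpy convention);
    returns ``(counts, bin_edges)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    top = max(result.baseline, bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, top)
    counts, edges = np.histogram(result.constrained_max.to_numpy(), bins=edges)
    return counts, edges
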