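"""Deviance partitioning of the full presence/absence model.

For each species, the variables selected independently within the five
predictor subsets (large/medium/small-scale PCNMs, environmental
variables, altitude) are merged into one full binomial GLM. Its
adjusted D² is the *total* explained deviance; the fraction *unshared*
with subset i is total minus the adjusted D² of the model refitted with
subset i's variables removed (leave-one-subset-out), and the *shared*
remainder is total − Σ unshared. Shared and unshared fractions can be
negative — a suppression signature, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .glm import SelectedModel, fit_binomial

__all__ = ["SUBSETS", "DeviancePartition", "partition", "partition_table"]

SUBSETS = ("large", "medium", "small", "environment", "altitude")


@dataclass
class DeviancePartition:
    """Adjusted-D² partition for one species, in percent."""

    species: str
    total: float
    shared: float
    unshared: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {"species": self.species, "total": self.total, "shared": self.shared}
        row.update({f"unshared_{k}": v for k, v in self.unshared.items()})
        return row


def _dedupe(columns: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for c in columns:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def partition(species: str, selections: dict[str, SelectedModel],
              y: np.ndarray, design_pool: pd.DataFrame, eps: float = 1e-10) -> DeviancePartition:
    """Leave-one-subset-out adjusted-D² partition (percent scale).

    ``selections`` maps subset name → its forward-selection result;
    ``design_pool`` must contain every selected column. The adjustment
    is recomputed per reduced fit with that fit's own coefficient
    count. Duplicate columns across subsets are dropped (with a
    warning) before fitting.
    """
    missing = [s for s in SUBSETS if s not in selections]
    if missing:
        raise ValueError(f"missing subset selections: {missing}")
    union: list[str] = []
    for name in SUBSETS:
        union.extend(selections[name].selected)
    deduped = _dedupe(union)
    if len(deduped) < len(union):
        warnings.warn(f"{species}: duplicated columns across subsets dropped", stacklevel=2)
    full = fit_binomial(y, design_pool[deduped] if deduped else None, eps=eps)
    total = full.adj_d2 * 100.0
    unshared: dict[str, float] = {}
    for name in SUBSETS:
        sel = selections[name].selected
        if not sel:
            unshared[name] = 0.0
            continue
        reduced_cols = [c for c in deduped if c not in set(sel)]
        reduced = fit_binomial(y, design_pool[reduced_cols] if reduced_cols else None, eps=eps)
        unshared[name] = total - reduced.adj_d2 * 100.0
    shared = total - sum(unshared.values())
    return DeviancePartition(species=species, total=total, shared=shared, unshared=unshared)


def partition_table(partitions: list[DeviancePartition]) -> pd.DataFrame:
    """Stack partitions into a species × fractions table (percent)."""
    return pd.DataFrame([p.as_row() for p in partitions]).set_index("species")
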