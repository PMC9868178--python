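"""Extraction of the 16 metabolic capacities from load characteristics.

A capacity is the signed extremum, over the 3-12 mM plasma-glucose grid, of
a (weighted) flux combination — e.g. gluconeogenesis is the most negative
net plasma-glucose exchange, reported with its negative (release) sign,
while glycolysis is the most positive — or, for the triacylglycerol storage
capacity, the largest steady-state tag pool in mM.  Ties between grid points
are broken toward the lowest glucose level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CapacityDef, ReferenceModelSpec
from .solver import LoadCharacteristic

__all__ = ["CapacityVector", "capacities", "capacity_table"]

N_CAPACITIES = 16


@dataclass(frozen=True)
class CapacityVector:
    sample_id: str
    values: Mapping[str, float]  # capacity name -> value
    units: Mapping[str, str]
    argmax_glucose: Mapping[str, float]  # grid point realising each extremum

    def __post_init__(self):
        if len(self.values) != N_CAPACITIES:
            raise ValueError(
                f"expected {N_CAPACITIES} capacities, got {len(self.values)}"
            )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sample_id)


def _series_for(defn: CapacityDef, load: LoadCharacteristic) -> np.ndarray:
    if defn.kind == "pool":
        return load.pool_series(defn.metabolite)
    out = np.zeros(len(load.glucose_grid))
    for rid, w in defn.terms.items():
        out = out + w * load.flux_series(rid)
    return out


def capacities(
    load: LoadCharacteristic,
    defs: Sequence[CapacityDef] | None = None,
    spec: ReferenceModelSpec | None = None,
    sample_id: str = "sample",
) -> CapacityVector:
    """Apply each capacity rule to a load characteristic.

    ``defs`` defaults to the capacity definitions of ``spec`` (one of the two
    must be given).  np.argmax/argmin return the first extremal index, which
    on an ascending grid implements the lowest-glucose tie-break.
    """
    if defs is None:
        if spec is None:
            raise ValueError("either defs or spec must be provided")
        defs = spec.capacity_defs
    grid = np.asarray(load.glucose_grid)
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    argmax: dict[str, float] = {}
    for d in defs:
        series = _series_for(d, load)
        i = int(np.argmax(series)) if d.rule == "max" else int(np.argmin(series))
        values[d.name] = float(series[i])
        units[d.name] = d.units
        argmax[d.name] = float(grid[i])
    return CapacityVector(
        sample_id=sample_id, values=values, units=units, argmax_glucose=argmax
    )


def capacity_table(vectors: Sequence[CapacityVector]) -> pd.DataFrame:
    """Stack per-sample capacity vectors into a samples x 16 table."""
    if not vectors:
        raise ValueError("no capacity vectors given")
    return pd.DataFrame([v.to_series() for v in vectors])
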