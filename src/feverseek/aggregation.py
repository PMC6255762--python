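"""Administrative-level descriptive rates of treated fever.

Observed treated-fever cases per 1,000 under-5 children by administrative
unit: the survey-estimated treated fraction among sampled fever cases in
each unit, expressed per 1,000, with national summaries weighting units by
their under-5 population (the population at risk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, assert_coregistered

__all__ = ["AdminAggregate", "admin_rates", "national_summary",
           "treated_percentage"]


def treated_percentage(treated: float, fever_total: float) -> float:
    """Observed percentage of fever episodes treated in the public sector."""
    if fever_total <= 0:
        raise ValueError("fever_total must be positive")
    if treated < 0 or treated > fever_total:
        raise ValueError("treated must lie in [0, fever_total]")
    return 100.0 * treated / fever_total


@dataclass
class AdminAggregate:
    unit: int
    treated: float
    fever_n: float
    pop_u5: float
    rate_per_1000: float  # NaN when no sampled fever cases

    def __post_init__(self) -> None:
        if self.treated > self.fever_n:
            raise ValueError("treated count cannot exceed fever count")


def admin_rates(
    children: pd.DataFrame,
    clusters: pd.DataFrame,
    admin_partition: Raster,
    population: Raster,
    weight_col: str | None = None,
) -> list[AdminAggregate]:
    """Treated-fever rate per 1,000 under-5 children per admin unit.

    Clusters are assigned to the admin unit of their published coordinates.
    Per unit, the (optionally design-weighted) treated fraction among sampled
    fever cases with observed responses is scaled to a per-1,000 rate; the
    unit's under-5 population is the sum of the population raster over its
    cells. Units with zero sampled fever cases are flagged missing (NaN
    rate). A cluster outside every admin unit raises ``ValueError``.
    """
    assert_coregistered(admin_partition, population)
    unit_of_cluster = {}
    for _, row in clusters.iterrows():
        try:
            u = admin_partition.value_at(row["x"], row["y"])
        except ValueError as exc:
            raise ValueError(
                f"cluster {row['cluster_id']} outside every admin unit: {exc}"
            ) from exc
        if np.isnan(u):
            raise ValueError(f"cluster {row['cluster_id']} outside every admin unit")
        unit_of_cluster[row["cluster_id"]] = int(u)

    units = np.unique(admin_partition.data[np.isfinite(admin_partition.data)])
    pop_per_unit = {
        int(u): float(population.data[admin_partition.data == u].sum())
        for u in units
    }

    w = (
        children[weight_col].to_numpy(dtype=float)
        if weight_col and weight_col in children.columns
        else np.ones(len(children))
    )
    y = children["y"].to_numpy(dtype=float)
    fever = children["fever"].to_numpy(dtype=float)
    cunit = children["cluster_id"].map(unit_of_cluster).to_numpy()

    out = []
    for u in sorted(pop_per_unit):
        sel = (cunit == u) & (fever == 1) & ~np.isnan(y)
        fever_n = float(w[sel].sum())
        treated = float((w[sel] * y[sel]).sum())
        rate = 1000.0 * treated / fever_n if fever_n > 0 else np.nan
        out.append(AdminAggregate(u, treated, fever_n, pop_per_unit[u], rate))
    return out


def national_summary(aggregates: list[AdminAggregate]) -> float:
    """Population-weighted national mean of the unit rates."""
    rates = np.array([a.rate_per_1000 for a in aggregates])
    pops = np.array([a.pop_u5 for a in aggregates])
    ok = ~np.isnan(rates)
    if not ok.any():
        raise ValueError("all admin units missing; no fever cases sampled")
    return float(np.sum(pops[ok] * rates[ok]) / np.sum(pops[ok]))


def aggregates_to_frame(aggregates: list[AdminAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [a.unit for a in aggregates],
            "fever_n": [a.fever_n for a in aggregates],
            "treated_n": [a.treated for a in aggregates],
            "pop_u5": [a.pop_u5 for a in aggregates],
            "rate_per_1000": [a.rate_per_1000 for a in aggregates],
        }
    )
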