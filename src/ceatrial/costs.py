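"""Per-patient discounted two-year total costs and arm-level cost tables.

Costs are assembled from three components (hospital, specialist services,
pharmaceuticals) observed over three 12-month periods: p0 (the year before
randomisation, descriptive only), p1 (the intervention year) and p2 (the
follow-up year).  The discounted two-year total per patient is

    total = (p1 components) + intervention payment          [year 1]
          + (p2 components) / (1 + r)                       [year 2]

with the A$1,000 per-participant payment added once, in year 1, in the
intervention arm only, scaled by a price-index factor (1.026 converts the
nominal payment to 2021/22 analysis-year prices, i.e. A$1,026).  Baseline
(p0) costs never enter the incremental totals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import COST_COMPONENTS
from .qaly import ELIGIBLE_COHORTS


def total_cost(
    year1_components: dict[str, float],
    year2_components: dict[str, float],
    arm: str,
    payment: float = 1000.0,
    rate: float = 0.05,
    index_factor: float = 1.0,
) -> float:
    """Discounted two-year total cost for one patient."""
    if payment < 0:
        raise ValueError("payment must be >= 0")
    for label, comps in (("year 1", year1_components), ("year 2", year2_components)):
        for name, v in comps.items():
            if v < 0:
                raise ValueError(f"negative {label} component {name!r}: {v}")
    year1 = sum(year1_components.values())
    year2 = sum(year2_components.values())
    pay = payment * index_factor if arm == "intervention" else 0.0
    return year1 + pay + year2 / (1.0 + rate)


def total_costs_for_dataset(
    dataset: pd.DataFrame,
    payment: float = 1000.0,
    rate: float = 0.05,
    index_factor: float = 1.0,
) -> pd.Series:
    """Vectorised :func:`total_cost` over the trial (indexed like ``dataset``)."""
    year1 = sum(dataset[f"cost_{c}_p1"] for c in COST_COMPONENTS)
    year2 = sum(dataset[f"cost_{c}_p2"] for c in COST_COMPONENTS)
    pay = np.where(dataset["arm"] == "intervention", payment * index_factor, 0.0)
    return year1 + pay + year2 / (1.0 + rate)


def _mean_se(x: pd.Series) -> tuple[float, float]:
    n = len(x)
    mean = float(x.mean())
    if n < 2:
        warnings.warn("single-patient cell: standard error undefined", stacklevel=2)
        return mean, float("nan")
    return mean, float(x.std(ddof=1) / np.sqrt(n))


def cost_table(
    dataset: pd.DataFrame,
    rate: float = 0.05,
    payment: float = 1000.0,
    index_factor: float = 1.0,
) -> pd.DataFrame:
    """Arm-level mean (SE) costs by component: baseline year and discounted
    two-year follow-up, for the adult + older-adult analysis set.

    Rows: hospital, specialist, pharma, intervention payment, total.
    Columns: <arm>_baseline_mean/se and <arm>_24m_mean/se per arm present.
    """
    data = dataset[dataset["cohort"].isin(ELIGIBLE_COHORTS)]
    if data.empty:
        raise ValueError("no adult/older-adult patients in dataset")

    rows: dict[str, dict[str, float]] = {}
    arms = [a for a in ("control", "intervention") if (data["arm"] == a).any()]
    for arm in arms:
        sub = data[data["arm"] == arm]
        pay = payment * index_factor if arm == "intervention" else 0.0
        total_base = 0.0 * sub[f"cost_{COST_COMPONENTS[0]}_p0"]
        total_fu = total_base + pay
        for comp in COST_COMPONENTS:
            base = sub[f"cost_{comp}_p0"]
            fu = sub[f"cost_{comp}_p1"] + sub[f"cost_{comp}_p2"] / (1.0 + rate)
            total_base = total_base + base
            total_fu = total_fu + fu
            m, se = _mean_se(base)
            rows.setdefault(comp, {})[f"{arm}_baseline_mean"] = m
            rows[comp][f"{arm}_baseline_se"] = se
            m, se = _mean_se(fu)
            rows[comp][f"{arm}_24m_mean"] = m
            rows[comp][f"{arm}_24m_se"] = se
        rows.setdefault("intervention_payment", {})[f"{arm}_baseline_mean"] = 0.0
        rows["intervention_payment"][f"{arm}_baseline_se"] = 0.0
        rows["intervention_payment"][f"{arm}_24m_mean"] = pay
        rows["intervention_payment"][f"{arm}_24m_se"] = 0.0
        m, se = _mean_se(total_base)
        rows.setdefault("total", {})[f"{arm}_baseline_mean"] = m
        rows["total"][f"{arm}_baseline_se"] = se
        m, se = _mean_se(total_fu)
        rows["total"][f"{arm}_24m_mean"] = m
        rows["total"][f"{arm}_24m_se"] = se

    table = pd.DataFrame(rows).T
    table.index.name = "component"
    if "intervention" not in arms:
        warnings.warn("no intervention arm present: intervention columns absent")
    return table
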