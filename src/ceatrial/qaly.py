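"""Discounted two-year QALYs by the trapezium method.

Utilities are observed at baseline and 12 months; no questionnaire is
collected at 24 months, so the 12-month utility is carried forward to 24
months for survivors (the base case assumes intervention gains are
sustained).  Sensitivity scenarios shrink the carried-forward utility in
the intervention arm by a decay fraction (5% or 15%).  Patients who die
between 12 and 24 months are assigned a 24-month utility of 0, and the
trapezium is still applied over months 12–24 (a linear decline to zero).

QALY = (u0 + u12)/2 · 1yr + [(u12 + u24)/2 · 1yr] / (1 + r),
with year 1 undiscounted and year 2 discounted one full year (r = 5%
annual by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .valuesets import ValueSet

#: cohorts entering the economic evaluation (the child cohort completes
#: proxy/youth questionnaire versions and is excluded)
ELIGIBLE_COHORTS = ("adult", "older")


class MissingUtilityError(ValueError):
    """A 12-month utility is missing and requires model-based handling."""


@dataclass
class QalyProfile:
    """Per-patient utility trajectory and discounted 2-year QALY."""

    patient_id: str
    u0: float
    u12: float | None
    u24: float | None
    dead_by_24: bool
    qaly: float | None
    discount_rate: float = 0.05
    decay: float = 0.0


def extrapolate_u24(u12: float, arm: str, dead_by_24: bool, decay: float = 0.0) -> float:
    """24-month utility under the carry-forward rule.

    Decedents score 0.  Surviving control patients keep u12 in every
    scenario; surviving intervention patients keep u12·(1 − decay).
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must lie in [0, 1], got {decay}")
    if dead_by_24:
        return 0.0
    if u12 is None or (isinstance(u12, float) and np.isnan(u12)):
        raise MissingUtilityError(
            "missing 12-month utility requires model-based handling; "
            "it cannot be extrapolated"
        )
    if arm == "intervention":
        return u12 * (1.0 - decay)
    return u12


def trapezium_qaly(u0: float, u12: float, u24: float, discount_rate: float = 0.05,
                   min_utility: float = -1.0) -> float:
    """Discounted 2-year QALY from three resolved utilities."""
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    for name, u in (("u0", u0), ("u12", u12), ("u24", u24)):
        if u > 1.0 + 1e-12 or u < min_utility - 1e-12:
            raise ValueError(f"{name} = {u} outside the value-set range [{min_utility}, 1]")
    year1 = (u0 + u12) / 2.0
    year2 = (u12 + u24) / 2.0 / (1.0 + discount_rate)
    return year1 + year2


def qalys_for_dataset(
    dataset: pd.DataFrame,
    value_set: ValueSet,
    decay: float = 0.0,
    discount_rate: float = 0.05,
    decay_both_arms: bool = False,
) -> pd.DataFrame:
    """Score states and compute one QALY profile per eligible patient.

    Child-cohort rows are excluded.  Rows whose 12-month state is missing
    get NaN u12/u24/qaly and are left for the mixed-model stage to handle
    under the missing-at-random assumption.

    Returns a DataFrame with columns patient_id, practice_id, arm, cohort,
    u0, u12, u24, dead_by_24, qaly.
    """
    eligible = dataset[dataset["cohort"].isin(ELIGIBLE_COHORTS)].copy()
    if eligible.empty:
        raise ValueError("no adult/older-adult patients: nothing to analyse")

    u0 = eligible["state_0"].map(value_set.utilities).astype(float)
    if u0.isna().any():
        bad = eligible.loc[u0.isna(), "state_0"].iloc[0]
        raise ValueError(f"unscoreable baseline state {bad!r}")
    observed = eligible["state_12"].notna()
    u12 = pd.Series(np.nan, index=eligible.index)
    u12[observed] = eligible.loc[observed, "state_12"].map(value_set.utilities).astype(float)

    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must lie in [0, 1], got {decay}")
    is_int = (eligible["arm"] == "intervention").to_numpy()
    control_shrink = 1.0 - decay if decay_both_arms else 1.0
    shrink = np.where(is_int, 1.0 - decay, control_shrink)
    u24 = u12.to_numpy() * shrink
    u24 = np.where(eligible["dead_by_24"].to_numpy(), 0.0, u24)

    year1 = (u0.to_numpy() + u12.to_numpy()) / 2.0
    year2 = (u12.to_numpy() + u24) / 2.0 / (1.0 + discount_rate)
    qaly = year1 + year2

    return pd.DataFrame(
        {
            "patient_id": eligible["patient_id"].to_numpy(),
            "practice_id": eligible["practice_id"].to_numpy(),
            "arm": eligible["arm"].to_numpy(),
            "cohort": eligible["cohort"].to_numpy(),
            "u0": u0.to_numpy(),
            "u12": u12.to_numpy(),
            "u24": u24,
            "dead_by_24": eligible["dead_by_24"].to_numpy(),
            "qaly": qaly,
        }
    )
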