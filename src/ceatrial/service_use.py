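"""Intervention effects on health-service-use counts.

Each outcome (ED presentations, admissions, hospital night stays,
specialist services, pharmaceutical items) is observed as a count per
patient in the baseline year and in follow-up.  The intervention effect is
the incidence rate ratio (IRR): the exponentiated group×time interaction of
a log-link negative binomial regression on the patient-period long format,
with terms for group, time and group×time, following the
intention-to-treat principle (all randomised patients retained).

Estimator.  The data-generating model has multiplicative (log-normal)
practice and patient intercepts; these scale every period of a patient
equally and are independent of randomised arm, so the marginal group×time
coefficient coincides with the conditional IRR.  The default estimator is
therefore a patient-level NB2 maximum-likelihood fit with cluster-robust
(practice) standard errors — the documented fallback for mixed-model
variance components, promoted to the default because it is stable and its
contract is parameter recovery rather than coefficient identity with any
particular mixed-model implementation.

Follow-up windows: ``"1yr"`` compares baseline with the intervention year
(p1); ``"2yr"`` compares baseline with the pooled months 0–24 (p1 + p2).
Periods enter without an exposure offset: the common time main effect
absorbs the longer pooled window, leaving the interaction ratio unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .config import OUTCOMES

WINDOWS = ("1yr", "2yr")

OUTCOME_LABELS = {
    "ed": "ED presentations",
    "adm": "Hospital admissions",
    "nights": "Hospital night stays",
    "spec": "Specialist services",
    "pharm": "Pharmaceuticals",
}


@dataclass
class CountModelSpec:
    """Which outcome/window/cohort to model."""

    outcome: str
    window: str = "2yr"
    cohort_filter: str | None = None  # None = all cohorts

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")
        if self.window not in WINDOWS:
            raise ValueError(f"window must be one of {WINDOWS}")


@dataclass
class IrrEstimate:
    """Incidence rate ratio with 95% CI and two-sided p-value."""

    irr: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.irr <= 0:
            raise ValueError("IRR must be positive")


class DegenerateCountsError(ValueError):
    """All counts are zero in a stratum; the interaction is not estimable."""


def to_long(dataset: pd.DataFrame, spec: CountModelSpec) -> pd.DataFrame:
    """Patient-period long format for one outcome: columns patient_id,
    practice_id, treat, post, count."""
    data = dataset
    if spec.cohort_filter is not None:
        data = data[data["cohort"] == spec.cohort_filter]
        if data.empty:
            raise ValueError(f"no patients in cohort {spec.cohort_filter!r}")
    base = data[f"count_{spec.outcome}_p0"].to_numpy()
    if spec.window == "1yr":
        follow = data[f"count_{spec.outcome}_p1"].to_numpy()
    else:
        follow = (
            data[f"count_{spec.outcome}_p1"] + data[f"count_{spec.outcome}_p2"]
        ).to_numpy()
    treat = (data["arm"] == "intervention").astype(int).to_numpy()
    long = pd.DataFrame(
        {
            "patient_id": np.tile(data["patient_id"].to_numpy(), 2),
            "practice_id": np.tile(data["practice_id"].to_numpy(), 2),
            "treat": np.tile(treat, 2),
            "post": np.repeat([0, 1], len(data)),
            "count": np.concatenate([base, follow]),
        }
    )
    return long


def fit_count_model(dataset: pd.DataFrame, spec: CountModelSpec) -> IrrEstimate:
    """IRR for one outcome/window: exponentiated group×time interaction."""
    long = to_long(dataset, spec)
    cell_sums = long.groupby(["treat", "post"])["count"].sum()
    if (cell_sums == 0).any():
        stratum = cell_sums.index[cell_sums == 0][0]
        raise DegenerateCountsError(
            f"all {spec.outcome!r} counts are zero in stratum (treat, post) = "
            f"{stratum}; the rate ratio is not estimable — pool periods or "
            "choose a coarser outcome"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.negativebinomial("count ~ treat + post + treat:post", long)
        fit = model.fit(
            disp=False, maxiter=200,
            cov_type="cluster", cov_kwds={"groups": long["practice_id"]},
        )
    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged:
        warnings.warn(
            f"NB fit for {spec.outcome!r} ({spec.window}) did not converge; "
            "estimates reported from the last iterate",
            stacklevel=2,
        )
    term = "treat:post"
    ci = fit.conf_int().loc[term]
    return IrrEstimate(
        irr=float(np.exp(fit.params[term])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(fit.pvalues[term]),
        converged=converged,
    )


def fitted_dispersion(dataset: pd.DataFrame, spec: CountModelSpec) -> float:
    """NB2 dispersion alpha from the same model (for calibration checks)."""
    long = to_long(dataset, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.negativebinomial("count ~ treat + post + treat:post", long).fit(
            disp=False, maxiter=200
        )
    return float(fit.params["alpha"])


def service_use_table(
    dataset: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    windows: tuple[str, ...] = ("1yr", "2yr"),
    cohort_filter: str | None = None,
) -> pd.DataFrame:
    """Descriptives and IRRs per outcome, in the trial-report row layout.

    Per outcome and period: total count and mean (SD) per patient; per
    follow-up window: IRR (95% CI) and p-value.  In a single-arm dataset
    the IRR columns are flagged unavailable (NaN).
    """
    data = dataset
    if cohort_filter is not None:
        data = data[data["cohort"] == cohort_filter]
        if data.empty:
            raise ValueError(f"no patients in cohort {cohort_filter!r}")
    single_arm = data["arm"].nunique() < 2
    rows = []
    for outcome in outcomes:
        row: dict[str, object] = {
            "outcome": OUTCOME_LABELS.get(outcome, outcome),
            "n_patients": len(data),
        }
        for arm in ("control", "intervention"):
            sub = data[data["arm"] == arm]
            for period, label in (("p0", "baseline"), ("p1", "12m"), ("p2", "24m")):
                col = f"count_{outcome}_{period}"
                if sub.empty:
                    row[f"{arm}_{label}_total"] = np.nan
                    row[f"{arm}_{label}_mean"] = np.nan
                    row[f"{arm}_{label}_sd"] = np.nan
                else:
                    row[f"{arm}_{label}_total"] = int(sub[col].sum())
                    row[f"{arm}_{label}_mean"] = float(sub[col].mean())
                    row[f"{arm}_{label}_sd"] = float(sub[col].std(ddof=1))
        for window in windows:
            if single_arm:
                warnings.warn("single-arm dataset: IRR unavailable", stacklevel=2)
                est = None
            else:
                est = fit_count_model(
                    data, CountModelSpec(outcome, window=window)
                )
            row[f"irr_{window}"] = est.irr if est else np.nan
            row[f"irr_{window}_ci_low"] = est.ci_low if est else np.nan
            row[f"irr_{window}_ci_high"] = est.ci_high if est else np.nan
            row[f"irr_{window}_p"] = est.p_value if est else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")
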