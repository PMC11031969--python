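"""Incremental cost-effectiveness analysis with non-parametric bootstrap.

The point estimate of the incremental QALY gain (ΔE) comes from a linear
mixed model of per-patient discounted QALYs on treatment arm with the
baseline utility as a covariate and a practice random intercept; the
incremental cost (ΔC) is the difference in arm means of discounted
two-year total costs.  Uncertainty is characterised by resampling
participants with replacement within arm, recomputing (ΔC_b, ΔE_b) on each
resample with costs and QALYs taken jointly per participant so their
covariance is preserved.  Replicate clouds feed the cost-effectiveness
plane (quadrant proportions) and the cost-effectiveness acceptability
curve: CEAC(λ) = proportion of replicates with positive net monetary
benefit λ·ΔE_b − ΔC_b.

Within bootstrap replicates ΔE uses the same covariate-adjusted mean
difference but with the practice random effect dropped (resampling
participants breaks cluster membership); this is an approximation relative
to re-fitting the full mixed model per replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .costs import total_costs_for_dataset
from .qaly import qalys_for_dataset
from .valuesets import ValueSet

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class CeaResult:
    """Point estimates plus the bootstrap replicate cloud for one scenario."""

    delta_cost: float
    delta_qaly: float
    icer: float | str
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    ci_qaly_model: tuple[float, float]  # 95% CI from the mixed model itself
    replicates: np.ndarray  # shape (B, 2): columns ΔC_b, ΔE_b
    B: int
    seed: int
    wtp_threshold: float = 50_000.0
    n_patients: int = 0

    @property
    def cost_effective_at_threshold(self) -> bool:
        """Positive expected net monetary benefit at the WTP threshold."""
        return self.wtp_threshold * self.delta_qaly - self.delta_cost > 0


@dataclass
class CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if not np.isclose(self.wtp_grid[idx], wtp):
            raise KeyError(f"threshold {wtp} not on the grid")
        return float(self.probability[idx])


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ΔC/ΔE when both differences share sign; dominance labels otherwise.

    An intervention that is cheaper and more effective is *dominant*;
    costlier and less effective is *dominated*.  ΔE = 0 leaves the ratio
    undefined.  Ties on ΔC = 0 resolve to the dominance label.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("ICER inputs must be finite")
    if delta_qaly == 0:
        return UNDEFINED
    if delta_qaly > 0 and delta_cost <= 0:
        return DOMINANT
    if delta_qaly < 0 and delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_qaly


def adjusted_qaly_gain(profiles: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Baseline-adjusted incremental QALYs from a practice-level mixed model.

    Fits  qaly ~ arm + u0  with a practice random intercept (REML) on
    complete cases; rows whose QALY is unresolved (missing 12-month state)
    are dropped, which is valid under missing-at-random given u0.  When the
    practice variance component collapses or the fit fails, falls back to
    the fixed-effects (OLS) estimate with an explicit warning.
    """
    data = profiles.dropna(subset=["qaly"]).copy()
    if data.empty:
        raise ValueError("no complete-case QALY profiles")
    data["treat"] = (data["arm"] == "intervention").astype(float)
    n_arms = data.groupby("arm")["practice_id"].nunique()
    if (n_arms < 2).any() or len(n_arms) < 2:
        raise ValueError("need at least 2 practices in each arm")

    formula = "qaly ~ treat + u0"
    if np.ptp(data["u0"].to_numpy()) == 0.0:
        # constant baseline covariate: drop it rather than fit a collinear term
        formula = "qaly ~ treat"

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["practice_id"])
            fit = model.fit(reml=True)
        singular = (not fit.converged) or float(fit.cov_re.iloc[0, 0]) < 1e-10
    except Exception:  # pragma: no cover - defensive: numerics can fail outright
        fit, singular = None, True

    if singular:
        warnings.warn(
            "practice variance component collapsed or mixed model failed to "
            "converge; falling back to a fixed-effects (OLS) fit",
            stacklevel=2,
        )
        ols = smf.ols(formula, data).fit()
        ci = ols.conf_int().loc["treat"]
        return float(ols.params["treat"]), (float(ci[0]), float(ci[1]))

    ci = fit.conf_int().loc["treat"]
    return float(fit.params["treat"]), (float(ci[0]), float(ci[1]))


def _ols_arm_effect(treat: np.ndarray, u0: np.ndarray, y: np.ndarray) -> float:
    """Arm coefficient of y ~ 1 + treat + u0 by least squares (no clustering).

    Degenerate resamples (constant baseline covariate, or too few points to
    identify three coefficients) reduce to the unadjusted mean difference.
    """
    if len(y) < 4 or np.ptp(u0) == 0.0 or np.ptp(treat) == 0.0:
        return float(y[treat == 1].mean() - y[treat == 0].mean())
    X = np.column_stack([np.ones_like(y), treat, u0])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def build_analysis_table(
    dataset: pd.DataFrame,
    value_set: ValueSet,
    decay: float = 0.0,
    discount_rate: float = 0.05,
    payment: float = 1000.0,
    index_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-patient analysis rows: arm, practice, cohort, u0, qaly, total_cost."""
    profiles = qalys_for_dataset(dataset, value_set, decay=decay, discount_rate=discount_rate)
    costs = total_costs_for_dataset(
        dataset, payment=payment, rate=discount_rate, index_factor=index_factor
    )
    cost_by_id = pd.Series(costs.to_numpy(), index=dataset["patient_id"].to_numpy())
    profiles["total_cost"] = profiles["patient_id"].map(cost_by_id).astype(float)
    return profiles


def _resample_indices(
    table: pd.DataFrame, B: int, seed: int, cluster: bool = False
) -> list[np.ndarray]:
    """B per-replicate row-index arrays, resampled within arm.

    With ``cluster=True`` whole practices are resampled within arm instead
    of participants.
    """
    rng = np.random.default_rng(seed)
    arms = [np.flatnonzero((table["arm"] == a).to_numpy()) for a in ("control", "intervention")]
    if any(len(a) == 0 for a in arms):
        raise ValueError("both arms must be non-empty")
    out = []
    if cluster:
        prac = table["practice_id"].to_numpy()
        groups = [
            [np.flatnonzero(prac == p) for p in np.unique(prac[a])] for a in arms
        ]
    complete = table["qaly"].notna().to_numpy()
    for _ in range(B):
        for _attempt in range(100):
            if cluster:
                idx = np.concatenate(
                    [
                        np.concatenate([g[k] for k in rng.integers(len(g), size=len(g))])
                        for g in groups
                    ]
                )
            else:
                idx = np.concatenate([rng.choice(a, size=len(a), replace=True) for a in arms])
            cc = complete[idx]
            treat = (table["arm"].to_numpy()[idx] == "intervention") & cc
            ctrl = (table["arm"].to_numpy()[idx] == "control") & cc
            if treat.sum() >= 1 and ctrl.sum() >= 1:
                break
            logger.info("degenerate bootstrap resample redrawn")
        out.append(idx)
    return out


def bootstrap_cea(
    table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    cluster: bool = False,
    indices: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Bootstrap replicate pairs (ΔC_b, ΔE_b), deterministic given seed.

    ΔC_b is the arm difference in mean total cost over the full resample;
    ΔE_b is the u0-adjusted arm difference in QALYs over the complete cases
    of the same resample (costs and QALYs move jointly per participant).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if indices is None:
        indices = _resample_indices(table, B, seed, cluster=cluster)
    arm = (table["arm"] == "intervention").to_numpy().astype(float)
    cost = table["total_cost"].to_numpy(dtype=float)
    qaly = table["qaly"].to_numpy(dtype=float)
    u0 = table["u0"].to_numpy(dtype=float)
    complete = ~np.isnan(qaly)

    reps = np.empty((len(indices), 2))
    for b, idx in enumerate(indices):
        a = arm[idx]
        dc = cost[idx][a == 1].mean() - cost[idx][a == 0].mean()
        cc = complete[idx]
        de = _ols_arm_effect(a[cc], u0[idx][cc], qaly[idx][cc])
        reps[b] = (dc, de)
    return reps


def cep_summary(replicates: np.ndarray) -> dict[str, float]:
    """Cost-effectiveness-plane quadrant proportions (sum to exactly 1).

    x-axis ΔE, y-axis ΔC.  NE = more effective & more costly.  Ties are
    deterministic: ΔE = 0 counts as the more-effective (east) side and
    ΔC = 0 as the cheaper (south) side, i.e. ties favour cost-effectiveness.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 1 or reps.shape[1] != 2:
        raise ValueError("need at least one (ΔC, ΔE) replicate")
    dc, de = reps[:, 0], reps[:, 1]
    east, north = de >= 0, dc > 0
    n = len(reps)
    ne = float((east & north).sum() / n)
    nw = float((~east & north).sum() / n)
    se = float((east & ~north).sum() / n)
    # remainder form keeps the four proportions summing to exactly 1.0
    sw = 1.0 - (ne + nw + se)
    return {"NE": ne, "NW": nw, "SE": se, "SW": sw}


def ceac(replicates: np.ndarray, wtp_grid: np.ndarray) -> CeacCurve:
    """CEAC(λ) = share of replicates with λ·ΔE_b − ΔC_b strictly positive."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("willingness-to-pay grid must be strictly ascending")
    reps = np.asarray(replicates, dtype=float)
    nmb = grid[:, None] * reps[None, :, 1] - reps[None, :, 0]
    return CeacCurve(wtp_grid=grid, probability=(nmb > 0).mean(axis=1))


def default_wtp_grid(stop: float = 100_000.0, step: float = 1_000.0) -> np.ndarray:
    """0..stop in `step` increments; always contains the A$50,000 threshold."""
    grid = np.arange(0.0, stop + step / 2, step)
    if not np.isclose(grid, 50_000.0).any() and stop >= 50_000.0:
        grid = np.sort(np.append(grid, 50_000.0))
    return grid


def analyse(
    table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    wtp_threshold: float = 50_000.0,
    cluster: bool = False,
    indices: list[np.ndarray] | None = None,
) -> CeaResult:
    """Point estimates + bootstrap for one analysis table."""
    by_arm = table.groupby("arm")["total_cost"].mean()
    delta_cost = float(by_arm.get("intervention", np.nan) - by_arm.get("control", np.nan))
    delta_qaly, ci_model = adjusted_qaly_gain(table)
    reps = bootstrap_cea(table, B=B, seed=seed, cluster=cluster, indices=indices)
    lo_c, hi_c = np.percentile(reps[:, 0], [2.5, 97.5])
    lo_e, hi_e = np.percentile(reps[:, 1], [2.5, 97.5])
    return CeaResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer(delta_cost, delta_qaly),
        ci_cost=(float(lo_c), float(hi_c)),
        ci_qaly=(float(lo_e), float(hi_e)),
        ci_qaly_model=ci_model,
        replicates=reps,
        B=len(reps),
        seed=seed,
        wtp_threshold=wtp_threshold,
        n_patients=len(table),
    )


def run_scenarios(
    dataset: pd.DataFrame,
    value_set: ValueSet,
    decays: tuple[float, ...] = (0.0, 0.05, 0.15),
    discount_rate: float = 0.05,
    payment: float = 1000.0,
    index_factor: float = 1.0,
    B: int = 1000,
    seed: int = 0,
    wtp_threshold: float = 50_000.0,
    wtp_grid: np.ndarray | None = None,
    cluster: bool = False,
) -> dict[float, tuple[CeaResult, CeacCurve]]:
    """Base case plus effectiveness-decay sensitivity scenarios.

    Costs are identical across scenarios by construction (the decay touches
    only the extrapolated 24-month utility in the intervention arm); the
    same bootstrap resamples are reused for every scenario, so the ΔC_b
    column of each replicate cloud is bitwise identical.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    results: dict[float, tuple[CeaResult, CeacCurve]] = {}
    indices = None
    ref_cost_col = None
    for decay in decays:
        table = build_analysis_table(
            dataset, value_set, decay=decay, discount_rate=discount_rate,
            payment=payment, index_factor=index_factor,
        )
        if indices is None:
            indices = _resample_indices(table, B, seed, cluster=cluster)
        res = analyse(
            table, B=B, seed=seed, wtp_threshold=wtp_threshold,
            cluster=cluster, indices=indices,
        )
        if ref_cost_col is None:
            ref_cost_col = res.replicates[:, 0]
        elif not np.array_equal(ref_cost_col, res.replicates[:, 0]):
            raise AssertionError("cost replicates changed across decay scenarios")
        results[decay] = (res, ceac(res.replicates, wtp_grid))
    return results
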