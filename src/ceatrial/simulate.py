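"""Synthetic clustered two-arm trial generator.

Emulates the data structure of a cluster-randomised primary-care trial:
practices randomised 1:1, three patient cohorts, EQ-5D-5L health states
observed at baseline and 12 months, deaths by 24 months concentrated in the
older cohort, right-skewed component costs coupled to service use, and
overdispersed service-use counts over three 12-month periods (p0 baseline,
p1 intervention year, p2 follow-up year).

Generative model, per patient i in practice j, cohort c:

* latent health  h_i ~ N(0, sd_h);  practice utility intercept a_j.
* latent utility at time t: u*_t = mu_c + a_j + h_i + eps_t, plus the
  additive intervention effect delta at 12 months in the intervention arm;
  u* is truncated to the value set's range and snapped to the nearest
  representable EQ-5D-5L state, so downstream code always scores states.
* counts (NB2, log link):  log rate = log(r_ck) + b_j + g_i + tau_p
  + 1[arm=intervention, p>0] * log(IRR_k), with g_i negatively coupled to
  h_i so sicker patients use more services.
* component costs = unit prices x counts + gamma noise (hospital cost is
  dominated by night stays), so count effects propagate into costs.
* deaths: Bernoulli per cohort, placed in period 2 (between 12 and 24
  months) only; 12-month states exist for all survivors of year 1.
* 12-month states are set missing at random via a logistic rule on the
  observed baseline utility (a separate random stream, so the mask can be
  reproduced from u0 and the seed alone).

Identical (config, seed) pairs yield byte-identical datasets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import COHORTS, COST_COMPONENTS, OUTCOMES, GeneratorConfig
from .valuesets import ValueSet, load_value_set

PERIODS = ("p0", "p1", "p2")

DATASET_COLUMNS = (
    ["patient_id", "practice_id", "arm", "cohort", "state_0", "state_12", "dead_by_24"]
    + [f"cost_{c}_{p}" for c in COST_COMPONENTS for p in PERIODS]
    + [f"count_{o}_{p}" for o in OUTCOMES for p in PERIODS]
)


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    main, miss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(main), np.random.default_rng(miss)


def snap_to_state(latent: np.ndarray, value_set: ValueSet) -> tuple[np.ndarray, np.ndarray]:
    """Truncate latent utilities to the value-set range and snap each to the
    nearest representable state.  Returns (codes, snapped utilities)."""
    codes, utils = value_set.as_arrays()
    clipped = np.clip(latent, utils[0], utils[-1])
    idx = np.searchsorted(utils, clipped)
    idx = np.clip(idx, 1, len(utils) - 1)
    left_closer = (clipped - utils[idx - 1]) <= (utils[idx] - clipped)
    idx = np.where(left_closer, idx - 1, idx)
    return codes[idx], utils[idx]


def missingness_mask(u0: np.ndarray, coefs: tuple[float, float], seed: int) -> np.ndarray:
    """MAR mask for the 12-month state: True where the state is missing.

    Depends only on the observed baseline utility and the seed — the same
    stream the generator uses — so the mask is reproducible by construction.
    """
    _, rng_miss = _spawn_rngs(seed)
    a, b = coefs
    p_miss = expit(a + b * np.asarray(u0, dtype=float))
    return rng_miss.uniform(size=len(u0)) < p_miss


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draw via gamma–Poisson mixture: Var = mu + alpha * mu^2."""
    shape = 1.0 / alpha
    lam = mean * rng.gamma(shape, alpha, size=mean.shape)
    return rng.poisson(lam)


def generate_trial(
    config: GeneratorConfig, value_set: ValueSet | None = None
) -> pd.DataFrame:
    """Simulate one trial dataset (one row per patient)."""
    config.validate()
    if value_set is None:
        value_set = load_value_set(config.value_set)
    rng, _ = _spawn_rngs(config.seed)

    n_practices = config.n_practices
    n_int = int(round(n_practices * config.allocation_ratio))
    if not 0 < n_int < n_practices:
        raise ValueError("allocation ratio leaves an empty arm")
    practice_arm = np.array(["control"] * (n_practices - n_int) + ["intervention"] * n_int)
    rng.shuffle(practice_arm)

    # practice-level intercepts
    prac_u = rng.normal(0.0, config.practice_sd_utility, size=n_practices)
    prac_c = rng.normal(0.0, config.practice_sd_lograte, size=n_practices)

    cohorts, practice_idx = [], []
    for cohort in COHORTS:
        n = int(config.cohort_sizes.get(cohort, 0))
        cohorts += [cohort] * n
        # deal each cohort across practices round-robin from a random start
        start = rng.integers(n_practices)
        practice_idx += [(start + k) % n_practices for k in range(n)]
    cohorts = np.array(cohorts)
    practice_idx = np.array(practice_idx, dtype=int)
    n_pat = len(cohorts)
    if n_pat == 0:
        raise ValueError("empty trial: all cohort sizes are zero")

    arm = practice_arm[practice_idx]
    is_int = arm == "intervention"

    # latent utilities -> states
    mu = np.array([config.utility_means[c] for c in cohorts])
    h = rng.normal(0.0, config.utility_patient_sd, size=n_pat)
    eps0 = rng.normal(0.0, config.utility_noise_sd, size=n_pat)
    eps12 = rng.normal(0.0, config.utility_noise_sd, size=n_pat)
    base = mu + prac_u[practice_idx] + h
    lat0 = base + eps0
    lat12 = base + eps12 + config.true_effect_utility * is_int
    state0, u0 = snap_to_state(lat0, value_set)
    state12, _ = snap_to_state(lat12, value_set)

    # patient count intercept, negatively coupled to latent health
    rho = config.health_count_coupling
    z = rng.normal(size=n_pat)
    if config.utility_patient_sd > 0:
        h_std = h / config.utility_patient_sd
    else:
        h_std = np.zeros(n_pat)
    g = config.patient_sd_lograte * (-rho * h_std + np.sqrt(1.0 - rho**2) * z)

    # centre the log-normal random effects so E[exp(b_j + g_i)] = 1 and the
    # marginal mean count equals the configured rate
    centring = -0.5 * (config.practice_sd_lograte**2 + config.patient_sd_lograte**2)

    counts: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        rate0 = np.array([config.baseline_rates[c][outcome] for c in cohorts])
        log_irr = np.log(config.true_irr[outcome])
        alpha = config.count_dispersion[outcome]
        for period in PERIODS:
            tau = 0.0 if period == "p0" else config.time_effects[period]
            effect = 0.0 if period == "p0" else log_irr * is_int
            mean = rate0 * np.exp(prac_c[practice_idx] + g + tau + effect + centring)
            counts[f"count_{outcome}_{period}"] = _nb_counts(rng, mean, alpha)

    prices = config.unit_prices
    costs: dict[str, np.ndarray] = {}  # rounded to cents so CSV round-trips exactly
    for period in PERIODS:
        noise = {
            comp: rng.gamma(config.cost_noise[comp]["shape"], config.cost_noise[comp]["scale"], n_pat)
            for comp in COST_COMPONENTS
        }
        costs[f"cost_hospital_{period}"] = np.round(
            prices["night"] * counts[f"count_nights_{period}"]
            + prices["admission"] * counts[f"count_adm_{period}"]
            + prices["ed"] * counts[f"count_ed_{period}"]
            + noise["hospital"],
            2,
        )
        costs[f"cost_specialist_{period}"] = np.round(
            prices["specialist"] * counts[f"count_spec_{period}"] + noise["specialist"], 2
        )
        costs[f"cost_pharma_{period}"] = np.round(
            prices["pharm"] * counts[f"count_pharm_{period}"] + noise["pharma"], 2
        )

    p_death = np.array([config.death_prob[c] for c in cohorts])
    dead = rng.uniform(size=n_pat) < p_death  # death falls in period 2 only

    state12 = state12.astype(object)
    miss = missingness_mask(u0, config.missing_prob_coefs, config.seed)
    state12[miss] = pd.NA

    df = pd.DataFrame(
        {
            "patient_id": [f"P{k:04d}" for k in range(1, n_pat + 1)],
            "practice_id": [f"PR{j + 1:02d}" for j in practice_idx],
            "arm": arm,
            "cohort": cohorts,
            "state_0": state0,
            "state_12": state12,
            "dead_by_24": dead,
        }
    )
    for col in DATASET_COLUMNS[7:]:
        df[col] = counts[col] if col.startswith("count_") else costs[col]
    return df


class DatasetValidationError(ValueError):
    """A dataset row violates the trial-data contract; names the row and field."""


def _check_state(code, row_id: str, col: str, allow_missing: bool) -> None:
    if code is None or (isinstance(code, float) and np.isnan(code)) or code is pd.NA:
        if allow_missing:
            return
        raise DatasetValidationError(f"row {row_id}: {col} is missing")
    s = str(code).strip()
    if len(s) != 5 or not s.isdigit() or any(ch not in "12345" for ch in s):
        raise DatasetValidationError(
            f"row {row_id}: {col} = {code!r} is not a valid EQ-5D-5L code "
            "(five digits, each level in 1..5)"
        )


def validate_dataset(df: pd.DataFrame) -> None:
    """Raise :class:`DatasetValidationError` on the first contract violation."""
    missing_cols = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetValidationError(f"missing columns: {missing_cols}")
    by_practice = df.groupby("practice_id")["arm"].nunique()
    mixed = by_practice[by_practice > 1]
    if len(mixed):
        raise DatasetValidationError(
            f"practice {mixed.index[0]!r} appears in more than one arm"
        )
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DatasetValidationError(f"duplicate patient_id {dup!r}")
    for row in df.itertuples(index=False):
        rid = row.patient_id
        if row.arm not in ("control", "intervention"):
            raise DatasetValidationError(f"row {rid}: arm = {row.arm!r}")
        _check_state(row.state_0, rid, "state_0", allow_missing=False)
        _check_state(row.state_12, rid, "state_12", allow_missing=True)
        for col in DATASET_COLUMNS[7:]:
            val = getattr(row, col)
            if pd.isna(val):
                raise DatasetValidationError(f"row {rid}: {col} is missing")
            if val < 0:
                raise DatasetValidationError(f"row {rid}: {col} = {val} is negative")
            if col.startswith("count_") and float(val) != int(val):
                raise DatasetValidationError(f"row {rid}: {col} = {val} is not an integer")


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial dataset to CSV (missing 12-month states as empty cells)."""
    validate_dataset(df)
    out = df.copy()
    out["dead_by_24"] = out["dead_by_24"].astype(int)
    out.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial dataset; round-trips :func:`write_dataset`."""
    df = pd.read_csv(
        path,
        dtype={"state_0": "string", "state_12": "string", "patient_id": "string",
               "practice_id": "string"},
        keep_default_na=True,
    )
    for col in ("patient_id", "practice_id", "arm", "cohort", "state_0"):
        df[col] = df[col].astype(object)
    state12 = df["state_12"].astype(object)
    df["state_12"] = np.where(pd.isna(state12), pd.NA, state12)
    df["dead_by_24"] = df["dead_by_24"].astype(bool)
    for col in DATASET_COLUMNS[7:]:
        if col.startswith("count_"):
            if (pd.to_numeric(df[col], errors="coerce") % 1 != 0).any():
                bad = df.loc[pd.to_numeric(df[col]) % 1 != 0].iloc[0]
                raise DatasetValidationError(
                    f"row {bad['patient_id']}: {col} is not an integer"
                )
            df[col] = df[col].astype(np.int64)
        else:
            df[col] = df[col].astype(float)
    validate_dataset(df)
    return df[list(DATASET_COLUMNS)]
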