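"""End-to-end pipeline: simulate (or load) → score → cost → CEA → counts.

A run is a pure function of its configuration and seed: the same
``RunConfig`` always produces byte-identical CSV artifacts.  Every run
writes a manifest recording the config, the seed and a SHA-256 checksum of
each artifact, sufficient to verify an exact reproduction.  The log file
records record counts in and out of each stage so filter effects (child
exclusion, missing 12-month states) are auditable; it carries timestamps
and is therefore excluded from the checksum list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import CeaResult, ceac, default_wtp_grid, run_scenarios
from .config import RunConfig
from .costs import cost_table
from .qaly import ELIGIBLE_COHORTS, qalys_for_dataset
from .service_use import service_use_table
from .simulate import generate_trial, read_dataset, write_dataset
from .valuesets import load_value_set

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summary_row(subgroup: str, decay: float, res: CeaResult, curve) -> dict:
    return {
        "subgroup": subgroup,
        "decay": decay,
        "n_patients": res.n_patients,
        "delta_cost": res.delta_cost,
        "delta_qaly": res.delta_qaly,
        "icer": res.icer,
        "ci_cost_low": res.ci_cost[0],
        "ci_cost_high": res.ci_cost[1],
        "ci_qaly_low": res.ci_qaly[0],
        "ci_qaly_high": res.ci_qaly[1],
        "ceac_at_threshold": curve.at(res.wtp_threshold),
        "cost_effective_at_threshold": res.cost_effective_at_threshold,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns a manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: list[Path] = []

    def fail(stage: str, exc: Exception) -> PipelineError:
        logger.error("stage %s failed: %s", stage, exc)
        return PipelineError(f"stage {stage!r} failed: {exc}")

    try:
        # --- stage: dataset ---
        try:
            if config.dataset_path:
                dataset = read_dataset(config.dataset_path)
                logger.info("loaded dataset %s: %d patients", config.dataset_path, len(dataset))
            else:
                gen = config.generator
                gen.seed = config.seed
                dataset = generate_trial(gen)
                path = out / "dataset.csv"
                write_dataset(dataset, path)
                artifacts.append(path)
                logger.info("simulated dataset: %d patients, %d practices",
                            len(dataset), dataset["practice_id"].nunique())
        except Exception as exc:
            raise fail("dataset", exc)

        # --- stage: scoring / QALYs ---
        try:
            value_set = load_value_set(config.value_set)
            profiles = qalys_for_dataset(
                dataset, value_set, decay=0.0, discount_rate=config.discount_rate
            )
            path = out / "qaly_profiles.csv"
            profiles.to_csv(path, index=False)
            artifacts.append(path)
            logger.info(
                "QALY profiles: %d eligible of %d patients (%d with missing 12m state)",
                len(profiles), len(dataset), int(profiles["qaly"].isna().sum()),
            )
        except Exception as exc:
            raise fail("qaly", exc)

        # --- stage: costs ---
        try:
            ct = cost_table(
                dataset, rate=config.discount_rate,
                payment=config.payment, index_factor=config.index_factor,
            )
            path = out / "cost_table.csv"
            ct.to_csv(path)
            artifacts.append(path)
            logger.info("cost table written (%d components)", len(ct))
        except Exception as exc:
            raise fail("costs", exc)

        # --- stage: CEA per subgroup and scenario ---
        grid = default_wtp_grid(config.wtp_grid[1], config.wtp_grid[2])
        summary_rows = []
        try:
            for subgroup in config.subgroups:
                if subgroup == "combined":
                    sub = dataset[dataset["cohort"].isin(ELIGIBLE_COHORTS)]
                else:
                    sub = dataset[dataset["cohort"] == subgroup]
                if sub.empty:
                    logger.warning("subgroup %s empty; skipped", subgroup)
                    continue
                results = run_scenarios(
                    sub, value_set, decays=config.scenarios,
                    discount_rate=config.discount_rate, payment=config.payment,
                    index_factor=config.index_factor, B=config.n_bootstrap,
                    seed=config.seed, wtp_threshold=config.wtp_threshold,
                    wtp_grid=grid,
                )
                for decay, (res, curve) in results.items():
                    summary_rows.append(_summary_row(subgroup, decay, res, curve))
                    tag = f"{subgroup}_decay{decay:g}"
                    rep = pd.DataFrame(
                        {"b": np.arange(1, res.B + 1),
                         "delta_cost": res.replicates[:, 0],
                         "delta_qaly": res.replicates[:, 1]}
                    )
                    path = out / f"replicates_{tag}.csv"
                    rep.to_csv(path, index=False)
                    artifacts.append(path)
                    path = out / f"ceac_{tag}.csv"
                    pd.DataFrame(
                        {"wtp": curve.wtp_grid, "probability": curve.probability}
                    ).to_csv(path, index=False)
                    artifacts.append(path)
                logger.info("CEA subgroup %s: %d patients, %d scenarios",
                            subgroup, len(sub), len(results))
            path = out / "cea_summary.csv"
            pd.DataFrame(summary_rows).to_csv(path, index=False)
            artifacts.append(path)
        except Exception as exc:
            raise fail("cea", exc)

        # --- stage: service use ---
        try:
            su = service_use_table(dataset)
            path = out / "service_use.csv"
            su.to_csv(path)
            artifacts.append(path)
            logger.info("service-use table: %d outcomes", len(su))
        except Exception as exc:
            raise fail("service_use", exc)

        manifest = {
            "seed": config.seed,
            "config": {
                "value_set": config.value_set,
                "discount_rate": config.discount_rate,
                "payment": config.payment,
                "index_factor": config.index_factor,
                "n_bootstrap": config.n_bootstrap,
                "wtp_threshold": config.wtp_threshold,
                "scenarios": list(config.scenarios),
                "subgroups": list(config.subgroups),
                "dataset_path": config.dataset_path,
                "generator": config.generator.to_dict(),
            },
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        manifest = json.loads(json.dumps(manifest))  # normalise tuples to lists
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("run complete: %d artifacts", len(artifacts))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
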