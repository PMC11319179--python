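"""Full-analysis orchestration: one config in, a bundle of CSV reports out.

``run_full_analysis`` evaluates every configured setting (urban/rural), then
writes:

* ``cea_table.csv`` — per-strategy cost/utility/C-U plus pairwise
  incremental rows (the published cost-utility table layout);
* ``tornado.csv`` — one-way sensitivity bars per setting and comparison;
* ``psa_samples.csv`` — (ΔC, ΔE) scatter per PSA draw and comparison;
* ``ceac.csv`` — acceptability curves over a λ grid, with the WTP noted;
* ``trace_<setting>_<arm>.csv`` — cohort occupancy traces;
* ``manifest.json`` — seed, package version and SHA-256 of each parameter
  file, so a run is attributable to its exact inputs.

On any failure, partial outputs written by the failed run are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cea import full_comparison
from .markov import evaluate_setting, run_cohort
from .params import ModelParameters, load_parameters
from .sensitivity import (
    ceac,
    default_lambda_grid,
    default_owsa_ranges,
    default_psa_distributions,
    owsa,
    psa,
    psa_frame,
    tornado_frame,
)

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameter_files: dict[str, str]  # setting label -> parameter file path
    mode: Literal["cohort", "microsim"] = "cohort"
    n_individuals: int | None = None
    seed: int | None = 0
    psa_iterations: int = Field(default=1000, ge=1)
    lambda_points: int = Field(default=101, ge=2)
    run_owsa: bool = True
    run_psa: bool = True
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode == "microsim" and (self.n_individuals is None or self.seed is None):
            raise ValueError("microsim mode requires n_individuals and seed")
        return self


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return RunConfig.model_validate(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    config: RunConfig,
    parameters: Mapping[str, ModelParameters] | None = None,
) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    ``parameters`` may supply already-built bundles keyed by setting label
    (e.g. from the synthetic generator); otherwise the configured parameter
    files are loaded.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}
    t0 = time.time()

    def write_csv(name: str, df: pd.DataFrame) -> Path:
        p = out_dir / name
        df.to_csv(p, index=False)  # full precision; round only for presentation
        written.append(p)
        return p

    try:
        bundles: dict[str, ModelParameters] = {}
        hashes: dict[str, str] = {}
        for label, path in config.parameter_files.items():
            if parameters is not None and label in parameters:
                bundles[label] = parameters[label]
                payload = json.dumps(
                    bundles[label].model_dump(mode="json"), sort_keys=True
                ).encode()
                hashes[label] = hashlib.sha256(payload).hexdigest()
            else:
                bundles[label] = load_parameters(path)
                hashes[label] = _sha256(Path(path))
            logger.info("loaded %s parameters (%s)", label, hashes[label][:12])

        cea_rows, tornado_rows, psa_rows, ceac_rows = [], [], [], []
        for label, params in bundles.items():
            stage = time.time()
            outcomes = evaluate_setting(
                params,
                mode=config.mode,
                n_individuals=config.n_individuals or 100_000,
                seed=config.seed or 0,
            )
            _results, table = full_comparison(outcomes, params.wtp, setting_label=label)
            cea_rows.append(table)
            logger.info("%s: cost-utility table in %.2fs", label, time.time() - stage)

            for arm in ("diagnosed", "missed", "negative"):
                trace = run_cohort(params, arm).trace
                write_csv(f"trace_{label}_{arm}.csv", trace.to_frame())
            outputs[f"trace_{label}"] = out_dir

            comparisons = [
                (r, c)
                for r, c in (("FCG", "POCT_HBA1C"), ("FCG", "VENOUS_HBA1C"),
                             ("POCT_HBA1C", "VENOUS_HBA1C"))
                if any(s.name == r for s in params.strategies)
                and any(s.name == c for s in params.strategies)
            ]
            if config.run_owsa:
                stage = time.time()
                ranges = default_owsa_ranges(params)
                for comp in comparisons[:1]:  # headline comparison
                    entries = owsa(params, ranges, comp)
                    tf = tornado_frame(entries, ranges)
                    tf.insert(0, "setting", label)
                    tf.insert(1, "comparison", f"{comp[1]}_vs_{comp[0]}")
                    tornado_rows.append(tf)
                logger.info("%s: OWSA in %.2fs", label, time.time() - stage)

            if config.run_psa:
                stage = time.time()
                dists = default_psa_distributions(params)
                samples = psa(
                    params,
                    dists,
                    n_iter=config.psa_iterations,
                    seed=config.seed or 0,
                    comparisons=comparisons,
                )
                pf = psa_frame(samples)
                pf.insert(0, "setting", label)
                psa_rows.append(pf)
                grid = default_lambda_grid(params.wtp.value, config.lambda_points)
                cf = ceac(samples, grid)
                cf.insert(0, "setting", label)
                cf["wtp"] = params.wtp.value
                ceac_rows.append(cf)
                logger.info(
                    "%s: PSA (%d iterations) in %.2fs",
                    label, config.psa_iterations, time.time() - stage,
                )

        outputs["cea_table"] = write_csv("cea_table.csv", pd.concat(cea_rows, ignore_index=True))
        if tornado_rows:
            outputs["tornado"] = write_csv(
                "tornado.csv", pd.concat(tornado_rows, ignore_index=True)
            )
        if psa_rows:
            outputs["psa_samples"] = write_csv(
                "psa_samples.csv", pd.concat(psa_rows, ignore_index=True)
            )
            outputs["ceac"] = write_csv("ceac.csv", pd.concat(ceac_rows, ignore_index=True))

        manifest = {
            "seed": config.seed,
            "mode": config.mode,
            "psa_iterations": config.psa_iterations if config.run_psa else 0,
            "version": __version__,
            "parameter_hashes": hashes,
            "elapsed_seconds": round(time.time() - t0, 3),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        outputs["manifest"] = manifest_path
        return outputs
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
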