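"""Pipeline orchestration and run provenance.

The deterministic pipeline runs the model's five stages in order —
(1) malnutrition-within-disease prevalence from the examination survey,
(2) disease prevalence from the routed surveys, (3) state populations,
(4) cost parameters, (5) the attributable-cost equation — with per-stage
logging, and writes a run manifest (seeds, config hash, input digests,
version) that makes every output reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .burden import BurdenResult, compute_burden
from .diseases import Disease, default_diseases
from .io import (
    read_cost_config,
    read_population_table,
    read_survey_table,
    write_burden_tables,
)
from .malnutrition import Thresholds
from .prevalence import MIN_CELL_N, estimate_pmn, estimate_rho
from .sensitivity import PsaConfig, PsaResult, run_psa

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineOutput:
    burden: BurdenResult
    psa: PsaResult | None
    manifest_path: Path
    table_paths: dict[str, Path]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, command: str, inputs: dict[str, str],
                   config: dict, seed: int | None) -> Path:
    """Write the run manifest; exactly one per output directory."""
    manifest = {
        "command": command,
        "inputs": {k: _digest(v) for k, v in inputs.items()},
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "version": __version__,
        "python": platform.python_version(),
    }
    path = Path(out_dir) / "run_manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def pipeline(
    exam_path: str | Path,
    interview_path: str | Path,
    population_path: str | Path,
    costs_path: str | Path,
    out_dir: str | Path,
    states: Sequence[str] | None = None,
    diseases: Sequence[Disease] | None = None,
    thresholds: Thresholds = Thresholds(),
    min_cell_n: int = MIN_CELL_N,
    psa_config: PsaConfig | None = None,
    command: str = "estimate",
) -> PipelineOutput:
    """Run the full model from input files to written tables + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diseases = tuple(diseases) if diseases is not None else default_diseases()

    def stage(n: int, name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {n} ({name}) failed: {exc}") from exc
        return result

    exam = stage(1, "malnutrition prevalence inputs",
                 lambda: read_survey_table(exam_path, "examination"))
    logger.info("stage 1: %d examination records", len(exam))
    interview = stage(2, "disease prevalence inputs",
                      lambda: read_survey_table(interview_path, "interview"))
    logger.info("stage 2: %d interview records", len(interview))
    population = stage(3, "state populations",
                       lambda: read_population_table(population_path))
    logger.info("stage 3: %d states", population["state"].nunique())
    cost_params = stage(4, "cost parameters", lambda: read_cost_config(costs_path))
    logger.info("stage 4: delta_mn=%.3g", cost_params.delta_mn)

    def run_model():
        pmn = estimate_pmn(exam, diseases, thresholds, min_cell_n)
        n_pooled = int((pmn.table["pooled_level"] > 0).sum())
        logger.info("stage 1: PMN estimated; %d cell(s) filled by pooling", n_pooled)
        rho = estimate_rho(interview, exam, diseases, min_cell_n)
        logger.info("stage 2: rho estimated; %d flagged-empty cell(s)",
                    len(rho.flagged_empty()))
        pmn.to_csv(out_dir / "pmn_table.csv")
        rho.to_csv(out_dir / "rho_table.csv")
        return compute_burden(pmn, rho, population, cost_params, states)

    burden = stage(5, "attributable-cost equation", run_model)
    logger.info("stage 5: national total %.4g USD/year", burden.national_total())

    psa_result = None
    if psa_config is not None:
        psa_result = stage(5, "probabilistic sensitivity analysis", lambda: run_psa(
            exam, interview, population, cost_params, psa_config,
            diseases=diseases, states=states, thresholds=thresholds,
            min_cell_n=min_cell_n,
        ))
        burden = psa_result.point

    table_paths = write_burden_tables(burden, out_dir)
    manifest_path = write_manifest(
        out_dir, command,
        inputs={"examination": str(exam_path), "interview": str(interview_path),
                "population": str(population_path), "costs": str(costs_path)},
        config={
            "states": sorted(states) if states else None,
            "diseases": [(d.id, d.prevalence_source) for d in diseases],
            "thresholds": {"pct_ibw": thresholds.pct_ibw,
                           "albumin_gdl": thresholds.albumin_gdl,
                           "ibw_floor_lb": thresholds.ibw_floor_lb},
            "min_cell_n": min_cell_n,
            "psa": None if psa_config is None else {
                "n_reps": psa_config.n_reps, "ci_level": psa_config.ci_level,
                "vary_global_delta": psa_config.vary_global_delta,
                "resample_surveys": psa_config.resample_surveys,
            },
        },
        seed=None if psa_config is None else psa_config.seed,
    )
    return PipelineOutput(burden=burden, psa=psa_result,
                          manifest_path=manifest_path, table_paths=table_paths)
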