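"""One-command end-to-end run: cohort → summary → networks → centrality → blocks.

Loads or simulates a cohort, then for each requested level (leaf, class) and
stratum (total, male, female) writes the cohort summary, centrality tables,
blockmodel outputs and graph exports, plus a manifest recording the
configuration, seed, package versions and whole-network densities. All
randomness flows from the single configured seed and no output carries a
timestamp, so identical configuration yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_report
from .cohort import Cohort, STRATA, filter_stratum, load_cohort, write_cohort
from .concor import BlockModel, ConcorConfig, concor_partition
from .network import LEVELS, build_network, network_density, write_edgelist, write_gexf, write_graphml
from .simulate import SyntheticCohortSpec, generate_cohort, _spec_to_dict
from .taxonomy import default_taxonomy, load_taxonomy

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    output_dir: Path
    cohort_path: Path | None = None
    spec: SyntheticCohortSpec | None = None
    taxonomy_path: Path | None = None
    levels: tuple[str, ...] = LEVELS
    strata: tuple[str, ...] = STRATA
    concor: ConcorConfig = field(default_factory=ConcorConfig)
    seed: int | None = None  # overrides the spec's seed when simulating

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.spec is None):
            raise ValueError("exactly one of cohort_path or spec must be given")
        bad = set(self.levels) - set(LEVELS)
        if bad:
            raise ValueError(f"unknown level(s) {sorted(bad)}")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ValueError(f"unknown stratum(s) {sorted(bad)}")


def _write_blockmodel(model: BlockModel, prefix: Path) -> list[str]:
    paths = []
    membership = pd.DataFrame(
        {"node": list(model.nodes), "block": [model.partition[v] for v in model.nodes]}
    )
    p = prefix.with_name(prefix.name + "_blocks.csv")
    membership.to_csv(p, index=False)
    paths.append(str(p))

    k = model.n_blocks
    dens = pd.DataFrame(
        model.density_matrix,
        index=[f"block_{b}" for b in range(k)],
        columns=[f"block_{b}" for b in range(k)],
    )
    p = prefix.with_name(prefix.name + "_density.csv")
    dens.to_csv(p, float_format="%.6f")
    paths.append(str(p))

    p = prefix.with_name(prefix.name + "_blockmodel.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "cutoff": model.cutoff,
                "n_blocks": k,
                "blocks": [list(b) for b in model.blocks],
                "residual_block": model.residual_block,
                "significant": model.significant.astype(bool).tolist(),
                "split_tree": model.split_tree,
                "converged": model.converged,
                "warnings": list(model.warnings),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    paths.append(str(p))
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "precipnet", "version": __version__,
                    "numpy": np.__version__, "pandas": pd.__version__},
        "config": {
            "input_mode": "cohort" if config.cohort_path else "synthetic",
            "levels": list(config.levels),
            "strata": list(config.strata),
            "concor": dataclasses.asdict(config.concor),
            "seed": config.seed,
        },
        "outputs": {},
        "metrics": {},
    }
    if config.spec is not None:
        spec = config.spec
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        manifest["config"]["spec"] = _spec_to_dict(spec)

    stage = "input"
    try:
        t0 = time.perf_counter()
        if config.cohort_path is not None:
            taxonomy = (
                load_taxonomy(config.taxonomy_path)
                if config.taxonomy_path
                else default_taxonomy()
            )
            cohort = load_cohort(config.cohort_path, taxonomy)
        else:
            cohort = generate_cohort(spec)
        cohort_file = out / "cohort.csv"
        write_cohort(cohort, cohort_file)
        manifest["outputs"]["cohort"] = cohort_file.name
        manifest["metrics"]["n_cases"] = len(cohort)
        log.info("stage %s done in %.3fs (%d cases)", stage, time.perf_counter() - t0, len(cohort))

        stage = "summary"
        t0 = time.perf_counter()
        from .cohort import summarize_cohort

        summary = summarize_cohort(cohort)
        summary_file = out / "summary.csv"
        summary.table.to_csv(summary_file)
        manifest["outputs"]["summary"] = summary_file.name
        manifest["metrics"].update(
            {
                "report_totals": summary.report_totals,
                "n_zero_problem": summary.n_zero_problem,
                "n_single_problem": summary.n_single_problem,
                "n_multi_problem": summary.n_multi_problem,
            }
        )
        log.info("stage %s done in %.3fs", stage, time.perf_counter() - t0)

        cohorts = {"total": cohort}
        for gender in ("male", "female"):
            if gender in config.strata:
                cohorts[gender] = filter_stratum(cohort, gender)

        manifest["metrics"]["density"] = {}
        for level in config.levels:
            stage = f"network[{level}]"
            t0 = time.perf_counter()
            for stratum in config.strata:
                net = build_network(cohorts[stratum], level)
                prefix = out / f"network_{level}_{stratum}"
                write_edgelist(net, prefix.with_suffix(".csv"))
                write_graphml(net, prefix.with_suffix(".graphml"))
                write_gexf(net, prefix.with_suffix(".gexf"))
                manifest["outputs"][f"network_{level}_{stratum}"] = prefix.with_suffix(".csv").name
                manifest["metrics"]["density"][f"{level}_{stratum}"] = network_density(net)
            log.info("stage %s done in %.3fs", stage, time.perf_counter() - t0)

            stage = f"centrality[{level}]"
            t0 = time.perf_counter()
            report = centrality_report(cohort, level)
            cent_file = out / f"centrality_{level}.csv"
            report.table.to_csv(cent_file, float_format="%.6f")
            manifest["outputs"][f"centrality_{level}"] = cent_file.name
            log.info("stage %s done in %.3fs", stage, time.perf_counter() - t0)

            stage = f"blockmodel[{level}]"
            t0 = time.perf_counter()
            for stratum in config.strata:
                net = build_network(cohorts[stratum], level)
                model = concor_partition(net, config.concor)
                prefix = out / f"blockmodel_{level}_{stratum}"
                for p in _write_blockmodel(model, prefix):
                    manifest["outputs"][Path(p).stem] = Path(p).name
                manifest["metrics"][f"n_blocks_{level}_{stratum}"] = model.n_blocks
            log.info("stage %s done in %.3fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = "manifest.json"
    manifest["output_dir"] = str(out)
    return manifest
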