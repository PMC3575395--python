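"""Orchestration: simulate/load -> preprocess -> train -> map -> export.

Runs the stages in fixed order, writes every artifact to a single output
directory and records a manifest (config echo, library versions, seed,
convergence status, artifact list).  Any stage failure aborts with an
error naming the stage.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autocm import (
    AutoCMConfig,
    link_strengths,
    save_model,
    train,
    weights_to_distances,
)
from .cohort import CohortDesign, generate_cohort
from .connectivity import EXPORT_FORMATS, build_map, export_graph
from .preprocessing import (
    assemble_dataset,
    read_marker_table,
    write_scaled_dataset,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        raise StageError(name, exc) from exc
    logger.info("stage %s: done", name)


@dataclass
class PipelineConfig:
    """One run: exactly one of ``input_csv`` (real data) or ``design``.

    ``seed`` feeds the cohort simulation only; everything downstream is
    deterministic.
    """

    out_dir: Path
    input_csv: Path | None = None
    design: CohortDesign | None = None
    autocm: AutoCMConfig = field(default_factory=AutoCMConfig)
    formats: tuple[str, ...] = EXPORT_FORMATS
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.design is None):
            raise ValueError(
                "exactly one of input_csv (real data) or design (simulation) "
                "must be provided"
            )
        unknown = [f for f in self.formats if f not in EXPORT_FORMATS]
        if unknown:
            raise ValueError(
                f"unknown export format(s) {unknown}; options: {EXPORT_FORMATS}"
            )


def _write_matrix_csv(values: np.ndarray, names: list[str], path: Path) -> None:
    pd.DataFrame(values, index=names, columns=names).to_csv(path, encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; return (and write) the run manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def register(key: str, path: Path) -> Path:
        artifacts[key] = str(path)
        return path

    with _stage("input"):
        if config.design is not None:
            table = generate_cohort(config.design, config.seed)
            table.to_csv(
                register("cohort_csv", out / "cohort.csv"), index=False,
                encoding="utf-8",
            )
        else:
            table = read_marker_table(config.input_csv)

    with _stage("preprocess"):
        dataset = assemble_dataset(table)
        write_scaled_dataset(
            dataset,
            register("scaled_csv", out / "scaled.csv"),
            register("variables_json", out / "variables.json"),
        )

    with _stage("train"):
        model = train(dataset, config.autocm)
        save_model(model, register("model_json", out / "model.json"))

    with _stage("map"):
        dm = weights_to_distances(model)
        lsm = link_strengths(model)
        _write_matrix_csv(
            dm.values, dm.names, register("distances_csv", out / "distances.csv")
        )
        _write_matrix_csv(
            lsm.values, lsm.names,
            register("link_strengths_csv", out / "link_strengths.csv"),
        )
        cmap = build_map(dm, lsm, polarities=dataset.polarities)

    with _stage("export"):
        suffix = {"graphml": "map.graphml", "dot": "map.dot", "edge-tsv": "edges.tsv"}
        for fmt in config.formats:
            export_graph(cmap, fmt, register(f"map_{fmt}", out / suffix[fmt]))
        hub_rows = ["node\tpolarity\thub_degree"] + [
            f"{name}\t{cmap.nodes[name]}\t{deg}"
            for name, deg in sorted(
                cmap.hub_scores.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        register("hubs_tsv", out / "hubs.tsv").write_text(
            "\n".join(hub_rows) + "\n", encoding="utf-8"
        )

    manifest = {
        "autocmap_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "mode": "simulate" if config.design is not None else "real-data",
        "autocm_config": {
            "C": model.config.C,
            "epsilon": model.config.epsilon,
            "max_epochs": model.config.max_epochs,
            "tolerance": model.config.tolerance,
            "update_mode": model.config.update_mode,
            "record_order": model.config.record_order,
            "symmetrization": model.config.symmetrization,
            "ls_normalization": model.config.ls_normalization,
        },
        "n_subjects": dataset.n_records,
        "n_variables": len(dataset.variables),
        "converged": model.converged,
        "epochs_run": model.epochs_run,
        "artifacts": artifacts,
    }
    if not model.converged:
        logger.warning("pipeline: training did not converge; artifacts exported anyway")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False), encoding="utf-8"
    )
    manifest["artifacts"]["manifest_json"] = str(out / "manifest.json")
    return manifest
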