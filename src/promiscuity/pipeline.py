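"""Orchestration of the three analysis prongs and cross-prong statistics.

``run_pipeline`` executes any subset of four stages — curation of a kinetic
table, synthetic-table generation, the activation-energy null sweep, and the
constraint-model duplication study — writing CSV/JSON outputs plus a
machine-readable manifest (inputs, seeds, package versions).  Distributions
from different prongs are compared with the two-sample Kolmogorov-Smirnov
statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .duplication import duplication_study
from .kinetics import (
    DEFAULT_COFACTORS,
    curate_records,
    dataset_summary,
    read_cofactor_list,
    read_kinetic_table,
    read_synonym_table,
    write_dataset_summary,
    write_kinetic_table,
    write_profile_summary,
)
from .null_model import sigma_sweep
from .synthetic import AscertainmentConfig, GeneratorConfig, generate_profiles


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D in [0, 1].

    D is the maximum absolute difference between the empirical cumulative
    distribution functions; symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class RunConfig:
    """Pipeline configuration: stage blocks plus a master seed.

    Stage blocks are plain dicts matching the keyword arguments of the
    underlying stage (absent block = stage skipped).  Round-trips through
    YAML unchanged.
    """

    seed: int
    outdir: str
    curation: dict | None = None
    generator: dict | None = None
    null_sweep: dict | None = None
    model: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def _stage_curate(block: dict, outdir: Path) -> dict:
    records = read_kinetic_table(block["records"])
    synonyms = read_synonym_table(block["synonyms"]) if block.get("synonyms") else {}
    cofactors = (
        read_cofactor_list(block["cofactors"]) if block.get("cofactors") else DEFAULT_COFACTORS
    )
    profiles = curate_records(records, synonyms, cofactors,
                              mean_of_ratios=block.get("mean_of_ratios", False))
    summary = dataset_summary(profiles)
    profile_path = outdir / "profiles.csv"
    summary_path = outdir / "dataset_summary.json"
    write_profile_summary(profiles, profile_path)
    write_dataset_summary(summary, summary_path)
    return {"profiles": str(profile_path), "dataset_summary": str(summary_path)}


def _stage_generate(block: dict, outdir: Path, seed: int) -> dict:
    config = GeneratorConfig(seed=block.pop("seed", seed), **block)
    _, records = generate_profiles(config)
    table_path = outdir / "synthetic_records.tsv"
    write_kinetic_table(records, table_path)
    return {"synthetic_records": str(table_path), "generator_seed": config.seed}


def _stage_null(block: dict, outdir: Path, seed: int) -> dict:
    table = sigma_sweep(
        sigmas=block.get("sigmas", [0.2, 1.0, 2.0, 4.0, 6.0]),
        mu=block.get("mu", -6.0),
        n_samples=block.get("n_samples", 1000),
        seed=block.get("seed", seed),
    )
    path = outdir / "null_sweep.csv"
    table.to_csv(path, index=False)
    return {"null_sweep": str(path)}


def _stage_model(block: dict, outdir: Path) -> dict:
    n = block.get("n", 3)
    study = duplication_study(n, saturation_constant=block.get("saturation_constant", 0.5))
    path = outdir / f"duplication_study_n{n}.csv"
    study.to_csv(path, index=False)
    return {"duplication_study": str(path), "rows": len(study)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dict.  Input validation happens before any stage
    runs; any stage error propagates (the CLI maps it to a nonzero exit).
    """
    outdir = Path(config.outdir)
    # The curation input must pre-exist unless a generate stage in this run
    # writes it first.
    if config.curation is not None and config.generator is None:
        records = Path(config.curation["records"])
        if not records.exists():
            raise FileNotFoundError(f"kinetic table not found: {records}")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "promiscuity",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": {},
    }
    if config.generator is not None:
        manifest["stages"]["generate"] = _stage_generate(dict(config.generator), outdir, config.seed)
    if config.curation is not None:
        manifest["stages"]["curate"] = _stage_curate(dict(config.curation), outdir)
    if config.null_sweep is not None:
        manifest["stages"]["null"] = _stage_null(dict(config.null_sweep), outdir, config.seed)
    if config.model is not None:
        manifest["stages"]["model"] = _stage_model(dict(config.model), outdir)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
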