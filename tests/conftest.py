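"""Shared fixtures: a small simulated capture dataset and one full
pipeline run over it, computed once per session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from capkit import cleaning, pipeline
from capkit.io import read_fasta
from capkit.simulate import SimulationConfig, SimulationTruth, write_dataset

# the study conditions: 20 target exons, 6 diploid samples, 10-30x
# coverage, heterozygosity 0.005, sequencing error 0.001
STUDY_CONFIG = dict(
    n_loci=20,
    n_samples=6,
    coverage_per_locus=(10.0, 30.0),
    heterozygosity=0.005,
    error_rate=0.001,
    seed=1,
)


@dataclass
class PipelineRun:
    root: Path
    truth: SimulationTruth
    cleaning_counts: dict
    result: pipeline.PipelineResult
    elapsed: float


def run_study(root: Path, preset: str = "conservative", **overrides) -> PipelineRun:
    import time

    t0 = time.time()
    cfg = SimulationConfig(**{**STUDY_CONFIG, **overrides})
    truth = write_dataset(cfg, root)
    ccfg = cleaning.CleaningConfig(adapters=list(read_fasta(root / "adapters.fasta")))
    counts = pipeline.clean_dataset(
        root / "raw", root / "cleaned", ccfg,
        summary_path=root / "run" / "summary_stats.txt",
    )
    result = pipeline.automate_all(
        root / "cleaned", root / "reference.fasta", root / "run",
        preset=preset, force=True,
    )
    return PipelineRun(root, truth, counts, result, time.time() - t0)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory) -> PipelineRun:
    """One end-to-end run under the study conditions (seed 1)."""
    return run_study(tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A tiny simulated dataset (files only, no pipeline run)."""
    root = tmp_path_factory.mktemp("small")
    cfg = SimulationConfig(n_loci=6, n_samples=3, seed=7)
    truth = write_dataset(cfg, root)
    return root, cfg, truth
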