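from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from ipp.admin_records import ObservationWindow, link_subjects, read_flow_dir
from ipp.classifier import build_patient_matrix, default_ruleset
from ipp.stratifier import StratificationResult, stratify_population
from ipp.synth import default_config, generate_population


@pytest.fixture(scope="session")
def window() -> ObservationWindow:
    return ObservationWindow(2013, 2014)


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@dataclass
class PipelineRun:
    """A full synthetic-data pipeline run shared across tests."""

    config: object
    flows: dict
    truth: pd.DataFrame  # indexed by subject_id
    bundles: dict
    matrix: pd.DataFrame
    strat: StratificationResult
    per_year: dict[int, StratificationResult]


def _run_pipeline(n_subjects: int, seed: int, tmp_path) -> PipelineRun:
    cfg = default_config(n_subjects)
    rules = default_ruleset()
    generate_population(cfg, seed=seed, out_dir=tmp_path)
    flow_results = read_flow_dir(tmp_path)
    assert all(not f.rejects for f in flow_results.values())
    link = link_subjects(flow_results, cfg.window)
    assert not link.orphans
    matrix = build_patient_matrix(link.bundles, rules, cfg.window)
    strat = stratify_population(matrix, link.bundles, cfg.window)
    per_year = {}
    for year in cfg.window.years:
        w = cfg.window.single_year(year)
        m = build_patient_matrix(link.bundles, rules, w)
        per_year[year] = stratify_population(m, link.bundles, w)
    truth = pd.read_csv(tmp_path / "ground_truth.csv", dtype={"death_year": "object"},
                        keep_default_na=False).set_index("subject_id")
    flows = {k: v.records for k, v in flow_results.items()}
    return PipelineRun(cfg, flows, truth, link.bundles, matrix, strat, per_year)


@pytest.fixture(scope="session")
def calibrated_run(tmp_path_factory) -> PipelineRun:
    """Default-configuration run at the calibration scale (n=50,000,
    seed 42): generated as raw flow CSVs, read back, linked, classified
    and stratified for the whole window and per year."""
    tmp = tmp_path_factory.mktemp("flows50k")
    return _run_pipeline(50_000, 42, tmp)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory) -> PipelineRun:
    """A small run (n=2,000, seed 7) for cheap structural tests."""
    tmp = tmp_path_factory.mktemp("flows2k")
    return _run_pipeline(2_000, 7, tmp)
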