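"""Shared fixtures: the synthetic bundle, one pipeline run, and EB harnesses.

Expensive artefacts (the fixture bundle, the end-to-end pipeline run and the
5,000-transcript EB fits) are session-scoped so each is computed once.
"""

import warnings

import pytest

from aponet import (SimulationParams, StudyDesign, fit_two_group,
                    generate_counts, make_fixtures, plant_modules,
                    run_pipeline)
from aponet.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def meta(design):
    return design.metadata()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> PipelineConfig:
    """Synthetic study bundle on disk plus its pipeline config (seed 1)."""
    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixtures(out, seed=1)


@pytest.fixture(scope="session")
def bundle_truth(bundle):
    from aponet import GroundTruth
    from pathlib import Path
    return GroundTruth.from_json(Path(bundle.counts).parent / "truth.json")


@pytest.fixture(scope="session")
def pipeline_run(bundle):
    """One full pipeline execution on the bundle; (config, summary)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = run_pipeline(bundle)
    return bundle, summary


def _two_class_design():
    return StudyDesign(classes=(("A", 1), ("B", 1)))


def _harness(frac_de):
    design = _two_class_design()
    params = SimulationParams(
        n_transcripts=5000, genotype_sd=0.0, frac_de=frac_de, de_log2fc=2.0,
        frac_specific_per_class={}, n_modules=0, module_size=0, seed=7)
    matrix, truth = generate_counts(design, params)
    meta = design.metadata()
    ga = meta.loc[meta.phenotypic_class == "A", "sample_id"].tolist()
    gb = meta.loc[meta.phenotypic_class == "B", "sample_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, table = fit_two_group(matrix, ga, gb)
    return model, table, truth


@pytest.fixture(scope="session")
def eb_null_fit():
    """3 vs 3 samples, 5,000 transcripts, no planted DE (seed 7)."""
    return _harness(frac_de=0.0)


@pytest.fixture(scope="session")
def eb_de_fit():
    """Same harness with 10% planted DE at |log2FC| = 2."""
    return _harness(frac_de=0.10)


@pytest.fixture(scope="session")
def planted_module_graph():
    """HRR graph over 10 planted modules of 30 transcripts each (seed 1)."""
    from aponet import hrr_edges, pearson_all_pairs
    design = StudyDesign()
    params = SimulationParams(n_transcripts=300, frac_specific_per_class={},
                              frac_de=0.0, n_modules=10, module_size=30, seed=1)
    matrix, truth = generate_counts(design, params)
    matrix, truth = plant_modules(matrix, params, truth)
    edges = pearson_all_pairs(matrix, r_cutoff=0.8)
    graph = hrr_edges(edges, hrr_limit=30, nodes=matrix.transcript_ids)
    return graph, truth
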