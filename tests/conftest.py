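"""Shared synthetic fixtures; everything is generated at test time."""

import numpy as np
import pytest

from quillcycle import cycling, diel_expression, synthdata


@pytest.fixture(scope="session")
def small_design():
    return synthdata.SyntheticDesign(n_genes=60, n_contigs=3, seed=7)


@pytest.fixture(scope="session")
def small_genome(small_design):
    genome, annotation, truth = synthdata.generate_genome_annotation(small_design)
    return genome, annotation, truth


@pytest.fixture(scope="session")
def sinusoid_study():
    """200 genes, 10% sinusoidal cyclers, everything expressed."""
    design = synthdata.SyntheticDesign(
        n_genes=200, n_contigs=3, cycler_fraction=0.10,
        trace_family_mix={"sinusoid": 0.10, "arrhythmic": 0.90},
        low_expr_fraction=0.0, edge_truncated_fraction=0.0, seed=21)
    genome, annotation, _ = synthdata.generate_genome_annotation(design)
    counts, truth = synthdata.generate_diel_counts(design, annotation)
    return design, counts, truth


@pytest.fixture(scope="session")
def tpm_and_calls(sinusoid_study):
    _, counts, truth = sinusoid_study
    tpm = diel_expression.compute_tpm(counts)
    library = cycling.build_model_library(sorted(set(counts.design["zt_hour"])))
    calls = cycling.classify_cycling(tpm, counts.design, library)
    return tpm, counts.design, library, calls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
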