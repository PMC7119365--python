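import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from silknet import pipeline, quant, simulate  # noqa: E402


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The packaged synthetic study fixture (seed 1), generated once."""
    outdir = tmp_path_factory.mktemp("study")
    manifest = simulate.generate_study(outdir, seed=1)
    return outdir, manifest


def study_pipeline_config(manifest):
    return {
        "inputs": dict(manifest),
        "params": {
            "network": {"beta": 16, "cut_height": 0.975, "min_module_size": 20},
            "diffcoex": {"fc_threshold": 1.5, "weight_floor": 0.1},
        },
    }


@pytest.fixture(scope="session")
def study_run(study_dir, tmp_path_factory):
    """One full pipeline run on the study fixture."""
    _, manifest = study_dir
    outdir = tmp_path_factory.mktemp("study_run")
    summary = pipeline.run_pipeline(study_pipeline_config(manifest), outdir)
    return outdir, summary


@pytest.fixture(scope="session")
def small_counts():
    """Deterministic 200-gene, 4-sample count matrix (seed 11)."""
    rng = np.random.default_rng(11)
    means = np.exp(rng.uniform(np.log(20), np.log(2000), 200))
    counts = rng.poisson(means[:, None] * rng.uniform(0.5, 2.0, 4), (200, 4))
    return pd.DataFrame(
        counts, index=[f"g{i:03d}" for i in range(200)], columns=list("ABCD")
    )


def collapsed_expression(dataset):
    """Quantify a simulated dataset through the package path and collapse."""
    norm = quant.compute_tmm_factors(dataset.counts)
    fpkm = quant.compute_fpkm(dataset.counts, dataset.gene_lengths, norm)
    design = dataset.sample_sheet.set_index("sample", drop=False)
    return quant.collapse_replicates(fpkm, design)


def module_recovery_config(seed, module_conditions=None):
    """3 planted 50-gene modules (within-|r| 0.9) among 400 genes."""
    return simulate.ExpressionSimConfig(
        n_genes=400,
        module_sizes=(50, 50, 50),
        within_module_cor=0.9,
        module_conditions=module_conditions,
        dispersion=0.02,
        amplitude=2.0,
        base_mean_range=(200.0, 2000.0),
        rng_seed=seed,
    )


def diffcoex_recovery_config(seed, n_domestic=10, n_wild=4):
    """Planted condition-specific pairs among unstructured genes."""
    pairs = [
        (f"G{2 * i + 1:04d}", f"G{2 * i + 2:04d}", "domestic", 1.0)
        for i in range(n_domestic)
    ]
    offset = 2 * n_domestic
    pairs += [
        (f"G{offset + 2 * i + 1:04d}", f"G{offset + 2 * i + 2:04d}", "wild", 1.0)
        for i in range(n_wild)
    ]
    return simulate.ExpressionSimConfig(
        n_genes=300,
        module_sizes=(),
        within_module_cor=0.0,
        diff_edge_spec=pairs,
        dispersion=0.05,
        amplitude=2.0,
        rng_seed=seed,
    )


def sweep_recovery_config(seed):
    """One planted sweep (10x diversity reduction, 0.5 boost) on a 5 Mb
    chromosome."""
    return simulate.GenotypeSimConfig(
        chrom_length=5_000_000,
        snp_density=0.002,
        sweep_intervals=[(2_000_000, 2_250_000, 10.0, 0.5)],
        rng_seed=seed,
    )
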