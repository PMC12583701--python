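import json

import numpy as np
import pytest

from splicetime.io import RunConfig, run_pipeline
from splicetime.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    """Default synthetic study in the noise-free limit, plus pipeline output."""
    outdir = tmp_path_factory.mktemp("sim_noise_free")
    bundle = simulate(SimConfig(seed=11), outdir / "data", noise=False)
    cfg = RunConfig(
        se_tables={k: str(p) for k, p in bundle.se_tables.items()},
        bed=str(bundle.bed),
        fasta=str(bundle.fasta),
        motifs=str(bundle.motifs),
        interactome=str(bundle.interactome),
        outdir=str(outdir / "out"),
    )
    summary = run_pipeline(cfg)
    truth = json.loads(bundle.truth.read_text())
    return bundle, cfg, summary, truth


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default synthetic study with Poisson-Binomial count noise."""
    outdir = tmp_path_factory.mktemp("sim_noisy")
    bundle = simulate(SimConfig(seed=12), outdir / "data", noise=True)
    cfg = RunConfig(
        se_tables={k: str(p) for k, p in bundle.se_tables.items()},
        bed=str(bundle.bed),
        fasta=str(bundle.fasta),
        motifs=str(bundle.motifs),
        interactome=str(bundle.interactome),
        outdir=str(outdir / "out"),
    )
    summary = run_pipeline(cfg)
    truth = json.loads(bundle.truth.read_text())
    return bundle, cfg, summary, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
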