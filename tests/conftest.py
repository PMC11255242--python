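"""Shared fixtures: small seeded datasets and a default-scale pipeline run."""

from __future__ import annotations

from dataclasses import replace

import pytest

from rloopscan import peakcall, simgen, workbench
from rloopscan.genome import Gene, GenomeBundle

SMALL_PROFILE = replace(
    simgen.HUMAN_LIKE, name="small_human", n_genes=60, chrom_length=3_000_000
)


@pytest.fixture(scope="session")
def small_dataset() -> simgen.Dataset:
    cfg = simgen.SimulationConfig(seed=5)
    return simgen.simulate_dataset(SMALL_PROFILE, cfg)


@pytest.fixture(scope="session")
def small_peaks(small_dataset) -> dict:
    return {
        cond: peakcall.call_peaks(small_dataset.coverage[cond])
        for cond in ("control", "kd")
    }


@pytest.fixture(scope="session")
def default_run() -> dict:
    """Full default two-species pipeline, shared by the acceptance tests."""
    cfg = workbench.PipelineConfig(seed=1, write_files=False)
    return workbench.run_pipeline(cfg)


@pytest.fixture()
def toy_bundle() -> GenomeBundle:
    """20 kb single-gene genome with two introns, deterministic sequence."""
    import numpy as np

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    gene = Gene(
        gene_id="toy1",
        chrom="chr1",
        strand="+",
        start=2_000,
        end=18_000,
        exons=[(2_000, 2_500), (8_000, 8_400), (17_500, 18_000)],
    )
    return GenomeBundle(chroms={"chr1": seq}, genes=[gene])
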