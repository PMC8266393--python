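import numpy as np
import pandas as pd
import pytest

from spikequant.annotation import GeneModel
from spikequant.coverage import CoverageTrack
from spikequant.samples import SampleMeta


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="G1", chrom="chrI", strand="+", start=4900, end=6400,
        cds_start=5100, tss=5000, pas=6400,
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="G2", chrom="chrI", strand="-", start=3600, end=5000,
        cds_start=4900, tss=5000, pas=3600,
    )


@pytest.fixture
def uniform_track():
    """Value 2.0 everywhere on a 10 kb chromosome, already normalized."""
    return CoverageTrack.from_dense(
        {"chrI": np.full(10_000, 2.0)}, norm_state="chec_normalized"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_rle_track(rng, length=5000, n_runs=60, norm_state="chec_normalized"):
    """Random piecewise-constant track plus its dense mirror, for oracles."""
    dense = np.zeros(length)
    bounds = np.sort(rng.choice(length, size=n_runs, replace=False))
    values = rng.uniform(0, 5, size=n_runs)
    prev = 0
    for b, v in zip(bounds, values):
        dense[prev:b] = v
        prev = b
    track = CoverageTrack.from_dense({"chrI": dense}, norm_state=norm_state)
    return track, dense


@pytest.fixture
def rnaseq_metas():
    def spike(cond, rep):
        return 5000 + 100 * rep + (1000 if cond == "IAA" else 0)

    return [
        SampleMeta(
            sample_id=f"rnaseq_{cond}_rep{rep}", assay="rnaseq", condition=cond,
            replicate=rep, spike_reads=spike(cond, rep), experimental_reads=100_000,
        )
        for cond in ("DMSO", "IAA")
        for rep in (1, 2)
    ]
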