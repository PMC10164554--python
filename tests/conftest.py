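from __future__ import annotations

import numpy as np
import pytest

from tscreg.annotation import GeneAnnotation, GeneModel
from tscreg.pipeline import RunConfig, run_all
from tscreg.synthetic import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20230323)


@pytest.fixture
def small_annotation() -> GeneAnnotation:
    """Two genes on chr1 (one per strand), one gene on chr2."""
    return GeneAnnotation(
        [
            GeneModel(
                name="ALPHA",
                transcript_id="tx1",
                chrom="chr1",
                strand="+",
                tx_start=10_000,
                tx_end=30_000,
                exons=((10_000, 12_000), (20_000, 22_000), (28_000, 30_000)),
            ),
            GeneModel(
                name="BETA",
                transcript_id="tx2",
                chrom="chr1",
                strand="-",
                tx_start=100_000,
                tx_end=120_000,
                exons=((100_000, 104_000), (116_000, 120_000)),
            ),
            GeneModel(
                name="GAMMA",
                transcript_id="tx3",
                chrom="chr2",
                strand="+",
                tx_start=50_000,
                tx_end=60_000,
                exons=((50_000, 52_000), (58_000, 60_000)),
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The default synthetic study plus the full pipeline run on it."""
    indir = tmp_path_factory.mktemp("sim") / "study"
    outdir = tmp_path_factory.mktemp("sim") / "report"
    manifest = simulate(SimConfig(seed=1), indir)
    summary = run_all(RunConfig(indir=str(indir), outdir=str(outdir)))
    return {"indir": indir, "outdir": outdir, "manifest": manifest, "summary": summary}


@pytest.fixture(scope="session")
def noisefree_sim(tmp_path_factory):
    """Synthetic study with jitter disabled: placement is exact."""
    indir = tmp_path_factory.mktemp("sim0") / "study"
    outdir = tmp_path_factory.mktemp("sim0") / "report"
    manifest = simulate(SimConfig(seed=2, jitter_sd=0.0), indir)
    summary = run_all(RunConfig(indir=str(indir), outdir=str(outdir)))
    return {"indir": indir, "outdir": outdir, "manifest": manifest, "summary": summary}
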