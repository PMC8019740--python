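import pytest

from rbptargets import pipeline
from rbptargets.models import GeneModels, TranscriptModel
from rbptargets.synthetic import SimulationConfig, simulate


def make_transcript(tid="t1", gene="g1", chrom="chr1", strand="+",
                    exons=((0, 100),), cds=(10, 70)):
    return TranscriptModel(transcript_id=tid, gene_id=gene, chrom=chrom,
                           strand=strand, exons=tuple(exons),
                           cds_start=cds[0], cds_end=cds[1])


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=7, n_genes=200, n_planted_down=30,
                            n_planted_up=8, n_planted_null=80,
                            n_cohorts=8, n_samples_per_cohort=60)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def study_cfg():
    """The study-scale default conditions (1,000 genes, 6 experiments,
    31 cohorts, 60/12/300 planted classes)."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study_bundle(study_cfg):
    return simulate(study_cfg)


@pytest.fixture(scope="session")
def study_result(study_bundle):
    return pipeline.run(study_bundle, match_seed=1)
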