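import pytest

from ribostall.simulate import CONDITIONS, SimConfig, gen_coverage, gen_transcripts


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=20, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Transcripts + truth + coverage for both conditions, shared read-only."""
    transcripts, truth = gen_transcripts(small_cfg)
    coverages = []
    for cond in CONDITIONS:
        coverages.extend(gen_coverage(transcripts, truth, small_cfg, cond))
    return transcripts, truth, coverages
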