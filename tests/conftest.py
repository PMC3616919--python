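import pytest

from zygotrace.synthetic_data import build_diploid_transcriptome, random_sequences


@pytest.fixture(scope="session")
def small_diploid():
    """A 20-gene diploid transcriptome with ~200 bp SNP spacing."""
    refs = random_sequences(20, 1000, seed=11)
    maternal, paternal, snps = build_diploid_transcriptome(refs, 200.0, seed=11)
    lengths = {g: len(s) for g, s in refs.items()}
    return refs, maternal, paternal, snps, lengths
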