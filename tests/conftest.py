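import numpy as np
import pytest

from recseq.annotation_io import TranscriptModel
from recseq.synthetic_data import SimConfig, simulate_study

RNG_BASES = np.array(list("ACGT"))


def random_transcript(
    rng: np.random.Generator,
    transcript_id: str = "T1",
    utr5_len: int = 50,
    cds_len: int = 300,
    utr3_len: int = 30,
) -> TranscriptModel:
    """A random transcript with a valid start and stop codon."""
    seq = list(RNG_BASES[rng.integers(0, 4, size=utr5_len + cds_len + utr3_len)])
    seq[utr5_len : utr5_len + 3] = list("ATG")
    seq[utr5_len + cds_len - 3 : utr5_len + cds_len] = list("TAA")
    return TranscriptModel.from_annotation(transcript_id, "".join(seq), utr5_len, cds_len)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small but complete synthetic study shared across tests.

    40 transcripts, 3+3 replicates, enough reads for the qualitative
    behaviour of every stage without dominating the suite's runtime.
    """
    outdir = tmp_path_factory.mktemp("small_study")
    config = SimConfig(
        n_transcripts=40,
        mean_recruitment=150.0,
        spike_total_rate=4000.0,
        n_rna_reads=8000,
    )
    paths, truth = simulate_study(config, seed=42, outdir=outdir)
    return config, paths, truth
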