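import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from tagseq import simdata
from tagseq.annotate_count import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_transcriptome():
    return simdata.make_transcriptome(10, 3.0, seed=42)


@pytest.fixture
def transcript_models(small_transcriptome):
    """Single-exon forward-strand gene per synthetic transcript reference."""
    return [
        TranscriptModel(
            transcript_id=f"{t.id}.t1",
            gene_id=f"{t.id}.gene",
            reference=t.id,
            strand="+",
            exons=[(0, len(t.sequence))],
        )
        for t in small_transcriptome
    ]


@pytest.fixture
def two_gene_models():
    """Two + strand genes on one chromosome.  Gene A's middle exon overlaps
    gene B's 3' terminus (TTS 2999), so a read there tests the cross-gene
    end-beats-exon priority; A's introns span (2000,2900) and (3100,5000)."""
    a = TranscriptModel(
        transcript_id="A.t1", gene_id="A", reference="chr1", strand="+",
        exons=[(1000, 2000), (2900, 3100), (5000, 6000)],
    )
    b = TranscriptModel(
        transcript_id="B.t1", gene_id="B", reference="chr1", strand="+",
        exons=[(1500, 1600), (2500, 3000)],
    )
    return [a, b]
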