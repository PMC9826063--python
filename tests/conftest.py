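import numpy as np
import pytest

from anchorphase.io_qc import AlignedRead
from anchorphase.simulate import simulate_target
from anchorphase.types import DNMRecord, ErrorModel, RegionSpec


def make_read(
    start,
    seq,
    read_id="r0",
    contig="sim1",
    cigar=None,
    quals=None,
):
    """Construct an AlignedRead with sensible defaults (all-match CIGAR,
    quality 30)."""
    if cigar is None:
        cigar = [("M", len(seq))]
    if quals is None:
        quals = np.full(len(seq), 30, dtype=np.int16)
    return AlignedRead(
        read_id=read_id, contig=contig, start=start, cigar=cigar,
        seq=seq, quals=np.asarray(quals, dtype=np.int16),
    )


@pytest.fixture
def small_region():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
    return RegionSpec(contig="sim1", start=101, end=160, reference_seq=seq)


@pytest.fixture(scope="session")
def clean_dataset():
    """A noise-free prezygotic target: every read matches its haplotype."""
    return simulate_target(
        seed=11,
        coverage=200,
        error=ErrorModel(substitution_rate=0.0, indel_rate=0.0),
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """A prezygotic target under substitution noise at study scale."""
    return simulate_target(
        seed=12,
        coverage=1000,
        error=ErrorModel(substitution_rate=0.04, indel_rate=0.0),
    )


def dnm_record(ds):
    return DNMRecord(ds.region.contig, ds.dnm.position, ds.dnm.ref_base, ds.dnm.alt_base)
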