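import numpy as np
import pytest

from cnvcascade.fixture import load_fixture
from cnvcascade.models import CnvCall, CnvType, GenomicInterval
from cnvcascade.synthetic_cohort import SpikeSpec


@pytest.fixture(scope="session")
def study_fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def study_report(study_fixture):
    return study_fixture.build_report()


def make_call(
    chrom="1",
    start=1000,
    end=2000,
    sample_id="s1",
    copy_state=1,
    num_snps=10,
    conf=50.0,
):
    return CnvCall(
        interval=GenomicInterval(chrom, start, end),
        sample_id=sample_id,
        copy_state=copy_state,
        num_snps=num_snps,
        conf=conf,
    )


def random_calls(rng, n, sample_prefix="s", chroms=("1", "2", "3")):
    """Random CNV calls for oracle comparisons (small coordinates, dense)."""
    calls = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, 10_000))
        length = int(rng.integers(1, 2_000))
        calls.append(
            make_call(
                chrom=chrom,
                start=start,
                end=start + length - 1,
                sample_id=f"{sample_prefix}{i}",
                copy_state=int(rng.choice([0, 1, 3, 4])),
            )
        )
    return calls


def spike_set(seed, n=20, size=100_000, **kwargs):
    """n spike specs at reproducible random genomic positions."""
    rng = np.random.default_rng(seed)
    spikes = []
    for i in range(n):
        chrom = str(int(rng.integers(1, 23)))
        start = int(rng.integers(1_000_000, 100_000_000))
        spikes.append(
            SpikeSpec(
                interval=GenomicInterval(chrom, start, start + size - 1),
                cnv_type=CnvType.LOSS if i % 2 else CnvType.GAIN,
                **kwargs,
            )
        )
    return tuple(spikes)
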