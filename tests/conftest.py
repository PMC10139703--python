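import numpy as np
import pandas as pd
import pytest

from methdiv import MethSiteMatrix, SampleMeta


def make_matrix(counts: dict, samples: list[SampleMeta]) -> MethSiteMatrix:
    """Build a MethSiteMatrix from {(chrom, pos): {sample_id: (meth, unmeth)}}."""
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=["chrom", "pos"])
    meth = pd.DataFrame(index=idx, columns=[s.sample_id for s in samples],
                        dtype=np.int64)
    unmeth = meth.copy()
    for site, per_sample in counts.items():
        for sid, (m, u) in per_sample.items():
            meth.loc[site, sid] = m
            unmeth.loc[site, sid] = u
    return MethSiteMatrix(meth.astype(np.int64), unmeth.astype(np.int64), samples)


@pytest.fixture
def six_samples():
    """The main-comparison design: three native samples per population."""
    return [
        SampleMeta("m1", "marine", "native"),
        SampleMeta("m2", "marine", "native"),
        SampleMeta("m3", "marine", "native"),
        SampleMeta("f1", "freshwater", "native"),
        SampleMeta("f2", "freshwater", "native"),
        SampleMeta("f3", "freshwater", "native"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20230322)
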