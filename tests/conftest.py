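import numpy as np
import pytest

from stabcons.msa import WeightedMSA, henikoff_weights
from stabcons.stability import DdgRecord, DdgScan
from stabcons.synthetic import SyntheticSpec


@pytest.fixture
def toy_msa() -> WeightedMSA:
    """Four gap-free sequences with one perfectly coupled column pair (0, 1)."""
    msa = WeightedMSA(
        ids=["s1", "s2", "s3", "s4"],
        rows=["AAGG", "AAGG", "VVGA", "VVGA"],
    )
    henikoff_weights(msa)
    return msa


@pytest.fixture
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=11)


def make_scan(ddg_by_letter: dict[str, float], native: str = "A",
              temperature_K: float = 300.0) -> DdgScan:
    """Scan with a single position built from explicit per-letter ddG values."""
    recs = [DdgRecord("A", 1, native, native, 0.0)]
    recs += [
        DdgRecord("A", 1, native, aa, v)
        for aa, v in ddg_by_letter.items()
        if aa != native
    ]
    return DdgScan(records={("A", 1): recs}, temperature_K=temperature_K)
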