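import pytest

from dhnscan import make_proteome
from dhnscan.pipeline import PipelineConfig, mine_proteome

STANDARD_MIX = {"K_n": 10, "KS": 10, "SK_n": 10, "Y_nK_n": 10, "Y_nSK_n": 10}
STANDARD_SEED = 11


@pytest.fixture(scope="session")
def standard_proteome():
    """200 background proteins + 50 planted dehydrins (10 per class) at
    substitution rate 0.1, the study-scale mining benchmark."""
    records, truth = make_proteome(200, STANDARD_MIX, 0.1, seed=STANDARD_SEED)
    return {r.id: str(r.seq) for r in records}, truth


@pytest.fixture(scope="session")
def mined_records(standard_proteome):
    proteome, _ = standard_proteome
    records, _ = mine_proteome(proteome, PipelineConfig())
    return {r.sequence_id: r for r in records}
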