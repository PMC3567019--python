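import numpy as np
import pandas as pd
import pytest

from snppop import GenotypePanel


def make_panel(dosages, positions=None, chromosome="1", populations=None):
    """Small panel builder for hand-computed examples."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(m)]
    markers = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chromosome": chromosome,
            "position_bp": positions,
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = [f"ind{i}" for i in range(n)]
    if populations is None:
        pops = {s: "POP" for s in samples}
    elif isinstance(populations, dict):
        pops = populations
    else:
        pops = dict(zip(samples, populations))
    return GenotypePanel(markers, samples, pops, dosages)


@pytest.fixture
def two_pop_panel():
    """10+10 diploids at one SNP with p=0.8 / p=0.2 (the worked example)."""
    g1 = [2] * 6 + [1] * 4  # 16/20 copies
    g2 = [0] * 6 + [1] * 4  # 4/20 copies
    return make_panel(
        np.array([g1 + g2]).T.reshape(20, 1),
        populations=["P1"] * 10 + ["P2"] * 10,
    )
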