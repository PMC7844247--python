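import numpy as np
import pandas as pd
import pytest

from riboshift import make_catalog
from riboshift.riboproteome import FractionTable


@pytest.fixture(scope="session")
def toy_catalog():
    """Minimal catalog: two 60S RPs, two 40S RPs, both markers, one factor."""
    return make_catalog(
        [
            dict(protein_id="L1", gene_model="AT1G00010", rp_class="RP60S", family="uL1"),
            dict(protein_id="L2", gene_model="AT1G00020", rp_class="RP60S", family="uL2"),
            dict(protein_id="S1", gene_model="AT1G00030", rp_class="RP40S", family="uS1"),
            dict(protein_id="S2", gene_model="AT1G00040", rp_class="RP40S", family="uS2"),
            dict(
                protein_id="eIF6A",
                gene_model="AT3G55620",
                rp_class="biogenesis",
                family="TIF6",
                marker_role="pre60S_marker",
            ),
            dict(
                protein_id="NMD3",
                gene_model="AT2G03820",
                rp_class="biogenesis",
                family="NMD3",
                marker_role="pre60S_marker",
            ),
            dict(protein_id="X", gene_model="AT1G00050", rp_class="biogenesis", family="NOG1"),
        ]
    )


@pytest.fixture
def labeled_table(toy_catalog):
    """Five-fraction table whose class pattern fixes the gradient identity."""
    data = pd.DataFrame(
        {
            "F1": [1.0, 2.0, 100.0, 80.0, 0.2, 0.1, 1.0],
            "F2": [5.0, 4.0, 10.0, 8.0, 1.0, 0.5, 2.0],
            "F3": [100.0, 120.0, 2.0, 1.0, 50.0, 40.0, 30.0],
            "F4": [90.0, 100.0, 20.0, 15.0, 40.0, 30.0, 20.0],
            "F5": [60.0, 70.0, 50.0, 45.0, 4.0, 2.0, 1.0],
        },
        index=["L1", "L2", "S1", "S2", "eIF6A", "NMD3", "X"],
    )
    return FractionTable(data, toy_catalog, genotype="Col-0", temperature="10C")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
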