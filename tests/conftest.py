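import numpy as np
import pandas as pd
import pytest

import resphylo as rp

# 12-taxon Yule tree with a trait pair; lambda/GLS oracle values for this
# dataset were computed once with R (phytools::phylosig and nlme::gls with a
# corBrownian correlation, ML) and are frozen in the tests that use it.
ORACLE_NEWICK = (
    "((T03:1.086585531869304,(T08:0.2979095060764669,T09:0.2979095060764669)"
    ":0.7886760257928371):2.0669732077373113,((T01:1.1565341043322,"
    "T02:1.1565341043322):0.7949203332914183,(((((T11:0.012814437818852224,"
    "T12:0.012814437818852224):0.11196233296923389,T10:0.1247767707880861)"
    ":0.42495546644227183,T05:0.549732237230358):0.011327742454787012,"
    "T04:0.561059979685145):0.2349934490429289,(T06:0.41891213141246236,"
    "T07:0.41891213141246236):0.37714129731561147):1.1554010088955442)"
    ":1.2021043019829973);"
)

ORACLE_DATA = pd.DataFrame(
    {
        "species": ["T03", "T08", "T09", "T01", "T02", "T11",
                    "T12", "T10", "T05", "T04", "T06", "T07"],
        "y": [10.654837, 8.787440, 10.659039, 9.911340, 9.666431, 8.773928,
              10.700826, 9.594128, 9.185489, 9.156214, 10.290962, 10.278554],
        "x": [0.001545, 0.284331, 0.094110, -1.118315, -1.150049, -1.658423,
              -1.646042, -1.138777, -1.572419, -1.762727, -1.007570,
              -0.935223],
    }
)


@pytest.fixture(scope="session")
def oracle_tree(tmp_path_factory):
    path = tmp_path_factory.mktemp("oracle") / "tree.nwk"
    path.write_text(ORACLE_NEWICK + "\n")
    return rp.read_tree(path)


@pytest.fixture(scope="session")
def oracle_data():
    return ORACLE_DATA.copy()


@pytest.fixture()
def toy_alignment():
    rows = np.array(
        [list("MK-AEL"), list("MKCAEL"), list("MRCAEV"), list("MRCGEV")]
    )
    return rp.Alignment(["sp1", "sp2", "sp3", "sp4"], rows)


@pytest.fixture()
def toy_traits():
    return rp.TraitTable(
        pd.DataFrame(
            {
                "species": ["sp1", "sp2", "sp3", "sp4"],
                "L_avg": [30.0, 10.0, 20.0, 20.0],
                "L_max": [45.0, 18.0, 31.0, np.nan],
            }
        )
    )


@pytest.fixture()
def small_bundle():
    return rp.make_dataset(
        rp.SimConfig(n_taxa=15, L_total=25, linked_columns=(5, 20), seed=11)
    )
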