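import numpy as np
import pandas as pd
import pytest

from amplistat import (FeatureTable, SampleMetadata, TaxonomyMap,
                       SyntheticConfig, generate_tables)


@pytest.fixture
def tiny_table():
    """2 taxa x 2 samples with counts [[5,0],[1,3]]."""
    return FeatureTable(pd.DataFrame([[5, 0], [1, 3]],
                                     index=["t1", "t2"],
                                     columns=["s1", "s2"]))


@pytest.fixture
def taxonomy_small():
    df = pd.DataFrame({
        "kingdom": ["bacteria", "bacteria", "bacteria", "fungi"],
        "oral": [True, False, True, False],
        "domain": ["Bacteria"] * 3 + ["Fungi"],
        "phylum": ["P1", "P1", "P2", "FP"],
        "class": ["C1", "C1", "C2", "FC"],
        "order": ["O1", "O1", "O2", "FO"],
        "family": ["F1", "F1", "F2", "FF"],
        "genus": ["G1", "G1", "G2", "FG"],
        "species": ["sp1", "sp2", "sp3", "fsp"],
    }, index=["t1", "t2", "t3", "t4"])
    return TaxonomyMap(df)


@pytest.fixture
def meta_two_groups():
    df = pd.DataFrame({"group": ["HC"] * 3 + ["ESCC"] * 3},
                      index=[f"s{i}" for i in range(6)])
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_cohort():
    """One scaled-down synthetic cohort shared across tests."""
    cfg = SyntheticConfig(seed=42)
    return generate_tables(cfg)
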