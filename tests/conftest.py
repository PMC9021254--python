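"""Shared fixtures: cohorts are simulated once per session and reused."""

import numpy as np
import pandas as pd
import pytest

from periomip.simulate import CohortDesign, null_design, planted_design, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Canonical planted cohort: 100 participants x 2 sites, 100 features,
    +2/-2 natural-log deep-site effects on the Treponema/Corynebacterium
    genera."""
    return simulate_cohort(planted_design(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects: deep and shallow exchangeable."""
    return simulate_cohort(null_design(seed=12))


@pytest.fixture(scope="session")
def fitted_ranker(planted_cohort):
    from periomip import fit_multinomial

    table, meta, _, _, _ = planted_cohort
    return fit_multinomial(table, meta, random_state=0)


@pytest.fixture(scope="session")
def planted_rpca(planted_cohort):
    from periomip import rpca

    table, _, _, _, _ = planted_cohort
    return rpca(table, rank=3, seed=0)


@pytest.fixture()
def tiny_table():
    return pd.DataFrame(
        [[5, 0, 3], [1, 3, 0], [2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )


@pytest.fixture()
def hand_taxonomy():
    return pd.Series(
        {
            "f1": "k__Bacteria; p__Spirochaetes; g__Treponema; s__Treponema_denticola",
            "f2": "k__Bacteria; p__Actinobacteria; g__Corynebacterium; s__Corynebacterium_matruchotii",
            "f3": "k__Bacteria; p__Firmicutes; g__Streptococcus; s__Streptococcus_sanguinis",
        },
        name="lineage",
    )
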