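import numpy as np
import pandas as pd
import pytest

from zooenergetics.nutrition import MacronutrientTotals

# Study-table period means (grams dry matter per day) used by several
# digestibility / metabolizable-energy tests: ingested diet and fecal
# output for the two animals.
FEMALE_INTAKE = MacronutrientTotals(dm_g=147.9, cp_g=24.9, ndf_g=42.1, cf_g=9.7, tnc_g=61.0)
FEMALE_FECAL = MacronutrientTotals(dm_g=52.7, cp_g=12.3, ndf_g=20.2, cf_g=3.5, tnc_g=6.5)
MALE_INTAKE = MacronutrientTotals(dm_g=214.1, cp_g=40.0, ndf_g=56.5, cf_g=12.1, tnc_g=88.7)
MALE_FECAL = MacronutrientTotals(dm_g=42.6, cp_g=10.1, ndf_g=17.2, cf_g=3.2, tnc_g=2.5)


@pytest.fixture(scope="session")
def female_tables():
    return FEMALE_INTAKE, FEMALE_FECAL


@pytest.fixture(scope="session")
def male_tables():
    return MALE_INTAKE, MALE_FECAL


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):1,C:2); — the three-taxon hand-checkable tree."""
    import dendropy

    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def diet_run():
    """One noiseless-fecal simulated diet year shared across tests."""
    from zooenergetics.simulate import female_like_diet_scenario, simulate_diet_study

    scenario = female_like_diet_scenario(seed=11)
    feed, fecal, truth = simulate_diet_study(scenario)
    return scenario, feed, fecal, truth
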