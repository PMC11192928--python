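import logging

import numpy as np
import pandas as pd
import pytest

from vitdmr import grs, pheno, simdata

logging.getLogger("vitdmr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def panel():
    return simdata.default_panel()


@pytest.fixture(scope="session")
def small_panel():
    return simdata.SnpPanel(
        [
            simdata.SnpRecord("rs1", "A", "G", 0.30, 1.5),
            simdata.SnpRecord("rs2", "C", "T", 0.50, 0.8),
            simdata.SnpRecord("rs3", "G", "A", 0.70, 1.1),
        ]
    )


@pytest.fixture(scope="session")
def cohort():
    cfg = simdata.SimConfig(n_total=4000, n_subcohort=1200)
    return simdata.simulate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def processed(cohort):
    return pheno.process_phenotypes(cohort.participants)


@pytest.fixture(scope="session")
def score(cohort):
    return grs.compute_grs(cohort.genotypes, cohort.panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_participants(n=50, seed=0):
    """Minimal hand-rolled participant table for phenotype-rule tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": rng.uniform(20, 80, n),
            "sex": rng.binomial(1, 0.5, n).astype(float),
            "bmi": rng.normal(27, 4, n),
            "smoking": rng.choice(["never", "former_lt10", "current_gt20"], n),
            "alcohol": rng.choice(["never", "1to4"], n),
            "activity": rng.choice(["inactive", "low"], n),
            "education": rng.choice(["lt10", "ge13"], n),
            "econ_difficulty": rng.choice(["no", "yes"], n),
            "day_of_year": rng.integers(1, 366, n).astype(float),
            "vitd_raw": rng.uniform(20, 100, n),
        }
    )
    for wave in (1, 2):
        base = rng.normal(130, 10, n)
        for r in (1, 2, 3):
            df[f"sbp_w{wave}_r{r}"] = base + rng.normal(0, 2, n)
            df[f"dbp_w{wave}_r{r}"] = base * 0.6 + rng.normal(0, 2, n)
        df[f"med_use_w{wave}"] = rng.binomial(1, 0.2, n).astype(bool)
    df["followup_w2"] = True
    return df
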