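"""Shared fixtures: a cohort reconstructing the published descriptive counts,
and small seeded simulated cohorts/fits reused across test modules."""

import numpy as np
import pytest

from mvtlogit.cohort import CohortData, Exposure, SurvivorRecord
from mvtlogit.sampler import MCMCConfig, fit_latent_t
from mvtlogit.simulate import GeneratorSpec, generate_cohort
from mvtlogit.core import ModelSpec
from mvtlogit.cohort import design_matrix


def _group_records(group: Exposure, size: int, counts: dict, cs_dose: float,
                   crt: int, offset: int) -> list[SurvivorRecord]:
    """Records whose marginal outcome counts match the requested totals;
    each binary variable set for the first k records of the group."""
    recs = []
    for i in range(size):
        y = tuple(int(i < counts[oc]) for oc in
                  ("obesity", "insulin_resistance", "pre_hypertension", "dyslipidemia"))
        recs.append(SurvivorRecord(
            id=f"R{offset + i:04d}", y=y, exposure=group,
            sex=int(i < counts["male"]), age_dx=6.6, wbc_dx=9.6, time_dx=15.4,
            cs_dose=cs_dose, crt=crt))
    return recs


@pytest.fixture(scope="session")
def table1_cohort() -> CohortData:
    """241 survivors whose per-group marginal counts equal the published
    descriptive table: groups 99/82/60; obesity 27/30/19; insulin resistance
    13/15/13; (pre-)hypertension 8/12/9; dyslipidemia 30/37/30; male 41/45/32."""
    spec = [
        (Exposure.LD_NO_CRT, 99, dict(obesity=27, insulin_resistance=13,
                                      pre_hypertension=8, dyslipidemia=30, male=41),
         7603.0, 0),
        (Exposure.LD_CRT, 82, dict(obesity=30, insulin_resistance=15,
                                   pre_hypertension=12, dyslipidemia=37, male=45),
         9747.0, 1),
        (Exposure.HD_CRT, 60, dict(obesity=19, insulin_resistance=13,
                                   pre_hypertension=9, dyslipidemia=30, male=32),
         19087.0, 1),
    ]
    records, offset = [], 0
    for group, size, counts, dose, crt in spec:
        records.extend(_group_records(group, size, counts, dose, crt, offset))
        offset += size
    return CohortData(records=tuple(records))


@pytest.fixture(scope="session")
def small_sim():
    """Simulated cohort (n=150) with its ground truth."""
    return generate_cohort(GeneratorSpec(n=150), seed=42)


@pytest.fixture(scope="session")
def quick_draws(small_sim):
    """A short seeded fit of the full model on the small simulated cohort."""
    X, terms = design_matrix(small_sim.cohort, "full")
    cfg = MCMCConfig(n_iter=900, n_burn=300, thin=4, seed=3)
    draws = fit_latent_t(small_sim.cohort.outcomes, X, ModelSpec(), cfg, terms=terms)
    return draws, X
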