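"""Shared fixtures: printed-count fixture cohort and seeded synthetic tables."""

import numpy as np
import pandas as pd
import pytest

from neoquad import (
    AgeGroupScheme,
    DeathRecord,
    Quarter,
    SyntheticConfig,
    build_quarter_tables,
    filter_analyzable,
    generate_cohort,
)

# Composition of the motivating surveillance cohort: 1007 enrolled deaths,
# 48 with unknown time of death, 2 without verbal autopsy (disjoint), and
# the 957 analyzable deaths split 397/142/235/183 across the four age bands.
COHORT_TOTAL = 1007
N_NO_TIME = 48
N_NO_VA = 2
BAND_COUNTS = (397, 142, 235, 183)


def make_printed_cohort() -> tuple[list[DeathRecord], dict[Quarter, int]]:
    """A fixture cohort reproducing the printed composition arithmetic.

    Deaths are spread deterministically over the 25 quarters from 2010Q4
    to 2016Q4, with ages placed inside each band.
    """
    scheme = AgeGroupScheme()
    lowers = (0,) + scheme.bounds[:-1]
    quarters = []
    q = Quarter(2010, 4)
    for _ in range(25):
        quarters.append(q)
        q = q.next()

    records: list[DeathRecord] = []
    i = 0
    for band, count in enumerate(BAND_COUNTS):
        span = scheme.bounds[band] - lowers[band]
        for j in range(count):
            quarter = quarters[i % 25]
            birth = quarter.start + pd.Timedelta(hours=6 * (i % 7))
            age_h = lowers[band] + (j % span) + 0.5
            records.append(
                DeathRecord(
                    record_id=f"ok-{i:04d}",
                    birth_dt=birth,
                    death_dt=birth + pd.Timedelta(hours=age_h),
                    has_va=True,
                    cause=("preterm", "asphyxia", "sepsis")[i % 3],
                )
            )
            i += 1
    for j in range(N_NO_TIME):
        quarter = quarters[j % 25]
        records.append(
            DeathRecord(
                record_id=f"notime-{j:03d}",
                birth_dt=quarter.start,
                death_dt=None,
                has_va=True,
                cause="preterm",
            )
        )
    for j in range(N_NO_VA):
        quarter = quarters[j % 25]
        birth = quarter.start + pd.Timedelta(hours=1)
        records.append(
            DeathRecord(
                record_id=f"nova-{j}",
                birth_dt=birth,
                death_dt=birth + pd.Timedelta(hours=30),
                has_va=False,
                cause=None,
            )
        )
    assert len(records) == COHORT_TOTAL
    tallies = {q: 1500 for q in quarters}
    return records, tallies


@pytest.fixture(scope="session")
def printed_cohort():
    return make_printed_cohort()


@pytest.fixture(scope="session")
def scheme():
    return AgeGroupScheme()


@pytest.fixture(scope="session")
def seeded_tables():
    """Default 25-quarter synthetic cohort (seed 1), tabulated."""
    records, tallies = generate_cohort(SyntheticConfig(seed=1))
    retained, _ = filter_analyzable(records)
    tables, _ = build_quarter_tables(retained, tallies)
    return tables
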