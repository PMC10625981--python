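import numpy as np
import pandas as pd
import pytest

from cvdnlp.synth import GeneratorConfig, generate_cohort

OBSERVATION = (pd.Timestamp("2011-01-01"), pd.Timestamp("2018-09-30"))


@pytest.fixture(scope="session")
def dense_cohort():
    """A small cohort with a high discharge rate, for labelling tests."""
    cfg = GeneratorConfig(n_patients=350, hosp_rate=0.30, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study conditions (~3% positives at 24 months)."""
    cfg = GeneratorConfig(n_patients=2000, seed=1)
    return generate_cohort(cfg)


def month_shift_oracle(date: pd.Timestamp, months: int) -> pd.Timestamp:
    """Independent calendar-month shift with day clamping (no pandas offsets)."""
    import calendar

    y, m, d = date.year, date.month, date.day
    total = y * 12 + (m - 1) - months
    ny, nm = divmod(total, 12)
    nm += 1
    nd = min(d, calendar.monthrange(ny, nm)[1])
    return pd.Timestamp(year=ny, month=nm, day=nd)
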