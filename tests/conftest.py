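import datetime as dt

import numpy as np
import pytest

from sleepclines.dam import BeamCrossSeries, LightSchedule


@pytest.fixture
def schedule():
    return LightSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(20110901)


def make_series(counts, fly_id="f1", schedule=None, start_zt_minute=0, **meta):
    """A ZT-aligned series starting at the given ZT minute."""
    schedule = schedule or LightSchedule()
    on = dt.datetime.combine(dt.date(2011, 9, 1), schedule.lights_on_clock_time)
    return BeamCrossSeries(
        fly_id=fly_id,
        counts=np.asarray(counts, dtype=np.int64),
        schedule=schedule,
        start_timestamp=on + dt.timedelta(minutes=start_zt_minute),
        **meta,
    )


@pytest.fixture
def day_series():
    """One full ZT day: active minute-on-minute-off by day, asleep at night."""
    counts = np.zeros(1440, dtype=np.int64)
    counts[0:720:2] = 2  # photophase: alternating activity
    counts[720:740] = 1  # brief activity after lights-off, then sleep
    return make_series(counts)
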