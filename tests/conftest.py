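import dataclasses

import numpy as np
import pytest

from crylight import synth
from crylight.types import ActivitySeries, LightSchedule


@pytest.fixture(scope="session")
def presets():
    return synth.standard_presets()


@pytest.fixture(scope="session")
def dm_preset(presets):
    return presets["DmCRY"]


def with_locomotor(preset, **kw):
    return dataclasses.replace(
        preset, locomotor=dataclasses.replace(preset.locomotor, **kw)
    )


def with_ephys(preset, **kw):
    return dataclasses.replace(
        preset, ephys=dataclasses.replace(preset.ephys, **kw)
    )


def with_choice(preset, **kw):
    return dataclasses.replace(preset, choice=synth.ChoiceParams(**kw))


def make_series(counts, dd_start_bin=None, t0="08:00", fly_id="fly0"):
    """ActivitySeries starting at lights-on with a 12:12 schedule."""
    counts = np.asarray(counts, dtype=np.int64)
    sched = LightSchedule(zt0_clock_time="08:00", dd_start_bin=dd_start_bin)
    return ActivitySeries(fly_id, "test", t0, counts, sched)


@pytest.fixture(scope="session")
def rhythmic_cohort(dm_preset):
    """30 rhythmic flies, tau 25.0 h, 7 d LD + 7 d DD."""
    preset = with_locomotor(dm_preset, tau_h=25.0, rhythmic_fraction=1.0)
    return synth.simulate_locomotor(
        preset, n_flies=30, days_ld=7, days_dd=7, seed=250
    )
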