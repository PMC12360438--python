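"""Shared fixtures: expensive protocol runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import sonomech as sm


@pytest.fixture()
def config():
    return sm.default_config()


@pytest.fixture(scope="session")
def arm_results():
    """All eight experimental arms on the default configuration.

    The control run doubles as the trigger-finding run, so each arm is
    simulated exactly once.
    """
    config = sm.default_config()
    control = sm.run_protocol(config, sm.TreatmentSchedule(arm_name="control"))
    trigger = float(np.interp(config["protocol"]["trigger_volume_mm3"],
                              control.tumor_volume_mm3, control.time_h))
    schedules = sm.build_experimental_arms(config, trigger_time_h=trigger)
    results = {"control": control}
    for schedule in schedules:
        if schedule.arm_name != "control":
            results[schedule.arm_name] = sm.run_protocol(config, schedule)
    return results


@pytest.fixture(scope="session")
def sweep_results():
    """Order/interval sweep tables for both administration orders."""
    config = sm.default_config()
    return {order: sm.parametric_sweep(config, order)
            for order in ("sono_first", "nano_first")}
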