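import numpy as np
import pytest

from chronopk.pump import build_trial_schedule, solve_transport_characteristics
from chronopk.volumes import PatientAnthropometrics, compute_compartment_volumes

DRUGS = ["CPT11", "LOHP", "FU5"]


@pytest.fixture(scope="session")
def trial_programs():
    return {d: build_trial_schedule(d) for d in DRUGS}


@pytest.fixture(scope="session")
def trial_deliveries(trial_programs):
    return {d: solve_transport_characteristics(p) for d, p in trial_programs.items()}


@pytest.fixture(scope="session")
def reference_patient():
    return PatientAnthropometrics(sex="male", height_m=1.75, weight_kg=75.0, patient_id="REF")


@pytest.fixture(scope="session")
def reference_volumes(reference_patient):
    return compute_compartment_volumes(reference_patient)


def random_program(rng, tube=None):
    """A random valid pump program: 1-3 drug segments plus a tube-emptying flush."""
    from chronopk.pump import DEFAULT_TUBE, InfusionSegment, PumpProgram

    tube = tube or DEFAULT_TUBE
    t = 0.0
    segments = []
    for _ in range(rng.integers(1, 4)):
        duration = float(rng.uniform(0.5, 3.0))
        shape = "constant" if rng.random() < 0.5 else "half_sin_squared"
        segments.append(InfusionSegment(
            start_h=t, duration_h=duration, shape=shape,
            peak_rate_ml_h=float(rng.uniform(2.0, 30.0)),
            solution="drug", stock_mg_ml=float(rng.uniform(1.0, 50.0)),
        ))
        t += duration + float(rng.uniform(0.0, 1.0))
    flush_rate = float(rng.uniform(8.0, 20.0))
    flush_duration = max(0.5, 2.5 * tube.volume_ml / flush_rate)  # guarantees >= tube volume
    segments.append(InfusionSegment(
        start_h=t, duration_h=flush_duration, shape="constant",
        peak_rate_ml_h=flush_rate, solution="glucose",
    ))
    return PumpProgram(segments=tuple(segments), tube=tube)
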