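import numpy as np
import pytest

import nmtflab as nl


@pytest.fixture(scope="session")
def default_protocol():
    return nl.StimulationProtocol()


@pytest.fixture(scope="session")
def vehicle_model():
    """Noise-free model calibrated to the control group's end-of-run forces."""
    return nl.FailureModel.from_normalized_forces(
        0.700, 0.2422, f0=0.126, d120=0.019, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def vehicle_recording(vehicle_model):
    rec, gt = nl.simulate_recording(model=vehicle_model)
    return rec, gt


@pytest.fixture(scope="session")
def default_stack():
    """One rendered NMJ stack at default geometry targets, with ground truth."""
    return nl.render_nmj_stack(nl.NMJShapeParams(seed=1))


def make_recording(rec_template, force):
    """Clone a recording with a replacement force channel (markers kept)."""
    return nl.ForceRecording(
        sampling_rate_hz=rec_template.sampling_rate_hz,
        time_s=rec_template.time_s,
        force_n=np.asarray(force, dtype=float),
        nerve_stim_marker=rec_template.nerve_stim_marker,
        muscle_stim_marker=rec_template.muscle_stim_marker,
        metadata=rec_template.metadata,
        protocol=rec_template.protocol,
    )
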