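import numpy as np
import pytest

from stimarx import preprocess, synth


@pytest.fixture(scope="session")
def switched_bundle():
    """A small switched-ARX recording with known ground truth, shared by
    read-only tests."""
    geom = synth.make_electrode_geometry(3, 120, seed=10)
    system = synth.sample_ground_truth_system(
        geom, family="sl-arx", L=4, M=3, noise_sd=0.1, seed=11)
    sched = synth.make_schedule(
        frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=6,
        gap_ms=1500, seed=12)
    rec = synth.simulate_recording(system, sched, geometry=geom, seed=13)
    ws = preprocess.extract_windows_and_folds(rec, seed=14)
    u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
    return {
        "geometry": geom, "system": system, "schedule": sched,
        "recording": rec, "windows": ws, "u": u, "U": U,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
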