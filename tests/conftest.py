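"""Shared fixtures: small frames and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from qusresponse.synthetic_rf import (
    AcousticPulse,
    FrameGeometry,
    ScatteringSpec,
    simulate_cohort,
    simulate_reference_frame,
    simulate_rf_frame,
)


@pytest.fixture(scope="session")
def pulse() -> AcousticPulse:
    return AcousticPulse()


@pytest.fixture(scope="session")
def tissue_spec() -> ScatteringSpec:
    return ScatteringSpec(
        esd_true=80.0, eac_true_db=30.0, attenuation=1.0, sound_speed=1540.0
    )


@pytest.fixture(scope="session")
def sample_frame(pulse, tissue_spec):
    """Homogeneous tissue frame with enough lines for spectral averaging."""
    geom = FrameGeometry.from_acquisition(
        2000, 512, 60.0, tissue_spec.sound_speed, pulse.sampling_frequency
    )
    return simulate_rf_frame(tissue_spec, geom, pulse, seed=101)


@pytest.fixture(scope="session")
def reference_frame(pulse):
    geom = FrameGeometry.from_acquisition(
        2000, 512, 60.0, 1488.0, pulse.sampling_frequency
    )
    return simulate_reference_frame(geom, pulse, seed=202)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 patients with very small frames: structure tests, not recovery."""
    return simulate_cohort(
        20,
        seed=7,
        responder_fraction=0.75,
        n_lines=32,
        n_samples=1280,
        core_radius_range_mm=(3.0, 4.0),
    )
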