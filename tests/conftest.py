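import numpy as np
import pytest

from maskmvpa.design import (
    DesignSpec,
    FeedforwardComponent,
    GroundTruth,
    NoiseModel,
    OscillatoryComponent,
    RecurrentComponent,
)


@pytest.fixture
def tiny_design():
    """Four objects, two masks, 8 trials/cell on 8 channels, coarse grid."""
    return DesignSpec(
        n_objects=4,
        trials_per_cell=8,
        n_channels=8,
        tmin_ms=-200.0,
        tmax_ms=800.0,
        tstep_ms=50.0,
        n_subjects=2,
    )


@pytest.fixture
def default_truth():
    return GroundTruth()


def make_truth(
    ff_amp=1.0,
    rec_early=0.2,
    rec_late=1.0,
    osc_amp=0.0,
    osc_freq=10.0,
    noise=1.0,
    overlap=1.0,
    jitter=0.3,
    signal=1.0,
):
    """Convenience ground-truth builder for planted-signal constructions."""
    return GroundTruth(
        feedforward=FeedforwardComponent(amplitude=ff_amp),
        recurrent=RecurrentComponent(
            amplitude_by_mask={"early": rec_early, "late": rec_late}
        ),
        oscillatory=OscillatoryComponent(freq_hz=osc_freq, amplitude=osc_amp),
        noise=NoiseModel(scale=noise),
        signal_scale=signal,
        cross_condition_overlap=overlap,
        subject_jitter=jitter,
    )
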