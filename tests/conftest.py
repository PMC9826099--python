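"""Shared fixtures: study-scale geometry plus scaled-down synthetic recordings.

Analysis tests run the full method chain on recordings with fewer trials and
a lower sampling rate than the default paradigm (the physics and windows are
unchanged; only the problem size shrinks to keep the suite fast).
"""

import numpy as np
import pytest

from triaxmeg.fields import BackgroundField
from triaxmeg.geometry import HeadModel, build_helmet_array
from triaxmeg.opm import NoiseModel, calibrate_linewidth
from triaxmeg.synthpara import (
    Paradigm,
    generate_participant,
    generate_recording,
    single_source_participant,
)


@pytest.fixture(scope="session")
def head():
    return HeadModel(np.zeros(3), 0.08)


@pytest.fixture(scope="session")
def array():
    return build_helmet_array(30, scalp_radius=0.09)


@pytest.fixture(scope="session")
def small_paradigm():
    """Two blocks x 5 trials at 600 Hz: the scaled-down study."""
    return Paradigm(n_blocks=2, trials_per_block=5, fs=600.0)


@pytest.fixture(scope="session")
def nulled_background():
    """Residual field after nulling: 0.2 nT uniform, 2.0 nT/m gradients."""
    g = np.array([1.7, -1.3, 1.5, 1.2, -1.0])
    g *= 2.0 / np.linalg.norm(g)
    return BackgroundField(np.array([0.14, 0.0, 0.14]), g)


@pytest.fixture(scope="session")
def gain_model():
    return calibrate_linewidth(3.0, 0.038)


@pytest.fixture(scope="session")
def participant():
    return generate_participant("P1", seed=5)


@pytest.fixture(scope="session")
def single_source():
    return single_source_participant("P1", seed=5)


@pytest.fixture(scope="session")
def study_recording(single_source, small_paradigm, nulled_background, gain_model):
    """One scaled-down recording with a single planted motor dipole."""
    return generate_recording(
        single_source,
        small_paradigm,
        env=nulled_background,
        gm=gain_model,
        nm=NoiseModel(10.0, seed=0),
        seed=100,
    )
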