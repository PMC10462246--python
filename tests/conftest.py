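from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

# property tests must replay identically across runs
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from predose import (
    KineticSpec,
    Radionuclide,
    load_nuclide,
    load_phantom,
    load_svalues,
    load_weights,
    plan_empirical,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mouse_phantom():
    return load_phantom(DATA / "phantom_mouse.csv")


@pytest.fixture(scope="session")
def human_phantom():
    return load_phantom(DATA / "phantom_human.csv")


@pytest.fixture(scope="session")
def beta_nuclide():
    return load_nuclide(DATA / "nuclide.csv", name="Lu177like")


@pytest.fixture(scope="session")
def alpha_nuclide():
    return load_nuclide(DATA / "nuclide.csv", name="Ac225like")


@pytest.fixture(scope="session")
def mouse_svalues(mouse_phantom):
    with pytest.warns(UserWarning, match="cross-fire"):
        return load_svalues(DATA / "svalues_mouse.csv", mouse_phantom, "Lu177like")


@pytest.fixture(scope="session")
def human_svalues(human_phantom):
    with pytest.warns(UserWarning, match="cross-fire"):
        return load_svalues(DATA / "svalues_human.csv", human_phantom, "Lu177like")


@pytest.fixture(scope="session")
def weighting_table():
    return load_weights(DATA / "weights.csv")


@pytest.fixture
def short_nuclide():
    """A 6 h half-life emitter for fast-kinetics tests."""
    return Radionuclide(name="Tc99mlike", half_life_h=6.0, delta_np_J=2.7e-15)


@pytest.fixture(scope="session")
def mouse_kinetics():
    """Bi-exponential mouse ground truth covering the whole body.

    Liver and kidneys clear bi-/mono-exponentially, the carcass holds the
    remainder; zero-time amplitudes sum to 1 (all activity accounted for).
    The schedule is planned from the dominant effective half-life.
    """
    half_life = 159.4
    lam_p = np.log(2) / half_life
    lam_dominant = 0.08 + lam_p
    te = np.log(2) / lam_dominant
    times = plan_empirical(5, te).times_h
    return KineticSpec(
        regions={
            "Liver": ((0.25, 0.08), (0.05, 0.008)),
            "Kidneys": ((0.10, 0.15),),
            "Carcass": ((0.45, 0.08), (0.15, 0.008)),
        },
        half_life_h=half_life,
        times_h=tuple(times),
        urinary_fractions=(0.7, 0.1),
        body_mass_mean_g=25.0,
        body_mass_sd_g=1.5,
        noise_cv=0.05,
        replicates=3,
        seed=20260101,
    )
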