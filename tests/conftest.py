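import numpy as np
import pytest

import ftirdeconv as fd

# Secondary-structure profiles used as generator ground truth throughout the
# suite, in band order 1627/1645/1654/1670/1685 cm-1 (intermolecular
# beta-sheet, unassigned remainder, alpha-helix, beta-turn, intramolecular
# beta-sheet).  The two named rows correspond to the control and the 5%
# propylene glycol model systems.
CONTROL_PROFILE = (36.58, 3.01, 19.56, 31.30, 9.55)
PG5_PROFILE = (34.29, 3.03, 18.36, 32.19, 12.13)

PROFILE_KEYS = (
    "intermolecular_beta_sheet_pct",
    "unassigned_pct",
    "alpha_helix_pct",
    "beta_turn_pct",
    "intramolecular_beta_sheet_pct",
)


def profile_errors(profile: fd.SecondaryStructureProfile, truth) -> dict:
    d = profile.as_dict()
    return {k: d[k] - t for k, t in zip(PROFILE_KEYS, truth)}


@pytest.fixture(scope="session")
def control_amide_fit():
    """Noise-free control-profile composite pushed through the amide chain."""
    spec, truth = fd.generate_amide_i(CONTROL_PROFILE)
    fit, profile = fd.analyze_amide(spec, anchors=None)
    return spec, truth, fit, profile


@pytest.fixture(scope="session")
def pg5_amide_fit():
    """Noise-free 5% propylene glycol composite through the amide chain."""
    spec, truth = fd.generate_amide_i(PG5_PROFILE)
    fit, profile = fd.analyze_amide(spec, anchors=None)
    return spec, truth, fit, profile


@pytest.fixture
def gaussian_spectrum():
    """A single Gaussian band (center 1650, h 0.8, fwhm 20) on flat baseline."""
    grid = fd.uniform_grid(1500.0, 1800.0, 1.0)
    band = fd.Band(1650.0, 0.8, 20.0, 0.0)
    return fd.Spectrum(grid, fd.gl_profile(grid, band)), band
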