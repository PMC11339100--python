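"""Shared fixtures: one phantom subject rendered and analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from perfx.engine import compute_maps
from perfx.phantom import (AcquisitionProtocol, default_aif, make_default_scene,
                           render)


@pytest.fixture(scope="session")
def aif():
    return default_aif()


@pytest.fixture(scope="session")
def scene():
    return make_default_scene(seed=1, lesion_delay=8.0)


@pytest.fixture(scope="session")
def truth(scene, aif):
    return scene.ground_truth(aif)


@pytest.fixture(scope="session")
def series_mdctp_noiseless(scene, aif):
    return render(scene, aif, AcquisitionProtocol.mdctp_like(), noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def series_mdctp(scene, aif):
    return render(scene, aif, AcquisitionProtocol.mdctp_like(), noise_sd=2.0, seed=11)


@pytest.fixture(scope="session")
def series_fdctp_noiseless(scene, aif):
    return render(scene, aif, AcquisitionProtocol.fdctp_like(), noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def maps_mdctp_noiseless(series_mdctp_noiseless):
    return compute_maps(series_mdctp_noiseless)


@pytest.fixture(scope="session")
def maps_mdctp(series_mdctp):
    return compute_maps(series_mdctp)


@pytest.fixture(scope="session")
def maps_fdctp_noiseless(series_fdctp_noiseless):
    return compute_maps(series_fdctp_noiseless, smooth_fwhm_mm=12.0)


def mirror_x(mask_or_map: np.ndarray) -> np.ndarray:
    """Reflect a volume about the midline plane (homologous voxels)."""
    return mask_or_map[::-1]
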