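"""Shared fixtures: synthetic phantoms are generated once per session.

All test data is produced programmatically by the simulator; nothing is
read from disk except what the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

from phantomqa import detect_markers, write_series
from phantomqa.synthetic_phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """A fully loaded noisy phantom (markers, 7 density plugs, air hole,
    resolution plug at +35 mm) at fine-mode defaults."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def default_markers(default_phantom):
    volume, _ = default_phantom
    return detect_markers(volume)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same layout without noise: every measurement is exact."""
    return generate_phantom(PhantomSpec(seed=0, noise_sigma_hu=0.0))


@pytest.fixture(scope="session")
def noiseless_markers(noiseless_phantom):
    volume, _ = noiseless_phantom
    return detect_markers(volume)


@pytest.fixture(scope="session")
def series_dir(tmp_path_factory, default_phantom):
    """The default phantom written out as a DICOM series folder."""
    volume, _ = default_phantom
    folder = tmp_path_factory.mktemp("series")
    write_series(volume, folder)
    return folder


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
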