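import numpy as np
import pytest

from cbbct.phantom import AcquisitionSpec, LesionSpec, render_exam


@pytest.fixture
def small_acq():
    """Desk-scale noiseless acquisition for geometric oracles."""
    return AcquisitionSpec(voxel_size=0.5, grid_shape=(48, 48, 48), noise_sd=0.0)


@pytest.fixture
def sphere_exam(small_acq):
    """Zero-noise 10 mm sphere with a persistent 1.5x curve peaking at 120 s."""
    lesion = LesionSpec(axes=(10, 10, 10), baseline_hu=200.0, peak_ratio=1.5, t_peak=120.0)
    return render_exam(lesion, small_acq, seed=0)
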