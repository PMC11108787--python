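import numpy as np
import pytest

from lctau.core_io import BrainVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def slab_fixture():
    """Noise-free LC slab with a planted 5-voxel cluster of contrast 0.3."""
    from lctau import synthetic

    shape = (12, 12, 6)
    lc = np.zeros(shape, bool)
    lc[4:8, 4:8, 1:5] = True
    ref = np.zeros(shape, bool)
    ref[0:3, 0:3, :] = True
    cluster = [(5, 5, 2), (5, 6, 2), (6, 5, 2), (6, 6, 2), (5, 5, 3)]
    slab, lcm, refm, truth = synthetic.gen_lc_slab(
        shape, lc, ref, cluster, contrast=0.3, noise_sd=0.0, seed=7)
    return {"slab": slab, "lc": lcm, "ref": refm, "truth": truth,
            "lc_bool": lc, "ref_bool": ref, "shape": shape}


@pytest.fixture
def unit_volume():
    return BrainVolume(np.ones((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
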