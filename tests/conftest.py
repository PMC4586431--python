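import time

import numpy as np
import pytest

import nucspark as ns


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One execution of the bundled end-to-end fixture, shared across tests.

    Returns (config, run directory, wall time in seconds).
    """
    out = tmp_path_factory.mktemp("demo_run")
    cfg = ns.demo_config(seed=7)
    t0 = time.time()
    ns.run_pipeline(cfg, out)
    return cfg, out, time.time() - t0


@pytest.fixture()
def noiseless_config():
    """Small noiseless two-nucleus fiber used by several modules."""
    return ns.SimConfig(
        image_width_px=128, image_height_px=128, n_frames=30,
        fiber=ns.FiberSpec(center_um=(12.8, 12.8), size_um=(22.0, 20.0)),
        nuclei=(ns.NucleusSpec(center_um=(8.0, 8.0)),
                ns.NucleusSpec(center_um=(18.0, 16.0))),
        shot_noise=False, read_noise_sd=0.0, seed=0,
    )


@pytest.fixture()
def disc_nucleus():
    """A 4-um-radius disc nucleus on a 128x128 grid at 0.2 um/px."""
    ps = 0.2
    yy, xx = np.mgrid[0:128, 0:128]
    x_um, y_um = (xx + 0.5) * ps, (yy + 0.5) * ps
    mask = (x_um - 12.9) ** 2 + (y_um - 12.9) ** 2 <= 4.0**2
    return ns.NucleusMask(nucleus_id=1, mask=mask, pixel_size_um=ps)
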