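import numpy as np
import pytest

import neuraltube as nt


@pytest.fixture(scope="session")
def params():
    return nt.published_defaults()


@pytest.fixture(scope="session")
def consensus():
    return nt.Topology.consensus()


@pytest.fixture(scope="session")
def synth_data():
    return nt.generate_synthetic_qpcr(
        n_genes_per_region=8, ct_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
        noise_sd=0.1, seed=7,
    )


@pytest.fixture(scope="session")
def small_tube():
    """Reduced bent-tube preset: fast enough for repeated 3D runs."""
    return nt.build_tube(
        length=600.0, outer_radius=90.0, wall_thickness=30.0,
        bend_angle_deg=90.0, bend_start=150.0, bend_end=300.0,
        zli_s=180.0, io_s=420.0, v_range=(280.0, 380.0),
        rp_range=(210.0, 600.0),
    )


@pytest.fixture(scope="session")
def straight_small_tube():
    return nt.build_tube(
        length=300.0, outer_radius=60.0, wall_thickness=20.0,
        bend_angle_deg=0.0, bend_start=50.0, bend_end=100.0,
        zli_s=60.0, io_s=240.0, v_range=(120.0, 180.0),
        rp_range=(100.0, 300.0),
    )


def steady_3d(tube, params, **kwargs):
    kwargs.setdefault("dt", 0.05)
    kwargs.setdefault("max_steps", 60_000)
    kwargs.setdefault("tol", 1e-6)
    return nt.simulate_to_steady(tube, params, **kwargs)
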