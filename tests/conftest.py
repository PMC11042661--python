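import numpy as np
import pytest

from solidstress import (
    SliceShapeSpec,
    StackRenderSpec,
    TraceSimSpec,
    make_height_field,
    oracle_indices,
    render_stack,
    simulate_trace,
)

CAP_RADIUS_UM = 1000.0
OUTLINE_RADIUS_UM = 500.0
SIN_AMPLITUDE_UM = 50.0
SIN_WAVELENGTH_UM = 800.0


@pytest.fixture(scope="session")
def cap_spec():
    return SliceShapeSpec(
        shape_kind="spherical_cap",
        amplitude_or_radius=CAP_RADIUS_UM,
        outline_radius=OUTLINE_RADIUS_UM,
    )


@pytest.fixture(scope="session")
def sin_spec():
    return SliceShapeSpec(
        shape_kind="sinusoid",
        amplitude_or_radius=SIN_AMPLITUDE_UM,
        wavelength=SIN_WAVELENGTH_UM,
        outline_radius=OUTLINE_RADIUS_UM,
    )


@pytest.fixture(scope="session")
def cap_oracle(cap_spec):
    return oracle_indices(cap_spec)


@pytest.fixture(scope="session")
def sin_oracle(sin_spec):
    return oracle_indices(sin_spec)


@pytest.fixture(scope="session")
def cap_stack(cap_spec):
    hf = make_height_field(cap_spec, resolution=10.0)
    return render_stack(hf, StackRenderSpec())


def render_shape(spec, noise_sd=0.0, seed=0, resolution=10.0):
    hf = make_height_field(spec, resolution=resolution)
    stack = render_stack(
        hf, StackRenderSpec(noise_sd=noise_sd, seed=seed), thickness=spec.thickness
    )
    return hf, stack


@pytest.fixture(scope="session")
def noiseless_trace():
    return simulate_trace(TraceSimSpec())


def index_rel_errors(idx, ref):
    return (
        abs(idx.dn_um / ref.dn_um - 1),
        abs(idx.ra / ref.ra - 1),
        abs(idx.km_per_um / ref.km_per_um - 1),
    )
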