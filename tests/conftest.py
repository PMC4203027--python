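import numpy as np
import pytest

import aerophylo as ap
from aerophylo.coefficients import coefficients_from_moments
from aerophylo.frames import transform_records


@pytest.fixture(scope="session")
def design():
    return ap.build_test_design()


@pytest.fixture(scope="session")
def geometry():
    return ap.ModelGeometry("model")


def reduce_taxon(truth, design, geometry, seed):
    """simulate -> transform -> coefficients for one taxon."""
    records = ap.simulate_taxon(truth, design, geometry, seed)
    moments = transform_records(records)
    geom = {truth.taxon_id: ap.ModelGeometry(truth.taxon_id, geometry.snout_vent,
                                             geometry.planform_area, geometry.sensor_offset)}
    return coefficients_from_moments(moments, geom)


@pytest.fixture(scope="session")
def noisefree_suite():
    return ap.make_fixture_suite(noise=False)


@pytest.fixture(scope="session")
def noisy_suite():
    return ap.make_fixture_suite()


@pytest.fixture(scope="session")
def noisefree_estimates(design, geometry, noisefree_suite):
    """Estimates for every zero-noise fixture taxon (computed once)."""
    out = {}
    for name, truth in noisefree_suite.items():
        coeffs = reduce_taxon(truth, design, geometry, seed=11)
        out[name] = ap.estimate_taxon(coeffs)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
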