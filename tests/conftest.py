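import numpy as np
import pytest

from humepr.lineshapes import LineComponent
from humepr.synthetic import EPRGeneratorConfig, generate_epr


@pytest.fixture
def forest_components():
    """Forest-soil-like Gaussian + Lorentzian pair (shared B0)."""
    from humepr.synthetic import preset_components

    return preset_components("forest")


@pytest.fixture
def make_spectrum():
    """Factory for synthetic spectra from explicit components."""

    def _make(components, *, noise_sigma=0.0, n_points=1024, span=None, seed=0,
              baseline=0.0, frequency=9.45):
        comps = tuple(components)
        b0s = [c.B0 for c in comps]
        widths = [c.dBpp for c in comps]
        if span is None:
            span = 6.0 * max(widths)
        cfg = EPRGeneratorConfig(
            components=comps,
            frequency=frequency,
            field_min=min(b0s) - span,
            field_max=max(b0s) + span,
            n_points=n_points,
            noise_sigma=noise_sigma,
            baseline=baseline,
            seed=seed,
        )
        return generate_epr(cfg)

    return _make


@pytest.fixture
def single_lorentzian():
    return LineComponent("lorentzian", 337.0, 0.45, 1.0)


@pytest.fixture
def single_gaussian():
    return LineComponent("gaussian", 337.0, 1.52, 1.0)
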