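import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from icga.synthetic import severity_presets, simulate_curve


@pytest.fixture(scope="session")
def time_grid():
    """Standard analysis grid: 120 s at 5 fps."""
    return np.arange(600) / 5.0


@pytest.fixture(scope="session")
def noiseless_curves(time_grid):
    """Noiseless, baseline-free curve per severity class, with truth records."""
    from dataclasses import replace

    out = {}
    for name, preset in severity_presets().items():
        model = replace(preset.model, baseline=0.0)
        curve, truth = simulate_curve(model, time_grid, seed=0, roi_label=name)
        out[name] = (curve, truth)
    return out
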