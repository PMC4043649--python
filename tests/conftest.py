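import numpy as np
import pytest

from cytovar.synth import wt_cohort_preset


@pytest.fixture(scope="session")
def wt_config():
    """Calibrated wild-type cohort preset (50 ul, full acquisition)."""
    return wt_cohort_preset()


@pytest.fixture(scope="session")
def fast_config():
    """Same cohort statistics at reduced acquisition for quick event-level tests."""
    return wt_cohort_preset(acquisition_fraction=0.1, volume_ul=20.0)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero-spread templates, zero technical/day noise: deterministic intensities."""
    cfg = wt_cohort_preset(acquisition_fraction=0.2, volume_ul=20.0)
    templates = {p: t.with_spread(0.0) for p, t in cfg.templates.items()}
    return cfg.copy(
        templates=templates,
        technical_cv={p: 0.0 for p in cfg.technical_cv},
        day_noise_cv=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
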