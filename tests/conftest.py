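import numpy as np
import pytest

from seatsense.pressure import PressureSequence, TrialMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_seq(rng):
    """A 5-frame random 4x4 sequence with strictly positive pressure."""
    frames = rng.uniform(0.5, 10.0, size=(5, 4, 4))
    return PressureSequence(frames, meta=TrialMeta(subject="S01", label="NC"))


def tiny_params(**overrides):
    """Small, fast simulation settings shared across test modules."""
    from seatsense.simulate import SimulationParams

    defaults = dict(n_subjects=4, reps=6, duration=1.2)
    defaults.update(overrides)
    return SimulationParams(**defaults)


def zero_effect(params):
    """Copy of ``params`` with every compensation effect size set to 0."""
    from dataclasses import replace

    return replace(
        params,
        tlf_forward_shift=0.0,
        tr_lateral_shift=0.0,
        tr_load_asymmetry=0.0,
        se_ipsilateral_shift=0.0,
        se_amp_asymmetry=0.0,
    )


def scale_effects(params, factor):
    from dataclasses import replace

    return replace(
        params,
        tlf_forward_shift=params.tlf_forward_shift * factor,
        tr_lateral_shift=params.tr_lateral_shift * factor,
        tr_load_asymmetry=params.tr_load_asymmetry * factor,
        se_ipsilateral_shift=params.se_ipsilateral_shift * factor,
        se_amp_asymmetry=params.se_amp_asymmetry * factor,
    )
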