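import numpy as np
import pytest

import eitzones as ez

TRUTH_KEYS = {
    "lung_ee": "lung_ee_true",
    "lung_tidal": "lung_tidal_true",
    "overinflated": "overinflated_true",
    "cyclic": "cyclic_true",
    "recruited": "recruited_true",
}


def dice_table(result, truth):
    """Dice overlap between analyzed masks and phantom ground truth, per step."""
    out = {}
    for step in result.steps:
        tm = truth.masks[step.peep_cmH2O]
        out[step.peep_cmH2O] = {
            pred: ez.dice(getattr(step.masks, pred), tm[tkey])
            for pred, tkey in TRUTH_KEYS.items()
        }
    return out


@pytest.fixture(scope="session")
def phantom_zero():
    """Default mixed phantom at zero noise, analyzed with default settings."""
    cfg = ez.PhantomConfig(noise_sd=0.0)
    sequences, truth = ez.generate(cfg)
    result = ez.analyze_trial(sequences)
    return cfg, sequences, truth, result


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default mixed phantom at noise SD = 10 % of the tidal amplitude."""
    cfg = ez.PhantomConfig(noise_sd=0.1 * ez.PhantomConfig().tidal_amplitude, seed=20160503)
    sequences, truth = ez.generate(cfg)
    result = ez.analyze_trial(sequences)
    return cfg, sequences, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_sequence(rng):
    """Small random frame sequence for I/O and rebase tests."""
    return ez.FrameSequence(
        frames=rng.normal(size=(5, 2, 2)),
        sample_rate_hz=40.0,
        subject_id="pig-01",
        peep_cmH2O=6.0,
    )
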