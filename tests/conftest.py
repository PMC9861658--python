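import numpy as np
import pytest

from fedsepsis import features, synth


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient seeded cohort with planted ground truth."""
    config = synth.SynthConfig(n_patients=200, seed=7)
    events, truth = synth.generate_cohort(config)
    return config, events, truth


def make_grid(values, mask=None, label=False, episode_id="e0", onset_window=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values).astype(int)
    return features.WindowGrid(
        episode_id=episode_id,
        channels=tuple(f"c{j}" for j in range(values.shape[1])),
        values=values,
        mask=mask,
        label=label,
        onset_window=onset_window,
    )
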