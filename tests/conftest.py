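import numpy as np
import pytest

from microstates import (CohortSpec, average_reference, make_layout,
                         make_template_maps, render_eeg, simulate_cohort,
                         simulate_label_sequence)


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def templates(layout):
    return make_template_maps(layout, seed=1)


@pytest.fixture(scope="session")
def rendered_subject(templates):
    """One 30-s alpha-dominant subject at snr 4, average-referenced."""
    seq = simulate_label_sequence([80.0] * 4, [1.0] * 4, 256.0, 256 * 30, seed=3)
    rec = render_eeg(seq, templates, snr=4.0, seed=3)
    return average_reference(rec), seq


@pytest.fixture(scope="session")
def noiseless_subject(templates):
    seq = simulate_label_sequence([80.0] * 4, [1.0] * 4, 256.0, 256 * 20, seed=11)
    rec = render_eeg(seq, templates, snr=np.inf, seed=11)
    return average_reference(rec), seq


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 subjects, 30 s each, with a strong class-D duration reduction."""
    spec = CohortSpec(groups=(("control", 4), ("disease", 4)), duration_s=30.0,
                      seed=5, group_scales={"disease": {"duration": {"D": 0.6}}})
    return simulate_cohort(spec)
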