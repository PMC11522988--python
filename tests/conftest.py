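import numpy as np
import pytest

from rhotic.synth import SpeakerProfile, SynthSpec, generate_corpus, vt_scale


def make_speaker(age=9.0, sex="M", cohort="RSSD", skill=0.5, speaker_id="spkT"):
    return SpeakerProfile(
        speaker_id=speaker_id,
        age_years=age,
        sex=sex,
        cohort=cohort,
        vt_scale=vt_scale(age, sex),
        rhotic_skill=skill,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A compact mixed corpus reused by read-only tests."""
    spec = SynthSpec(
        n_speakers=10,
        utterances_per_speaker=24,
        prop_typical=0.3,
        rssd_skill=0.5,
        age_range=(7.0, 17.0),
        seed=42,
    )
    return generate_corpus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
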