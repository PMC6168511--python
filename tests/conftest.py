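import numpy as np
import pytest

from vocalsig import synth


@pytest.fixture(scope="session")
def fs() -> int:
    return 44100


@pytest.fixture(scope="session")
def flat600_template() -> synth.CallTypeTemplate:
    """Purely harmonic call type with a flat 600 Hz fundamental."""
    return synth.CallTypeTemplate(
        "X", 600.0, ("flat", 0.0), (2400.0, 4000.0, 6200.0), 0.15, 0.05, 1.0, 0.0
    )


@pytest.fixture(scope="session")
def zero_profile(flat600_template) -> synth.IndividualProfile:
    labels = [flat600_template.label, "DC", "Te", "Ws"]
    return synth.IndividualProfile("z00", {lb: np.zeros(synth.N_OFFSET) for lb in labels})


@pytest.fixture(scope="session")
def make_call():
    """Factory wrapping a bare waveform into an annotated CallRecord."""

    def _make(waveform: np.ndarray, fs: int = 44100, **ids) -> synth.CallRecord:
        return synth.CallRecord(
            ids.get("vocalizer_id", "v00"),
            ids.get("call_type", "T"),
            ids.get("rendition_id", "r000"),
            waveform,
            fs,
        )

    return _make


@pytest.fixture(scope="session")
def strong_signature_features():
    """Features for 3 well-separated vocalizers, one call type, 20 renditions."""
    from vocalsig import features

    cfg = synth.SignatureConfig(
        n_individuals=3, renditions_per_type=20,
        sigma_between=4.0, sigma_within=0.5, seed=5,
    )
    calls = synth.generate_calls(cfg, synth.default_templates(("DC",)))
    return features.extract_paf_table(calls)
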