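import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120673)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_sim(tmp_path):
    """A small simulated dataset shared by integration-style tests:
    800-base transcript, ~40x raw depth, default quality model."""
    from transwalk.simulate import SimParams, simulate_reads, simulate_transcript

    p = SimParams(transcript_length=800, n_fragments=160, seed=11)
    transcript, truth = simulate_transcript(p)
    r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
    truth = simulate_reads(transcript, p, r1, r2, truth)
    return {"params": p, "transcript": transcript, "truth": truth, "r1": r1, "r2": r2}
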