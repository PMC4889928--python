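import numpy as np
import pytest

from apomut.shm import CloneObservation, Reference
from apomut.simulator import SimConfig


def make_reference(rng: np.random.Generator, length: int = 300) -> Reference:
    """Random reference with a CDR3-like identifier window at the 3' end."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Reference(
        id="JH4_synth",
        sequence=seq,
        analysis_window=(0, length),
        cdr3_window=(length - 12, length),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def reference(rng):
    return make_reference(rng)


@pytest.fixture
def balanced_reference():
    """Equal top/bottom C content in identical contexts (ACGT repeats have
    each C preceded by A and each G preceded by C, i.e. bottom-strand C
    preceded by G... use a palindromic repeat for exact strand symmetry)."""
    # reverse complement of ACGT is ACGT: the repeat is its own reverse
    # complement, so top and bottom C site sets are context-identical
    return Reference(id="pal", sequence="ACGT" * 50)


@pytest.fixture
def base_config():
    return SimConfig(
        deamination_rate=0.02,
        p_ap=0.7,
        p_reprime=0.5,
        leading_template_strand="top",
        n_clones=100,
        seed=1,
    )


def clones_from_sequences(sequences, sample_id="m1", prefix="c"):
    return [
        CloneObservation(clone_id=f"{prefix}{i:03d}", sample_id=sample_id, sequence=s)
        for i, s in enumerate(sequences)
    ]
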