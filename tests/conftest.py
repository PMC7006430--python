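import numpy as np
import pytest

from dsrnacensus import SimConfig, generate_transcriptome
from dsrnacensus.synthetic import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic transcriptome with mixed planted duplexes."""
    config = SimConfig(
        n_genes=12,
        insertions_per_gene=1,
        p_inverted=0.5,
        divergence=0.02,
        repeat_length=(80, 250),
        rng_seed=11,
    )
    transcripts, planted = generate_transcriptome(config)
    return config, transcripts, planted


def make_planted_sequence(
    seed: int,
    *,
    length: int = 2000,
    arm_length: int = 100,
    inverted: bool = True,
    pos1: int = 400,
    pos2: int = 1200,
):
    """Deterministic background with one planted duplication.

    The bases flanking each arm are forced to mismatch their partner so the
    maximal local alignment is exactly the planted arm pair.
    """
    from dsrnacensus import revcomp

    rng = np.random.default_rng(seed)
    bg = list(random_sequence(length - 2 * arm_length, rng))
    arm = random_sequence(arm_length, rng)
    partner = revcomp(arm) if inverted else arm
    # Force the bases flanking the two insertion points to mismatch under
    # both orientations (A vs C same-strand, A vs comp(C)=G opposite-strand)
    # so extension cannot run past the planted arms.
    bg[pos1 - 1], bg[pos1] = "A", "A"
    bg[pos2 - 1], bg[pos2] = "C", "C"
    seq = (
        "".join(bg[:pos1])
        + arm
        + "".join(bg[pos1:pos2])
        + partner
        + "".join(bg[pos2:])
    )
    arm1 = (pos1, pos1 + arm_length)
    arm2 = (pos2 + arm_length, pos2 + 2 * arm_length)
    return seq, arm1, arm2
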