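import numpy as np
import pytest

from memidr.io import TRANSMEM, FeatureInterval, ProteinRecord
from memidr.simulate import (
    DISORDERED_COMPOSITION,
    ORDERED_COMPOSITION,
    TM_COMPOSITION,
)


def sample_seq(rng: np.random.Generator, comp: dict, n: int) -> str:
    letters = list(comp)
    probs = np.array([comp[a] for a in letters])
    return "".join(rng.choice(letters, size=n, p=probs / probs.sum()))


def make_multipass_record(
    pid: str = "TMLIKE",
    n_tm: int = 8,
    loop_len: int = 25,
    tm_len: int = 21,
    nterm_tail: int = 0,
    cterm_tail: int = 100,
    seed: int = 0,
) -> ProteinRecord:
    """A multi-pass protein with a single disordered tail.

    Ordered loops between TM segments; a disorder-biased tail of
    ``cterm_tail`` (or ``nterm_tail``) residues at the respective
    terminus.  Only TRANSMEM features are attached, leaving orientation
    undetermined.
    """
    rng = np.random.default_rng(seed)
    parts, features = [], []
    pos = 1
    if nterm_tail:
        parts.append(sample_seq(rng, DISORDERED_COMPOSITION, nterm_tail))
        pos += nterm_tail
    else:
        parts.append(sample_seq(rng, ORDERED_COMPOSITION, loop_len))
        pos += loop_len
    for i in range(n_tm):
        parts.append(sample_seq(rng, TM_COMPOSITION, tm_len))
        features.append(FeatureInterval(TRANSMEM, pos, pos + tm_len - 1))
        pos += tm_len
        if i < n_tm - 1:
            parts.append(sample_seq(rng, ORDERED_COMPOSITION, loop_len))
            pos += loop_len
    if cterm_tail:
        parts.append(sample_seq(rng, DISORDERED_COMPOSITION, cterm_tail))
    else:
        parts.append(sample_seq(rng, ORDERED_COMPOSITION, loop_len))
    rec = ProteinRecord(id=pid, sequence="".join(parts))
    rec.attach_features(features)
    return rec


@pytest.fixture
def tmem117_like() -> ProteinRecord:
    """8 TM segments, ~100-residue disordered C-terminal tail."""
    return make_multipass_record(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
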