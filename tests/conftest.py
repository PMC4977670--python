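import numpy as np
import pytest

from promscan import BackgroundModel, PositionMatrix


@pytest.fixture
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


def make_matrix(motif_id: str, probs, **kw) -> PositionMatrix:
    return PositionMatrix(motif_id, np.asarray(probs, dtype=float), **kw)


def random_matrix(rng: np.random.Generator, length: int, motif_id: str = "rand", **kw) -> PositionMatrix:
    return PositionMatrix(motif_id, rng.dirichlet(np.ones(4), size=length), **kw)


def sharp_matrix(motif_id: str, consensus_idx, dominant: float = 0.94, **kw) -> PositionMatrix:
    """High-information matrix with one dominant base per column."""
    L = len(consensus_idx)
    probs = np.full((L, 4), (1.0 - dominant) / 3.0)
    probs[np.arange(L), consensus_idx] = dominant
    return PositionMatrix(motif_id, probs, **kw)
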