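import numpy as np
import pytest

from epimix.annotation_io import DEFAULT_MARKS, MarkTrackSet


def dense_to_pairs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert a per-bp boolean array to sorted (starts, ends) interval arrays."""
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate([[0], starts])
    if mask.size and mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return starts.astype(np.int64), ends.astype(np.int64)


def random_trackset(genome, rng, density=0.3, block=50):
    """A random MarkTrackSet plus the dense per-mark boolean oracle arrays.

    Marks are drawn block-wise so intervals have realistic lengths; the dense
    arrays are the ground truth the interval representation must reproduce.
    """
    coverage = {m: {} for m in DEFAULT_MARKS}
    dense = {m: {} for m in DEFAULT_MARKS}
    for chrom, length in genome.items():
        n_blocks = length // block + 1
        for mark in DEFAULT_MARKS:
            blocks = rng.random(n_blocks) < density
            mask = np.repeat(blocks, block)[:length]
            dense[mark][chrom] = mask
            if mask.any():
                coverage[mark][chrom] = dense_to_pairs(mask)
    ts = MarkTrackSet("toy", DEFAULT_MARKS, coverage, dict(genome))
    return ts, dense


def dense_mark_matrix(dense, chrom, length):
    """(length, 8) binary matrix from the dense per-mark oracle arrays."""
    return np.column_stack(
        [dense[m][chrom].astype(np.int8) for m in DEFAULT_MARKS]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    return {"chrA": 10_000, "chrB": 5_000}


@pytest.fixture
def toy_trackset(toy_genome, rng):
    return random_trackset(toy_genome, rng)
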