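"""Shared numerical helpers: seeding, z-scaling, interval overlap."""

from __future__ import annotations

import numpy as np

# Sub-stream indices for deriving independent generator streams from one
# root seed; regenerating one stage never perturbs another.
STREAMS = {
    "genome": 1,
    "timeseries": 2,
    "marks": 3,
    "population": 4,
    "genie3": 5,
    "activity": 6,
    "structure": 7,
    "kmeans": 8,
}


def derive_seed(root_seed: int, stream: str | int, index: int = 0) -> int:
    """Deterministically derive a sub-seed below 2**31 from a root seed."""
    stream_id = STREAMS[stream] if isinstance(stream, str) else int(stream)
    ss = np.random.SeedSequence([int(root_seed), stream_id, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(root_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, stream, index))


def zscale(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """z-score along an axis; zero-variance slices become all-zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=0, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of intersection of two half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from scipy.stats import false_discovery_control

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return false_discovery_control(pvals, method="bh")
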