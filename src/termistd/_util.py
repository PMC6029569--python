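"""Small shared helpers: complement tables, k-mer indexing, RNG plumbing."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer of ``seq`` (all occurrences, ascending)."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    """k-mer -> position, restricted to k-mers occurring exactly once."""
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


def circular_rotate(seq: str, origin: int) -> str:
    """Rotate so that position ``origin`` becomes position 0."""
    origin %= len(seq)
    return seq[origin:] + seq[:origin]


def longest_increasing_subsequence_length(values) -> int:
    """O(n log n) LIS length (strictly increasing)."""
    import bisect

    tails: list = []
    for v in values:
        i = bisect.bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)
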