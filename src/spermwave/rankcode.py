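"""Rank-order binary coding of circular sequences and the D_m dissimilarity.

A real circular sequence is binarized by its rise/fall pattern (bit n is 1
iff the sequence strictly rises at step n, with the circular predecessor used
at the seam).  Sliding m-bit windows of the binary code, wrapping around the
seam, are read as integer words; their occurrence counts give a probability
and a frequency rank per word.  Because both the binarization and the windows
are circular, the resulting profile is exactly invariant under circular
shifts of the source sequence — this start-point independence is the reason
for encoding waveforms this way — and invariant under positive scaling.

Profiles are compared with D_m, a rank-difference dissimilarity weighted by
the joint word probabilities and normalized into [0, 1], and with the plain
(unnormalized) rank-difference sum whose per-model average is the dARD
statistic used by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankCode",
    "RankProfile",
    "ModelSet",
    "rank_binarize",
    "word_histogram",
    "dm_distance",
    "rank_difference_sum",
    "pairwise_dm",
    "select_representatives",
    "average_rank_difference",
]


@dataclass(frozen=True)
class RankCode:
    """Circular binary rise/fall code of a real sequence."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class RankProfile:
    """Word histogram of an m-bit sliding-window scan of a rank code.

    ``counts[w]`` is the number of windows reading as word ``w``; ``probs``
    normalizes counts to sum 1; ``ranks`` assigns 1 to the most frequent word,
    breaking count ties by ascending word value, and is a permutation of
    ``1 .. 2**m``.
    """

    m: int
    counts: np.ndarray
    probs: np.ndarray = field(repr=False, default=None)
    ranks: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if len(counts) != 2**self.m:
            raise ValueError(f"counts must have 2**m = {2**self.m} entries")
        if self.probs is None:
            total = counts.sum()
            object.__setattr__(self, "probs", counts / total if total else counts.astype(float))
        if self.ranks is None:
            order = np.lexsort((np.arange(len(counts)), -counts))
            ranks = np.empty(len(counts), dtype=int)
            ranks[order] = np.arange(1, len(counts) + 1)
            object.__setattr__(self, "ranks", ranks)


@dataclass(frozen=True)
class ModelSet:
    """The representative ("model") profiles of one class."""

    profiles: tuple[RankProfile, ...]
    label: str
    indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.profiles) < 1:
            raise ValueError("a model set needs at least one profile")

    @property
    def size(self) -> int:
        return len(self.profiles)


def rank_binarize(x: np.ndarray) -> RankCode:
    """Binarize a circular sequence: bit n is 1 iff ``x[n] > x[n-1]``.

    The predecessor of the first element is the last element (circular
    closure); ties map to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    return RankCode(bits=(x > np.roll(x, 1)).astype(np.uint8))


def word_histogram(code: RankCode, m: int) -> RankProfile:
    """Histogram of all ``len(code)`` circular m-bit windows, stride 1.

    Window bits are read most-significant-first in sequence order.
    """
    if not 1 <= m <= 16:
        raise ValueError("m must lie in [1, 16]")
    bits = np.asarray(code.bits, dtype=np.int64)
    L = len(bits)
    if L < m:
        raise ValueError(f"code length {L} shorter than window width {m}")
    idx = (np.arange(L)[:, None] + np.arange(m)[None, :]) % L
    weights = 1 << np.arange(m - 1, -1, -1)
    words = bits[idx] @ weights
    counts = np.bincount(words, minlength=2**m)
    return RankProfile(m=m, counts=counts)


def dm_distance(a: RankProfile, b: RankProfile) -> float:
    """The normalized rank-difference dissimilarity D_m in [0, 1].

    ``sum |R1-R2| p1 p2 / ((2**m - 1) sum p1 p2)``.  When the supports are
    disjoint the expression is 0/0 and is defined as 1.0 (maximal
    dissimilarity).
    """
    if a.m != b.m:
        raise ValueError("profiles must share the same word width m")
    joint = a.probs * b.probs
    norm = joint.sum()
    if norm == 0:
        return 1.0
    return float(
        (np.abs(a.ranks - b.ranks) * joint).sum() / ((2**a.m - 1) * norm)
    )


def rank_difference_sum(a: RankProfile, b: RankProfile) -> float:
    """Unnormalized ``sum |R1 - R2|`` over words observed in either profile."""
    if a.m != b.m:
        raise ValueError("profiles must share the same word width m")
    support = (a.probs + b.probs) > 0
    return float(np.abs(a.ranks - b.ranks)[support].sum())


def pairwise_dm(profiles: list[RankProfile]) -> np.ndarray:
    """Symmetric matrix of D_m distances between all profile pairs."""
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dm_distance(profiles[i], profiles[j])
    return out


def select_representatives(
    profiles: list[RankProfile],
    k: int,
    label: str = "",
    dm: np.ndarray | None = None,
) -> ModelSet:
    """Pick the ``k`` profiles with the smallest total D_m to all others.

    Ties break by input order; selected profiles are returned in input order.
    A precomputed pairwise D_m matrix may be passed to avoid recomputation.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must not be empty")
    if not 1 <= k <= len(profiles):
        raise ValueError("k must lie in [1, len(profiles)]")
    if dm is None:
        dm = pairwise_dm(profiles)
    totals = dm.sum(axis=1)
    chosen = sorted(np.argsort(totals, kind="stable")[:k])
    return ModelSet(
        profiles=tuple(profiles[i] for i in chosen),
        label=label,
        indices=tuple(int(i) for i in chosen),
    )


def average_rank_difference(test: RankProfile, models: ModelSet) -> float:
    """dARD: mean rank-difference sum from ``test`` to each model profile."""
    sums = [rank_difference_sum(test, p) for p in models.profiles]
    return float(np.mean(sums))
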