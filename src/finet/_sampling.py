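"""Uniform sampling of unordered pairs from a protein universe.

Pairs are indexed lexicographically ((0,1), (0,2), ..., (m-2,m-1)) so a
pair can be drawn by drawing an integer rank, which keeps sampling O(n)
in the number of pairs requested rather than in the universe size.
"""

from __future__ import annotations

from typing import Optional, Sequence, Set, Tuple

import numpy as np

Pair = Tuple[str, str]


def unrank_pairs(ranks: np.ndarray, m: int) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized rank -> (i, j) with i < j, lexicographic pair order."""
    k = np.asarray(ranks, dtype=np.int64)
    disc = (2 * m - 1) ** 2 - 8 * k
    i = ((2 * m - 1) - np.sqrt(disc.astype(np.float64))) / 2
    i = np.floor(i).astype(np.int64)
    # guard against float round-off at block boundaries
    for _ in range(2):
        offset = i * m - i * (i + 1) // 2
        too_high = offset > k
        i[too_high] -= 1
        offset = i * m - i * (i + 1) // 2
        too_low = k - offset >= (m - 1 - i)
        i[too_low] += 1
    offset = i * m - i * (i + 1) // 2
    j = k - offset + i + 1
    return i, j


def sample_pair_ranks(
    total: int, n: int, rng: np.random.Generator,
    exclude: Optional[Set[int]] = None,
) -> np.ndarray:
    """n distinct ranks in [0, total) uniform without replacement."""
    exclude = exclude or set()
    avail = total - len(exclude)
    if n > avail:
        raise ValueError(
            f"requested {n} pairs but only {avail} are available"
        )
    if total <= 4 * (n + len(exclude)) or total < 1024:
        pool = np.setdiff1d(
            np.arange(total, dtype=np.int64),
            np.fromiter(exclude, dtype=np.int64, count=len(exclude)),
        )
        return rng.choice(pool, size=n, replace=False)
    chosen: Set[int] = set()
    while len(chosen) < n:
        need = n - len(chosen)
        for v in rng.integers(0, total, size=max(2 * need, 32)):
            v = int(v)
            if v not in exclude and v not in chosen:
                chosen.add(v)
                if len(chosen) == n:
                    break
    return np.fromiter(chosen, dtype=np.int64, count=n)


def pair_rank(i: int, j: int, m: int) -> int:
    """Inverse of :func:`unrank_pairs` for a single pair, i < j."""
    return i * m - i * (i + 1) // 2 + (j - i - 1)


def sample_pairs(
    universe: Sequence[str],
    n: int,
    rng: np.random.Generator,
    exclude_pairs: Optional[Set[Pair]] = None,
) -> Set[Pair]:
    """n distinct unordered pairs over the universe, uniform, excluding any
    pair in ``exclude_pairs``."""
    items = sorted(set(universe))
    m = len(items)
    total = m * (m - 1) // 2
    pos = {p: idx for idx, p in enumerate(items)}
    exclude_ranks: Set[int] = set()
    for a, b in exclude_pairs or ():
        ia, ib = pos.get(a), pos.get(b)
        if ia is None or ib is None:
            continue
        if ia > ib:
            ia, ib = ib, ia
        if ia != ib:
            exclude_ranks.add(pair_rank(ia, ib, m))
    ranks = sample_pair_ranks(total, n, rng, exclude=exclude_ranks)
    ii, jj = unrank_pairs(ranks, m)
    return {(items[a], items[b]) for a, b in zip(ii.tolist(), jj.tolist())}
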