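"""Internal helpers for unordered gene pairs and condensed-triangle indexing.

A gene pair is always represented as a canonical tuple ``(g1, g2)`` with
``g1 < g2`` lexicographically.  Condensed indexing follows the
``scipy.spatial.distance.squareform`` convention: for ``n`` items the pair
``(i, j)`` with ``i < j`` sits at ``i*(2n - i - 1)//2 + (j - i - 1)``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .errors import ValidationError

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair as a sorted tuple; self-pairs are rejected."""
    if a == b:
        raise ValidationError(f"self-pair ({a}, {b}) is not a valid gene pair")
    return (a, b) if a < b else (b, a)


def canonicalize_pairs(pairs: Iterable[tuple[str, str]]) -> set[Pair]:
    return {canonical_pair(a, b) for a, b in pairs}


def row_offsets(i: np.ndarray | int, n: int):
    """Condensed index at which row ``i`` of the upper triangle starts."""
    return i * (2 * n - i - 1) // 2


def condensed_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Condensed index of pairs ``(i, j)`` with ``i < j`` among ``n`` items."""
    return row_offsets(i, n) + (j - i - 1)


def condensed_to_ij(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`condensed_index` (vectorised, exact)."""
    k = np.asarray(k, dtype=np.int64)
    # float solve of the row quadratic, then an integer fix-up for safety
    i = np.floor((2 * n - 1 - np.sqrt((2.0 * n - 1) ** 2 - 8.0 * k)) / 2).astype(np.int64)
    i = np.clip(i, 0, n - 2)
    for _ in range(2):
        i = np.where(row_offsets(i, n) > k, i - 1, i)
        i = np.where(row_offsets(i + 1, n) <= k, i + 1, i)
    j = k - row_offsets(i, n) + i + 1
    return i, j


def n_choose_2(n: int) -> int:
    return n * (n - 1) // 2
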