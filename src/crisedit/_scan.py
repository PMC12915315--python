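"""Vectorized sliding-window mismatch scanning shared by guide screening and
self-target analysis. Bases compare by byte equality, so N matches only N."""

from __future__ import annotations

import numpy as np


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def window_mismatch_counts(arr: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``arr``.

    Returns a vector of length ``len(arr) - len(query) + 1`` (empty when the
    query is longer than the sequence).
    """
    n, k = arr.size, query.size
    m = n - k + 1
    if m <= 0:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(m, dtype=np.int32)
    for j in range(k):
        counts += arr[j : j + m] != query[j]
    return counts


def motif_start_mask(arr: np.ndarray, motif: np.ndarray) -> np.ndarray:
    """Boolean mask over window starts where ``motif`` matches exactly."""
    return window_mismatch_counts(arr, motif) == 0
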