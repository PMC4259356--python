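"""Independent brute-force oracles the fast implementations are checked against.

These deliberately use different mechanisms (Python string sets, direct
sliding-window comparison, exhaustive enumeration) from the packed-integer
code paths under test.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_longest_match(probe: str, transcripts: Mapping[str, str], both_strands: bool = True) -> int:
    """Longest substring of probe (or its reverse complement) present in any
    transcript, by descending-length substring sets."""
    queries = [probe, revcomp(probe)] if both_strands else [probe]
    for k in range(len(probe), 0, -1):
        subs = {q[i : i + k] for q in queries for i in range(len(q) - k + 1)}
        for t in transcripts.values():
            text = {t[i : i + k] for i in range(len(t) - k + 1)}
            if subs & text:
                return k
    return 0


def brute_best_identity(probe: str, transcripts: Mapping[str, str], both_strands: bool = True) -> float:
    """Best full-length ungapped identity at any offset in any transcript."""
    best = 0
    enc = {c: i for i, c in enumerate("ACGTN")}
    queries = [probe, revcomp(probe)] if both_strands else [probe]
    p_arrs = [np.array([enc[c] for c in q]) for q in queries]
    L = len(probe)
    for t in transcripts.values():
        if len(t) < L:
            continue
        t_arr = np.array([enc[c] for c in t])
        windows = np.lib.stride_tricks.sliding_window_view(t_arr, L)
        valid = (windows < 4).all(axis=1)
        if not valid.any():
            continue
        for p in p_arrs:
            matches = (windows[valid] == p).sum(axis=1).max()
            best = max(best, int(matches))
    return best / L


def brute_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def brute_motif_hits(seq: str, log_odds: np.ndarray, threshold: float) -> int:
    """Count windows on both strands scoring >= threshold, python loop."""
    enc = {c: i for i, c in enumerate("ACGTN")}
    w = log_odds.shape[0]
    total = 0
    for s in (seq, revcomp_n(seq)):
        for i in range(len(s) - w + 1):
            window = s[i : i + w]
            if "N" in window:
                continue
            score = sum(log_odds[j, enc[c]] for j, c in enumerate(window))
            if score >= threshold - 1e-12:
                total += 1
    return total


_COMP_N = str.maketrans("ACGTN", "TGCAN")


def revcomp_n(seq: str) -> str:
    return seq.translate(_COMP_N)[::-1]
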