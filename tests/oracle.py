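"""Independent brute-force oracle for local profile alignment scores.

Enumerates every legal local state path explicitly and aggregates by max
(viterbi) or log-sum-exp (forward).  Paths enter at any match state at any
target position, move through match/insert/delete states, and exit from a
match state; inserts emit at background (log-odds 0), deletes emit nothing.
Exponential in size — only usable for profiles with a handful of columns —
and deliberately independent of the dynamic-programming implementation.
"""

from __future__ import annotations

import math

import numpy as np

from orthocomplete.profile import TRANSITIONS


def enumerate_path_scores(em: np.ndarray, x: np.ndarray) -> list[float]:
    """Scores (nats) of every legal local path of the profile against x."""
    M = em.shape[0]
    L = x.shape[0]
    t = TRANSITIONS
    scores: list[float] = []

    def extend(state: str, k: int, i: int, acc: float) -> None:
        # state at column k, having just consumed target up to index i (M/I)
        # or not consumed (D); i is the index of the next unread residue
        if state == "M":
            scores.append(acc)  # exit is free from any match state
        # transitions out
        if state == "M":
            if k + 1 < M and i < L:
                extend("M", k + 1, i + 1, acc + t["mm"] + em[k + 1, x[i]])
            if i < L:
                extend("I", k, i + 1, acc + t["mi"])
            if k + 1 < M:
                extend("D", k + 1, i, acc + t["md"])
        elif state == "I":
            if i < L:
                extend("I", k, i + 1, acc + t["ii"])
            if k + 1 < M and i < L:
                extend("M", k + 1, i + 1, acc + t["im"] + em[k + 1, x[i]])
        elif state == "D":
            if k + 1 < M:
                extend("D", k + 1, i, acc + t["dd"])
            if k + 1 < M and i < L:
                extend("M", k + 1, i + 1, acc + t["dm"] + em[k + 1, x[i]])

    for k0 in range(M):
        for i0 in range(L):
            extend("M", k0, i0 + 1, em[k0, x[i0]])
    return scores


def brute_force_bits(em: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(viterbi_bits, forward_bits) by exhaustive enumeration."""
    scores = enumerate_path_scores(em, x)
    vit = max(scores)
    fwd = vit + math.log(sum(math.exp(s - vit) for s in scores))
    return vit / math.log(2), fwd / math.log(2)
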