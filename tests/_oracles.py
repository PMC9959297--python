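"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the Smith-Waterman scorer
is a plain dynamic-programming implementation over numpy rows, used to verify
the package's alignment-based segment assignment.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def sw_score(read: str, seg: str) -> float:
    """Textbook O(n*m) local-alignment score (linear gap penalty)."""
    r = np.frombuffer(read.encode(), dtype="S1")
    s = np.frombuffer(seg.encode(), dtype="S1")
    m = len(s)
    prev = np.zeros(m + 1)
    best = 0.0
    idx2 = 2.0 * np.arange(m)
    for i in range(len(r)):
        sub = np.where(s == r[i], MATCH, MISMATCH)
        t = np.maximum(0.0, np.maximum(prev[:m] + sub, prev[1:] + GAP))
        # close horizontal gap chains: cur[j] = max_{k<=j} t[k] - 2*(j-k)
        cur = np.maximum.accumulate(t + idx2) - idx2
        best = max(best, float(cur.max()))
        prev = np.concatenate(([0.0], cur))
    return best


def sw_scores_batch(read: str, segs: list[str]) -> np.ndarray:
    """sw_score against many equal-length segments at once."""
    r = np.frombuffer(read.encode(), dtype="S1")
    S = np.vstack([np.frombuffer(s.encode(), dtype="S1") for s in segs])
    k, m = S.shape
    prev = np.zeros((k, m + 1))
    best = np.zeros(k)
    idx2 = 2.0 * np.arange(m)
    for i in range(len(r)):
        sub = np.where(S == r[i], MATCH, MISMATCH)
        t = np.maximum(0.0, np.maximum(prev[:, :m] + sub, prev[:, 1:] + GAP))
        cur = np.maximum.accumulate(t + idx2, axis=1) - idx2
        best = np.maximum(best, cur.max(axis=1))
        prev = np.concatenate((np.zeros((k, 1)), cur), axis=1)
    return best


def oracle_best(read: str, segments) -> tuple[float, str]:
    """Best (score, gene) over candidate segments; ties -> smaller name."""
    by_len: dict[int, list] = {}
    for seg in segments:
        by_len.setdefault(len(seg.sequence), []).append(seg)
    best: tuple[float, str] | None = None
    for _ln, group in by_len.items():
        scores = sw_scores_batch(read, [s.sequence for s in group])
        for seg, sc in zip(group, scores):
            cand = (float(sc), seg.name)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    assert best is not None
    return best
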