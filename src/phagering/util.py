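"""Small sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random DNA of length n with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA))[rng.choice(4, size=n, p=p)])


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=n)])


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def z_array(s: str) -> np.ndarray:
    """Z-algorithm: z[i] = length of the longest common prefix of s and s[i:]."""
    n = len(s)
    z = np.zeros(n, dtype=np.int64)
    z[0] = n
    l = r = 0
    for i in range(1, n):
        if i < r:
            z[i] = min(r - i, z[i - l])
        while i + z[i] < n and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > r:
            l, r = i, i + z[i]
    return z


def longest_segment_at_identity(match: np.ndarray, min_frac: float):
    """Longest contiguous segment of a 0/1 match vector whose identity (mean)
    is >= min_frac and whose two endpoints are matches.

    Returns (start, end), half-open, or None.  Classic transform: with
    t = match - min_frac the condition becomes sum(t[start:end]) >= 0, i.e.
    pref[end] >= pref[start]; candidate starts form a strictly decreasing
    staircase of prefix values searchable by bisection.
    """
    m = np.asarray(match, dtype=np.int8)
    n = len(m)
    if n == 0:
        return None
    pref = np.concatenate([[0.0], np.cumsum(m - min_frac)])
    stack_idx: list[int] = []  # start indices, pref strictly decreasing
    stack_pref: list[float] = []
    best = None
    eps = 1e-9
    for e in range(1, n + 1):
        s = e - 1
        if m[s] == 1 and (not stack_pref or pref[s] < stack_pref[-1] - eps):
            stack_idx.append(s)
            stack_pref.append(pref[s])
        if m[e - 1] != 1:
            continue
        # leftmost stacked start with pref[start] <= pref[e]
        # stack_pref is decreasing; search reversed view
        lo, hi = 0, len(stack_idx)
        while lo < hi:
            mid = (lo + hi) // 2
            if stack_pref[mid] <= pref[e] + eps:
                hi = mid
            else:
                lo = mid + 1
        if lo < len(stack_idx) and stack_idx[lo] < e:
            if best is None or (e - stack_idx[lo]) > (best[1] - best[0]):
                best = (int(stack_idx[lo]), int(e))
    return best
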