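"""Detection of "circular" contigs by terminal direct repeats.

Short-read assemblers emit a circular (or terminally redundant) genome as a
linear contig whose two ends carry an identical direct repeat, typically the
assembly k-mer size.  A contig whose first r bases equal its last r bases for
some r in a configured window (default 50-200 bp) is called circular; the
duplicated suffix is trimmed and the sequence is rotated to a canonical form
so that any two assemblies of the same circular genome compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .util import z_array

REASON_OK = "ok"
REASON_TOO_SHORT = "contig_shorter_than_2x_min_len"
REASON_NO_REPEAT = "no_terminal_repeat_in_window"
REASON_REPEAT_TOO_LONG = "terminal_repeat_exceeds_max_len"


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: non-ACGTN characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CircularityCall:
    contig_id: str
    is_circular: bool
    repeat_length: int | None
    canonical_seq: str | None
    reason: str


def terminal_repeat_lengths(seq: str) -> list[int]:
    """All r in [1, len//2] with seq[:r] == seq[-r:], N never matching."""
    n = len(seq)
    if n < 2:
        return []
    z = z_array(seq)
    out = []
    for r in range(1, n // 2 + 1):
        if z[n - r] >= r and "N" not in seq[:r]:
            out.append(r)
    return out


def least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm, O(n))."""
    if not s:
        return s
    t = s + s
    n = len(t)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = t[j]
        i = f[j - k - 1]
        while i != -1 and sj != t[k + i + 1]:
            if sj < t[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != t[k + i + 1]:
            if sj < t[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return t[k:k + len(s)]


def find_terminal_repeat(
    contig: Contig, min_len: int = 50, max_len: int = 200
) -> CircularityCall:
    """Report the longest terminal direct repeat within [min_len, max_len].

    Repeats longer than max_len do not qualify (they fall outside the
    assembler-artifact window) and are flagged with a distinct reason code.
    The match is exact; N never matches.
    """
    if not 0 < min_len <= max_len:
        raise ValueError("require 0 < min_len <= max_len")
    n = len(contig.seq)
    if n < 2 * min_len:
        return CircularityCall(contig.id, False, None, None, REASON_TOO_SHORT)
    lengths = terminal_repeat_lengths(contig.seq)
    in_window = [r for r in lengths if min_len <= r <= max_len]
    if in_window:
        r = max(in_window)
        trimmed = contig.seq[: n - r]
        return CircularityCall(contig.id, True, r, least_rotation(trimmed), REASON_OK)
    if any(r > max_len for r in lengths):
        return CircularityCall(contig.id, False, None, None, REASON_REPEAT_TOO_LONG)
    return CircularityCall(contig.id, False, None, None, REASON_NO_REPEAT)


def canonicalize(call: CircularityCall) -> str:
    """Canonical sequence of a circular contig (duplicated suffix removed,
    lexicographically least rotation)."""
    if not call.is_circular or call.canonical_seq is None:
        raise ValueError(f"contig {call.contig_id} is not circular ({call.reason})")
    return call.canonical_seq


def screen_contigs(
    contigs: list[Contig], min_len: int = 50, max_len: int = 200
) -> list[CircularityCall]:
    return [find_terminal_repeat(c, min_len, max_len) for c in contigs]
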