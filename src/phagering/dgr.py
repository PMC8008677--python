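"""Diversity-generating retroelement (DGR) detection and the adenine-bias test.

A DGR copies a template repeat (TR) onto a variable repeat (VR) through an
error-prone reverse transcriptase (RT) that misincorporates specifically at
template adenines.  Detection is two-staged: near-exact repeat pairs are
sought inside a 10-kb window centered on the annotated RT, then each template
repeat is re-searched genome-wide (ungapped, effectively all diagonals given
a word size of 4) at >= 75% identity and >= 50% query coverage, on both
strands.  The hallmark of an active DGR is that TR->VR substitutions are
confined to TR adenine positions; this is formalized as a one-sided binomial
test on the partition of substituted columns by template base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .util import longest_segment_at_identity, revcomp


@dataclass(frozen=True)
class RepeatPair:
    genome_id: str
    tr_start: int
    tr_end: int
    vr_start: int
    vr_end: int
    vr_strand: str  # strand of the VR copy relative to the TR
    identity: float  # percent over the aligned (ungapped) span
    within_10kb_window: bool


@dataclass(frozen=True)
class DgrReport:
    genome_id: str
    n_aligned: int
    n_a_positions: int
    n_a_substituted: int
    n_nona_substituted: int
    p_value: float
    hypervariable: bool


def _self_repeats(region: str, min_len: int, min_id: float, seed_k: int = 12):
    """Ungapped repeat pairs within ``region`` (forward strand), as
    ((s1, e1), (s2, e2), identity) with s1 < s2, via k-mer anchored diagonals."""
    n = len(region)
    index: dict[str, list[int]] = {}
    for i in range(n - seed_k + 1):
        index.setdefault(region[i : i + seed_k], []).append(i)
    diags = set()
    for positions in index.values():
        for i in positions:
            for j in positions:
                if j - i >= min_len // 2:  # distinct occurrences only
                    diags.add(j - i)
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    pairs = []
    for d in sorted(diags):
        m = (arr[: n - d] == arr[d:]).astype(np.int8)
        seg = longest_segment_at_identity(m, min_id / 100.0)
        if seg is None or seg[1] - seg[0] < min_len:
            continue
        s, e = seg
        ident = 100.0 * float(m[s:e].mean())
        pairs.append(((s, e), (s + d, e + d), ident))
    return pairs


def _query_genome(
    tr: str, genome: str, min_id: float, min_cov: float
) -> list[tuple[int, int, str, float]]:
    """Ungapped hits of TR against the genome on both strands, >= min_id %
    identity over a segment covering >= min_cov % of the TR.

    With a word size of 4 essentially every diagonal carries a seed, so all
    offsets are evaluated; a window-sum prefilter keeps this fast.
    """
    m = len(tr)
    min_seg = int(np.ceil(m * min_cov / 100.0))
    min_matches = int(np.floor(min_seg * min_id / 100.0))
    tr_arr = np.frombuffer(tr.encode(), dtype=np.uint8)
    hits = []
    for strand, g in (("+", genome), ("-", revcomp(genome))):
        garr = np.frombuffer(g.encode(), dtype=np.uint8)
        L = len(garr)
        if L < min_seg:
            continue
        win = np.lib.stride_tricks.sliding_window_view(garr, m) if L >= m else None
        if win is not None:
            eq = win == tr_arr  # (L - m + 1, m)
            totals = eq.sum(axis=1)
            cand = np.nonzero(totals >= min_matches)[0]
            for o in cand:
                seg = longest_segment_at_identity(eq[o].astype(np.int8), min_id / 100.0)
                if seg is None or seg[1] - seg[0] < min_seg:
                    continue
                s, e = seg
                ident = 100.0 * float(eq[o, s:e].mean())
                gs, ge = int(o + s), int(o + e)
                if strand == "-":
                    gs, ge = L - ge, L - gs
                hits.append((gs, ge, strand, ident))
    return hits


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def find_repeat_pairs(
    genome: str,
    rt_locus: tuple[int, int],
    genome_id: str = "genome",
    window: int = 10_000,
    stage1_min_len: int = 80,
    stage1_min_id: float = 85.0,
    stage2_min_id: float = 75.0,
    stage2_min_cov: float = 50.0,
) -> list[RepeatPair]:
    """Two-stage TR/VR discovery around an annotated reverse transcriptase.

    Stage 1 finds near-exact repeat pairs (>= stage1_min_len bp at
    >= stage1_min_id % identity) inside a ``window`` centered on the RT; the
    RT-proximal interval of each pair is taken as the template repeat.
    Stage 2 re-searches each template repeat genome-wide at the relaxed
    thresholds, picking up variable repeats outside the window.
    """
    if rt_locus is None:
        raise ValueError("rt_locus is required (supply an RT annotation)")
    rt_center = (rt_locus[0] + rt_locus[1]) // 2
    w_start = max(0, rt_center - window // 2)
    w_end = min(len(genome), rt_center + window // 2)
    region = genome[w_start:w_end]

    pairs: list[RepeatPair] = []
    trs: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2), ident in _self_repeats(
        region, stage1_min_len, stage1_min_id
    ):
        i1 = (s1 + w_start, e1 + w_start)
        i2 = (s2 + w_start, e2 + w_start)
        if _overlaps(i1, i2):
            continue
        # TR = the RT-proximal interval
        c1 = abs((i1[0] + i1[1]) // 2 - rt_center)
        c2 = abs((i2[0] + i2[1]) // 2 - rt_center)
        tr, vr = (i1, i2) if c1 <= c2 else (i2, i1)
        if any(_overlaps(tr, t) for t in trs):
            continue
        trs.append(tr)
        pairs.append(
            RepeatPair(genome_id, tr[0], tr[1], vr[0], vr[1], "+", ident, True)
        )

    # stage 2: each TR as a genome-wide query
    for rp in list(pairs):
        tr_seq = genome[rp.tr_start : rp.tr_end]
        for gs, ge, strand, ident in _query_genome(
            tr_seq, genome, stage2_min_id, stage2_min_cov
        ):
            iv = (gs, ge)
            if _overlaps(iv, (rp.tr_start, rp.tr_end)):
                continue
            if any(_overlaps(iv, (p.vr_start, p.vr_end)) for p in pairs):
                continue
            within = rp.tr_start >= w_start and ge <= w_end and gs >= w_start
            pairs.append(
                RepeatPair(
                    rp.genome_id, rp.tr_start, rp.tr_end, gs, ge, strand, ident,
                    within and rp.within_10kb_window,
                )
            )
    return sorted(pairs, key=lambda p: (p.tr_start, p.vr_start))


def _align_ungapped(tr: str, vr: str) -> tuple[np.ndarray, np.ndarray]:
    """Best ungapped offset of VR against TR; returns (tr_index_array,
    vr_chars) for the aligned columns."""
    ta = np.frombuffer(tr.encode(), dtype=np.uint8)
    va = np.frombuffer(vr.encode(), dtype=np.uint8)
    if len(ta) == len(va):
        return np.arange(len(ta)), va
    short, lng = (va, ta) if len(va) < len(ta) else (ta, va)
    best, best_o = -1, 0
    for o in range(len(lng) - len(short) + 1):
        m = int((lng[o : o + len(short)] == short).sum())
        if m > best:
            best, best_o = m, o
    if len(va) < len(ta):
        return np.arange(best_o, best_o + len(va)), va
    return np.arange(len(ta)), va[best_o : best_o + len(ta)]


def adenine_bias_test(
    tr: str,
    vr_set: list[str],
    alpha: float = 0.01,
    min_a_substituted: int = 3,
    genome_id: str = "genome",
) -> DgrReport:
    """Test whether TR->VR substitutions are confined to template adenines.

    Each TR column counts as substituted once if any VR differs there.  Under
    the null that substituted columns fall on template positions at random,
    the number landing on adenines is Binomial(n_substituted, f_A) with f_A
    the adenine fraction of the aligned template; the reported p-value is the
    upper tail.  ``hypervariable`` additionally requires at least
    ``min_a_substituted`` substituted adenine sites.
    """
    tr = tr.upper()
    if not vr_set:
        raise ValueError("empty VR set")
    aligned_cols: set[int] = set()
    substituted: set[int] = set()
    for vr in vr_set:
        idx, v = _align_ungapped(tr, vr.upper())
        if len(idx) == 0:
            continue
        aligned_cols.update(int(i) for i in idx)
        t = np.frombuffer(tr.encode(), dtype=np.uint8)[idx]
        substituted.update(int(i) for i in idx[np.nonzero(t != v)[0]])
    if not aligned_cols:
        raise ValueError("TR and VRs share no aligned columns")
    cols = sorted(aligned_cols)
    is_a = {i for i in cols if tr[i] == "A"}
    n_a = len(is_a)
    n_a_sub = len(substituted & is_a)
    n_nona_sub = len(substituted - is_a)
    n_sub = n_a_sub + n_nona_sub
    f_a = n_a / len(cols)
    if n_sub == 0:
        p = 1.0
    else:
        p = float(stats.binom.sf(n_a_sub - 1, n_sub, f_a))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return DgrReport(
        genome_id, len(cols), n_a, n_a_sub, n_nona_sub, p,
        bool(p < alpha and n_a_sub >= min_a_substituted),
    )


def count_substituted_adenine_sites(msa: list[tuple[str, str]]) -> int:
    """Count template-adenine columns showing >= 1 substitution in an aligned
    TR/VR stack (TR first row, VRs below; gap-tolerant).

    This is the worked-example recount used on published TR/VR alignments.
    """
    if len(msa) < 2:
        raise ValueError("need a TR row plus at least one VR row")
    tr = msa[0][1].upper()
    count = 0
    for j, t in enumerate(tr):
        if t != "A":
            continue
        for _, vr in msa[1:]:
            v = vr[j].upper() if j < len(vr) else "-"
            if v not in ("-", ".", "N", t):
                count += 1
                break
    return count


def render_alignment(tr: str, vr_set: list[str], width: int = 60) -> str:
    """Text rendering of TR over VRs with substituted columns marked '*'."""
    rows = [("TR", tr.upper())] + [(f"VR{i+1}", v.upper()) for i, v in enumerate(vr_set)]
    n = max(len(s) for _, s in rows)
    marks = "".join(
        "*"
        if any(len(s) > j and s[j] != tr[j] for _, s in rows[1:] if j < len(tr))
        else " "
        for j in range(n)
    )
    out = []
    for off in range(0, n, width):
        for name, s in rows:
            out.append(f"{name:>6}  {s[off:off+width]}")
        out.append(f"{'':>6}  {marks[off:off+width]}")
        out.append("")
    return "\n".join(out)
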