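"""Read recruitment and length-normalized fractional abundance.

Virome reads are first decontaminated against a decoy database (exact 31-mer
screen: a read sharing at least half of its k-mers with a decoy is removed),
then recruited to the phage genome database with a deterministic exact-seed
ungapped mapper.  Ties are split fractionally across the tied genomes.  The
fractional abundance of genome i with recruited count c_i and length L_i is

    F_i = (c_i / L_i) / sum_j (c_j / L_j),

the reads-per-base share, so that fractions sum to one whenever any read is
recruited; a genome is "detected" when it recruits at least one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import revcomp


@dataclass
class RecruitmentResult:
    counts: dict[str, float]
    windows: dict[str, np.ndarray]  # mean per-base coverage per 100-bp window
    n_decontaminated: int
    n_unmapped: int
    n_skipped_short: int


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def build_decoy_index(decoys: dict[str, str], k: int = 31) -> set:
    idx = set()
    for seq in decoys.values():
        for km in _kmers(seq, k):
            idx.add(km)
        for km in _kmers(revcomp(seq), k):
            idx.add(km)
    return idx


def recruit_reads(
    reads: list[tuple[str, str]],
    genomes: dict[str, str],
    decoys: dict[str, str] | None = None,
    k: int = 31,
    circular: bool = False,
    min_identity: float = 0.9,
    window: int = 100,
) -> RecruitmentResult:
    """Assign reads to genomes by exact k-mer seeding + ungapped scoring.

    A read is removed at decontamination if >= 50% of its k-mers occur in the
    decoy set.  Surviving reads go to the genome(s) with the most matching
    bases at the best diagonal (ties split 1/t), provided at least
    ``min_identity`` of the read matches.  Circular genomes are matched
    across the origin.
    """
    decoy_idx = build_decoy_index(decoys, k) if decoys else set()

    gindex: dict[str, list[tuple[str, int, str]]] = {}
    arrays: dict[str, tuple[np.ndarray, int]] = {}
    ext: dict[str, str] = {}
    max_rl = max((len(s) for _, s in reads), default=0)
    for gid, seq in genomes.items():
        work = seq + seq[: max_rl - 1] if circular and max_rl > 1 else seq
        ext[gid] = work
        arrays[gid] = (np.frombuffer(work.encode(), dtype=np.uint8), len(seq))
        for i in range(0, len(work) - k + 1):
            gindex.setdefault(work[i : i + k], []).append((gid, i, "+"))

    counts = {gid: 0.0 for gid in genomes}
    depth = {gid: np.zeros(len(seq)) for gid, seq in genomes.items()}
    n_deco = n_unmapped = n_short = 0

    for _, rseq in reads:
        if len(rseq) < k:
            n_short += 1
            continue
        if decoy_idx:
            kms = list(_kmers(rseq, k))
            if sum(km in decoy_idx for km in kms) >= 0.5 * len(kms):
                n_deco += 1
                continue
        best_score = 0
        best: list[tuple[str, int]] = []
        for strand, q in (("+", rseq), ("-", revcomp(rseq))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            cands = set()
            step = max(1, (len(q) - k) // 4) if len(q) > k else 1
            probe_positions = list(range(0, len(q) - k + 1, step))
            for i in probe_positions:
                for gid, gpos, _ in gindex.get(q[i : i + k], ()):
                    cands.add((gid, gpos - i))
            for gid, off in cands:
                garr, L = arrays[gid]
                if off < 0 or off + len(q) > len(garr):
                    continue
                score = int((garr[off : off + len(q)] == qa).sum())
                if score < min_identity * len(q):
                    continue
                if score > best_score:
                    best_score, best = score, [(gid, off)]
                elif score == best_score:
                    if (gid, off) not in best:
                        best.append((gid, off))
        if not best:
            n_unmapped += 1
            continue
        tied_genomes = sorted({gid for gid, _ in best})
        w = 1.0 / len(tied_genomes)
        placed = set()
        for gid, off in best:
            if gid in placed:
                continue
            placed.add(gid)
            counts[gid] += w
            _, L = arrays[gid]
            rl = len(rseq)
            for pos in range(off, off + rl):
                depth[gid][pos % L] += w

    windows = {}
    for gid, dv in depth.items():
        L = len(dv)
        nwin = int(np.ceil(L / window))
        padded = np.zeros(nwin * window)
        padded[:L] = dv
        wv = padded.reshape(nwin, window).sum(axis=1)
        sizes = np.full(nwin, window, dtype=float)
        if L % window:
            sizes[-1] = L % window
        windows[gid] = wv / sizes
    return RecruitmentResult(counts, windows, n_deco, n_unmapped, n_short)


def fractional_abundance(
    counts: dict[str, float], lengths: dict[str, int]
) -> pd.DataFrame:
    """AbundanceTable: per-genome count, length-normalized fraction, detection."""
    rows = []
    for gid in sorted(counts):
        c = counts[gid]
        if c < 0:
            raise ValueError(f"negative count for {gid}")
        L = lengths[gid]
        if L <= 0:
            raise ValueError(f"non-positive length for {gid}")
        rows.append((gid, c, L))
    total = sum(c / L for _, c, L in rows)
    recs = []
    for gid, c, L in rows:
        f = (c / L) / total if total > 0 else 0.0
        recs.append(
            {"genome": gid, "count": c, "length": L, "fraction": f,
             "detected": c >= 1.0 - 1e-9}
        )
    return pd.DataFrame(recs)


def counts_from_sam(path, genomes: dict[str, str]) -> dict[str, float]:
    """Recruited-read counts from an external mapper's SAM file (primary
    alignments only)."""
    import pysam

    counts = {gid: 0.0 for gid in genomes}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name in counts:
                counts[rec.reference_name] += 1.0
    return counts
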