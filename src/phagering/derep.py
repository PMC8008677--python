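"""Genome dereplication and protein clustering.

Genomes are dereplicated greedily at 95% average nucleotide identity (ANI)
over 80% of the (shorter) genome length; proteins are clustered greedily at
an identity/coverage threshold (95%/50% for the non-redundant protein set,
50% identity for marker clustering).  ANI is estimated by shared-k-mer
anchoring of syntenic blocks followed by direct base comparison, which is
exact for the substitution-divergence regime this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .util import revcomp


@dataclass(frozen=True)
class AniEstimate:
    id_a: str
    id_b: str
    ani: float  # percent identity over aligned blocks
    aligned_fraction: float  # percent of the shorter genome covered


@dataclass(frozen=True)
class GenomeCluster:
    representative: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class ProteinCluster:
    representative: str
    members: tuple[str, ...]
    identity_threshold: float
    coverage_threshold: float


def _anchor_blocks(q: str, r: str, k: int, merge_gap: int):
    """Syntenic blocks between q and r: exact shared k-mers grouped by
    diagonal, merged when separated by <= merge_gap."""
    index: dict[str, list[int]] = {}
    for j in range(len(r) - k + 1):
        index.setdefault(r[j : j + k], []).append(j)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        for j in index.get(q[i : i + k], ()):
            by_diag.setdefault(i - j, []).append(i)
    blocks = []  # (q_start, q_end, diag)
    for d, positions in by_diag.items():
        positions.sort()
        s = e = positions[0]
        for i in positions[1:]:
            if i <= e + k + merge_gap:
                e = i
            else:
                blocks.append((s, e + k, d))
                s = e = i
        blocks.append((s, e + k, d))
    return blocks


def estimate_ani(
    a: tuple[str, str],
    b: tuple[str, str],
    k: int = 16,
    merge_gap: int = 100,
) -> AniEstimate:
    """ANI and aligned fraction between two genomes, (id, seq) pairs.

    Symmetric and deterministic: the pair is ordered internally before
    anchoring.  Raises on degenerate (all-N or < 1 kb) input.
    """
    for gid, seq in (a, b):
        if len(seq) < 1000:
            raise ValueError(f"genome {gid}: shorter than 1 kb")
        if set(seq) <= {"N"}:
            raise ValueError(f"genome {gid}: degenerate (all N)")
    # canonical internal order: query = shorter genome
    (qid, q), (rid, r) = sorted((a, b), key=lambda x: (len(x[1]), x[0]))
    fwd = _ani_core(q, r, k, merge_gap)
    rev = _ani_core(q, revcomp(r), k, merge_gap)
    ani, frac = fwd if fwd[1] >= rev[1] else rev
    return AniEstimate(a[0], b[0], ani, frac)


def _ani_core(q: str, r: str, k: int, merge_gap: int) -> tuple[float, float]:
    blocks = _anchor_blocks(q, r, k, merge_gap)
    if not blocks:
        return 0.0, 0.0
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ra = np.frombuffer(r.encode(), dtype=np.uint8)
    matches = aligned = 0
    cov = np.zeros(len(q), dtype=bool)
    for qs, qe, d in blocks:
        rs, re_ = qs - d, qe - d
        if rs < 0:
            qs, rs = qs - rs, 0
        if re_ > len(r):
            qe, re_ = qe - (re_ - len(r)), len(r)
        if qe <= qs:
            continue
        m = qa[qs:qe] == ra[rs:re_]
        matches += int(m.sum())
        aligned += qe - qs
        cov[qs:qe] = True
    if aligned == 0:
        return 0.0, 0.0
    return float(100.0 * matches / aligned), float(100.0 * cov.mean())


def estimate_ani_circular(a, b, k: int = 16, merge_gap: int = 100) -> AniEstimate:
    """ANI for canonicalized circular genomes: additionally compared against
    an origin-shifted copy of b so a block split by the origin is not lost."""
    e1 = estimate_ani(a, b, k, merge_gap)
    bid, bseq = b
    shift = len(bseq) // 2
    e2 = estimate_ani(a, (bid, bseq[shift:] + bseq[:shift]), k, merge_gap)
    return e1 if e1.aligned_fraction >= e2.aligned_fraction else e2


def dereplicate_genomes(
    genomes: dict[str, str],
    ani_min: float = 95.0,
    cov_min: float = 80.0,
    k: int = 16,
    circular: bool = False,
) -> list[GenomeCluster]:
    """Greedy longest-first dereplication: each genome joins the first
    representative it matches at >= ani_min ANI over >= cov_min percent of
    the shorter genome, else founds a new cluster."""
    if not genomes:
        raise ValueError("no genomes to dereplicate")
    est = estimate_ani_circular if circular else estimate_ani
    order = sorted(genomes, key=lambda g: (-len(genomes[g]), g))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for gid in order:
        placed = False
        for rep in reps:
            e = est((gid, genomes[gid]), (rep, genomes[rep]), k=k)
            if e.ani >= ani_min and e.aligned_fraction >= cov_min:
                members[rep].append(gid)
                placed = True
                break
        if not placed:
            reps.append(gid)
            members[gid] = [gid]
    return [GenomeCluster(rep, tuple(members[rep])) for rep in reps]


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11
        al.extend_gap_score = -1
        _aligner = al
    return _aligner


def protein_identity(rep: str, member: str) -> tuple[float, float]:
    """(percent identity over the local alignment span, percent of the member
    covered by the span)."""
    aln = _get_aligner().align(rep, member)[0]
    ra, ma = aln.aligned  # blocks on target (rep) and query (member)
    matches = cols = 0
    for (rs, re_), (ms, me) in zip(ra, ma):
        a1, a2 = rep[rs:re_], member[ms:me]
        matches += sum(x == y for x, y in zip(a1, a2))
        cols += len(a1)
    if cols == 0:
        return 0.0, 0.0
    covered = sum(me - ms for _, (ms, me) in zip(ra, ma))
    return 100.0 * matches / cols, 100.0 * covered / len(member)


def cluster_proteins(
    proteins: dict[str, str],
    id_min: float = 95.0,
    cov_min: float = 50.0,
) -> list[ProteinCluster]:
    """Greedy longest-first centroid clustering of proteins.

    A protein joins the first representative to which it aligns at
    >= id_min percent identity over >= cov_min percent of its own length.
    """
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for pid in order:
        placed = False
        for rep in reps:
            ident, cov = protein_identity(proteins[rep], proteins[pid])
            if ident >= id_min and cov >= cov_min:
                members[rep].append(pid)
                placed = True
                break
        if not placed:
            reps.append(pid)
            members[pid] = [pid]
    return [
        ProteinCluster(rep, tuple(members[rep]), id_min, cov_min) for rep in reps
    ]
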