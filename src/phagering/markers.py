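"""Marker-profile search and two-round phage classification.

Phage hallmark genes (large terminase subunit TerL, major capsid protein MCP,
portal protein) are detected with fixed-width position-specific log-odds
models built from marker multiple alignments.  Scoring is best ungapped local
alignment of a protein against the model columns; statistical significance is
calibrated per profile from seeded shuffled decoys with a Gumbel (EVD) tail,
the classical null for ungapped local alignment scores.

Classification follows a two-round decision rule: a relaxed search (e < 0.05)
over all contigs, reassessment of the genetic code (amber TAG->Gln
reassignment) for contigs with any hit, then a stricter re-search (e < 0.01);
a contig is called phage when it exceeds 3 kb and carries at least one
round-2 hit to a TerL, MCP or portal profile.
"""

from __future__ import annotations

import functools
import zlib
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy import stats

from . import genes as _genes
from .util import AA_ALPHABET, AA_INDEX

MARKER_CATEGORIES = ("TerL", "MCP", "portal")

_GAP_CHARS = set("-.")


@dataclass
class ProfileModel:
    """Position-specific log-odds model over the 20 standard amino acids."""

    name: str
    category: str  # TerL | MCP | portal | other-phage
    log_odds: np.ndarray  # (ncol, 20), natural log
    background: np.ndarray  # (20,)
    frequencies: np.ndarray  # (ncol, 20) column frequencies (post-pseudocount)
    gumbel_loc: float | None = None
    gumbel_scale: float | None = None
    n_decoys: int = 0

    @property
    def ncol(self) -> int:
        return self.log_odds.shape[0]


@dataclass(frozen=True)
class ProfileHit:
    protein_id: str
    profile_name: str
    category: str
    score: float
    evalue: float
    span: tuple[int, int]  # aligned span on the protein, half-open


@dataclass(frozen=True)
class PhageCall:
    contig_id: str
    is_phage: bool
    markers_found: frozenset[str]
    round1_pass: bool
    round2_pass: bool
    code_id: str
    length: int


def build_profile(
    msa: list[tuple[str, str]],
    name: str,
    category: str = "other-phage",
    pseudocount: float = 0.5,
    max_gap_frac: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from an aligned protein FASTA.

    Columns with more than ``max_gap_frac`` gaps are dropped from the model;
    remaining columns get per-residue counts smoothed with ``pseudocount``
    against a uniform background.
    """
    if len(msa) < 2:
        raise ValueError("profile requires >= 2 aligned sequences")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal aligned length")
    width = lengths.pop()
    nseq = len(msa)
    counts = np.zeros((width, 20))
    gaps = np.zeros(width)
    for _, s in msa:
        for j, ch in enumerate(s.upper()):
            if ch in _GAP_CHARS:
                gaps[j] += 1
            else:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[j, idx] += 1
    keep = gaps / nseq <= max_gap_frac
    counts = counts[keep]
    if counts.shape[0] < 10:
        raise ValueError("profile has fewer than 10 usable columns")
    freqs = counts + pseudocount
    freqs /= freqs.sum(axis=1, keepdims=True)
    background = np.full(20, 1 / 20)
    log_odds = np.log(freqs / background)
    return ProfileModel(name, category, log_odds, background, freqs)


def _seq_indices(aa_seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, -1) for a in aa_seq.upper()], dtype=np.int64)


def score_proteins_batch(profile: ProfileModel, seqs: list[str]) -> np.ndarray:
    """Best ungapped local alignment score of each protein against the model.

    All proteins are scored in one vectorized dynamic program: with
    E[i, j] = best diagonal segment sum ending at residue i / column j,
    E[i, j] = max(E[i-1, j-1], 0) + S[i, j]; the sweep runs over the model
    columns with every protein concatenated (separator sentinels prevent
    segments from crossing protein boundaries).
    """
    if not seqs:
        return np.zeros(0)
    parts, bounds = [], [0]
    for s in seqs:
        parts.append(_seq_indices(s))
        parts.append(np.array([-2], dtype=np.int64))  # separator
        bounds.append(bounds[-1] + len(s) + 1)
    idx = np.concatenate(parts)
    n = len(idx)
    safe = np.where(idx >= 0, idx, 0)
    sep = idx == -2
    unknown = idx == -1
    lo = profile.log_odds
    ncol = profile.ncol

    def column_scores(j: int) -> np.ndarray:
        col = lo[j, safe]
        col[unknown] = 0.0
        col[sep] = -1e30
        return col

    e_prev = column_scores(0)
    best = e_prev.copy()
    for j in range(1, ncol):
        s_col = column_scores(j)
        e_new = s_col.copy()
        e_new[1:] += np.maximum(e_prev[:-1], 0.0)
        np.maximum(best, e_new, out=best)
        e_prev = e_new
    starts = np.array(bounds[:-1])
    out = np.maximum.reduceat(best, starts) if n else best
    return np.maximum(out, 0.0)


def score_protein(profile: ProfileModel, aa_seq: str) -> float:
    """Best ungapped local alignment score of one protein (see
    :func:`score_proteins_batch`)."""
    if not aa_seq:
        return 0.0
    return float(score_proteins_batch(profile, [aa_seq])[0])


def _best_span(profile: ProfileModel, aa_seq: str) -> tuple[int, int]:
    """Protein span of the best-scoring ungapped local alignment (only
    computed for reported hits)."""
    idx = _seq_indices(aa_seq)
    L, ncol = len(idx), profile.ncol
    if L == 0:
        return (0, 0)
    safe = np.where(idx >= 0, idx, 0)
    S = profile.log_odds[:, safe].T.copy()  # (L, ncol)
    S[idx < 0, :] = 0.0
    E = np.empty_like(S)
    E[:, 0] = S[:, 0]
    E[0, :] = S[0, :]
    for j in range(1, ncol):
        E[1:, j] = np.maximum(E[:-1, j - 1], 0.0) + S[1:, j]
    i, j = np.unravel_index(int(np.argmax(E)), E.shape)
    end = i + 1
    while i > 0 and j > 0 and E[i - 1, j - 1] > 0:
        i, j = i - 1, j - 1
    return (int(i), int(end))


def calibrate_profile(
    profile: ProfileModel,
    n_decoys: int = 500,
    seed: int | None = None,
    decoy_length: int | None = None,
) -> ProfileModel:
    """Fit a Gumbel null to scores of shuffled (i.i.d. background) decoys.

    Deterministic: the default seed derives from the profile name, so the
    calibration is a stable property of the packaged profile.
    """
    if seed is None:
        seed = zlib.crc32(profile.name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    m = decoy_length or max(profile.ncol, 100)
    aas = np.array(list(AA_ALPHABET))
    decoys = ["".join(aas[rng.integers(0, 20, size=m)]) for _ in range(n_decoys)]
    scores = score_proteins_batch(profile, decoys)
    loc, scale = stats.gumbel_r.fit(scores)
    return replace(
        profile, gumbel_loc=float(loc), gumbel_scale=float(scale), n_decoys=n_decoys
    )


def evalue(profile: ProfileModel, score: float, search_space: int) -> float:
    """E-value for one comparison scaled to the whole search space
    (number of proteins x number of profiles searched)."""
    if profile.gumbel_loc is None:
        raise ValueError(f"profile {profile.name} is not calibrated")
    z = (score - profile.gumbel_loc) / profile.gumbel_scale
    # survival of Gumbel ~ exp(-z) in the far tail; compute stably
    if z > 40:
        p = float(np.exp(-min(z, 700.0)))
    else:
        p = float(stats.gumbel_r.sf(score, profile.gumbel_loc, profile.gumbel_scale))
    return max(p * search_space, 1e-300)


def emit_sequence(profile: ProfileModel, rng: np.random.Generator) -> str:
    """Sample a protein from the model's column frequency vectors."""
    aas = np.array(list(AA_ALPHABET))
    cols = [rng.choice(20, p=f / f.sum()) for f in profile.frequencies]
    return "".join(aas[cols])


def search_profiles(
    proteins: dict[str, str],
    profiles: list[ProfileModel],
    e_cutoff: float = 0.05,
    search_space: int | None = None,
) -> list[ProfileHit]:
    """Score every protein against every profile; report hits below e_cutoff.

    ``search_space`` defaults to len(proteins) * len(profiles); pass a larger
    value when the search is part of a bigger screen.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    for p in profiles:
        if p.gumbel_loc is None:
            raise ValueError(f"profile {p.name} is not calibrated")
    space = search_space or max(1, len(proteins) * len(profiles))
    pids = list(proteins)
    seqs = [proteins[p] for p in pids]
    hits = []
    for prof in profiles:
        scores = score_proteins_batch(prof, seqs)
        z = (scores - prof.gumbel_loc) / prof.gumbel_scale
        with np.errstate(over="ignore"):
            p = np.where(
                z > 40,
                np.exp(-np.minimum(z, 700.0)),
                -np.expm1(-np.exp(-np.minimum(z, 700.0))),
            )
        evalues = np.maximum(p * space, 1e-300)
        for i in np.nonzero(evalues < e_cutoff)[0]:
            hits.append(
                ProfileHit(pids[i], prof.name, prof.category, float(scores[i]),
                           float(evalues[i]), _best_span(prof, seqs[i]))
            )
    hits.sort(key=lambda h: (h.evalue, h.protein_id, h.profile_name))
    return hits


def classify_contigs(
    contigs: dict[str, str],
    profiles: list[ProfileModel],
    e1: float = 0.05,
    e2: float = 0.01,
    min_length: int = 3000,
    min_aa: int = 30,
    circular_flags: dict[str, bool] | None = None,
    suppressor_trna: set[str] | frozenset[str] = frozenset(),
) -> list[PhageCall]:
    """Two-round marker classification of (canonicalized) contigs.

    Round 1: standard-code ORFs, relaxed cutoff e1 over all contigs.
    Contigs with any hit are re-assessed for amber reassignment (suppressor
    annotation dominates, coding-density heuristic otherwise), re-called and
    re-searched at the stricter cutoff e2.  is_phage requires contig length
    strictly greater than ``min_length`` and a round-2 hit to a marker
    (TerL/MCP/portal) profile.
    """
    if e2 > e1:
        raise ValueError("round-2 cutoff must not be looser than round 1")
    circular_flags = circular_flags or {}

    r1_proteins: dict[str, str] = {}
    prot2contig: dict[str, str] = {}
    for cid, seq in contigs.items():
        for orf in _genes.call_orfs(
            seq, _genes.STANDARD_CODE, min_aa, circular_flags.get(cid, False), cid
        ):
            r1_proteins[orf.protein_id] = orf.aa_seq
            prot2contig[orf.protein_id] = cid

    hits1 = search_profiles(r1_proteins, profiles, e1)
    r1_contigs = {prot2contig[h.protein_id] for h in hits1}

    # round 2: re-assess code on round-1-positive contigs, re-call, re-search
    codes: dict[str, str] = {}
    r2_proteins: dict[str, str] = {}
    prot2contig2: dict[str, str] = {}
    for cid in sorted(r1_contigs):
        code = _genes.assess_code_reassignment(
            contigs[cid],
            suppressor_trna_flag=cid in suppressor_trna,
            circular=circular_flags.get(cid, False),
        )
        codes[cid] = code.id
        for orf in _genes.call_orfs(
            contigs[cid], code, min_aa, circular_flags.get(cid, False), cid
        ):
            r2_proteins[orf.protein_id] = orf.aa_seq
            prot2contig2[orf.protein_id] = cid

    hits2 = search_profiles(r2_proteins, profiles, e2) if r2_proteins else []
    markers_by_contig: dict[str, set[str]] = {}
    r2_pass: set[str] = set()
    for h in hits2:
        cid = prot2contig2[h.protein_id]
        r2_pass.add(cid)
        if h.category in MARKER_CATEGORIES:
            markers_by_contig.setdefault(cid, set()).add(h.category)

    calls = []
    for cid, seq in contigs.items():
        mk = frozenset(markers_by_contig.get(cid, set()))
        is_phage = len(seq) > min_length and bool(mk)
        calls.append(
            PhageCall(
                contig_id=cid,
                is_phage=is_phage,
                markers_found=mk,
                round1_pass=cid in r1_contigs,
                round2_pass=cid in r2_pass,
                code_id=codes.get(cid, _genes.STANDARD_CODE.id),
                length=len(seq),
            )
        )
    return calls


def read_aligned_fasta(path_or_handle) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (id, sequence)."""
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(path_or_handle, "fasta")]


@functools.lru_cache(maxsize=None)
def load_packaged_profiles(calibrate: bool = True) -> tuple[ProfileModel, ...]:
    """The marker profiles shipped with the package (synthetic TerL, MCP and
    portal families), built and Gumbel-calibrated deterministically."""
    cats = {"terl_synthetic": "TerL", "mcp_synthetic": "MCP", "portal_synthetic": "portal"}
    profiles = []
    data = resources.files("phagering") / "data"
    for name, cat in cats.items():
        with (data / f"{name}.afa").open() as fh:
            msa = read_aligned_fasta(fh)
        prof = build_profile(msa, name=name, category=cat)
        if calibrate:
            prof = calibrate_profile(prof)
        profiles.append(prof)
    return tuple(profiles)
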