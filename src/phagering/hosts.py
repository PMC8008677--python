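"""CRISPR spacer -> protospacer host prediction and anti-CRISPR screening.

A CRISPR spacer carried by a bacterial genome that matches a phage sequence
(the protospacer) at >= 95% identity over >= 95% of the spacer length is
evidence that the bacterium is (or was) a host of that phage.  Matching is
ungapped seed-and-extend from exact 8-mer seeds on both strands, with no
low-complexity masking.

Anti-CRISPR (Acr) candidates are filtered by a four-criterion conjunction:
mean prediction score of the protein's 50%-identity cluster >= 0.9, located
in a directon (run of adjacent co-oriented genes) of <= 5 genes, an
HTH-domain protein in the directon, and no strong database hit for the
cluster.  The per-protein score is an input (an external model's output); the
filter is what this module implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .derep import cluster_proteins
from .genes import Orf
from .util import revcomp

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class Spacer:
    id: str
    seq: str
    lineage: dict  # rank -> taxon name (subset of RANKS)

    def __post_init__(self):
        if len(self.seq) < 16:
            raise ValueError(f"spacer {self.id}: shorter than 16 nt")


@dataclass(frozen=True)
class ProtospacerMatch:
    spacer_id: str
    contig_id: str
    start: int  # 0-based half-open, forward strand of the genome
    end: int
    strand: str
    identity: float  # percent, over the aligned span
    coverage: float  # percent of the spacer length aligned
    spacer_seq: str
    protospacer_seq: str  # genome subsequence, forward strand


def _match_one_orientation(sp: str, genome: str, word: int, L: int, circular: bool):
    """Candidate placements (offset, matches, aligned span) of spacer ``sp``
    against ``genome`` (already wrap-extended if circular)."""
    slen = len(sp)
    index: dict[str, list[int]] = {}
    for i in range(slen - word + 1):
        index.setdefault(sp[i : i + word], []).append(i)
    offsets = set()
    for g in range(len(genome) - word + 1):
        for i in index.get(genome[g : g + word], ()):
            o = g - i
            if circular:
                if 0 <= o < L:
                    offsets.add(o)
            elif -slen < o < L:
                offsets.add(o)
    out = []
    for o in sorted(offsets):
        a_start = max(0, -o)  # spacer coords
        a_end = min(slen, len(genome) - o)
        if a_end <= a_start:
            continue
        seg = genome[o + a_start : o + a_end]
        matches = sum(x == y for x, y in zip(sp[a_start:a_end], seg))
        out.append((o, a_start, a_end, matches))
    return out


def match_spacers(
    spacers: list[Spacer],
    genomes: dict[str, str],
    word: int = 8,
    id_min: float = 95.0,
    cov_min: float = 95.0,
    circular: bool = False,
) -> list[ProtospacerMatch]:
    """Ungapped spacer->genome matches passing the 95%/95% rule.

    Identity is computed over the aligned span, coverage over the full spacer
    length.  Both strands are searched; coordinates are always reported on
    the genome's forward strand.  On circular genomes the search crosses the
    origin and coordinates are reported modulo the genome length.
    """
    out = []
    for cid in sorted(genomes):
        seq = genomes[cid]
        L = len(seq)
        max_sp = max((len(s.seq) for s in spacers), default=0)
        work = seq + seq[: max_sp - 1] if circular and max_sp > 1 else seq
        for sp in spacers:
            slen = len(sp.seq)
            for strand, query in (("+", sp.seq), ("-", revcomp(sp.seq))):
                for o, a_s, a_e, m in _match_one_orientation(
                    query, work, word, L, circular
                ):
                    span = a_e - a_s
                    identity = 100.0 * m / span
                    coverage = 100.0 * span / slen
                    if identity >= id_min and coverage >= cov_min:
                        start, end = o + a_s, o + a_e
                        proto = work[start:end]
                        out.append(
                            ProtospacerMatch(
                                sp.id, cid, start % L if circular else start,
                                ((end - 1) % L) + 1 if circular else end,
                                strand, identity, coverage, sp.seq, proto,
                            )
                        )
    # dedupe (a long spacer can seed the same placement repeatedly)
    seen = {}
    for m in out:
        seen[(m.spacer_id, m.contig_id, m.start, m.strand)] = m
    return sorted(
        seen.values(), key=lambda m: (m.contig_id, m.start, m.spacer_id, m.strand)
    )


@dataclass
class HostPrediction:
    contig_id: str
    taxa_by_rank: dict  # rank -> set of taxon names
    multi_genus: bool
    n_spacers: int


def predict_hosts(
    matches: list[ProtospacerMatch], spacers: list[Spacer]
) -> tuple[list[HostPrediction], list[tuple[str, tuple[str, ...]]]]:
    """Aggregate spacer matches into per-phage host predictions.

    Returns (predictions, cross_targeting) where cross_targeting lists
    protospacer sequences found verbatim in two or more phage genomes.
    """
    by_id = {s.id: s for s in spacers}
    per_contig: dict[str, list[ProtospacerMatch]] = {}
    for m in matches:
        if m.spacer_id not in by_id:
            raise KeyError(f"unknown spacer id {m.spacer_id!r}")
        per_contig.setdefault(m.contig_id, []).append(m)
    preds = []
    for cid in sorted(per_contig):
        taxa: dict[str, set] = {r: set() for r in RANKS}
        for m in per_contig[cid]:
            for rank, name in by_id[m.spacer_id].lineage.items():
                if rank in taxa and name:
                    taxa[rank].add(name)
        preds.append(
            HostPrediction(
                cid,
                {r: t for r, t in taxa.items() if t},
                multi_genus=len(taxa["genus"]) >= 2,
                n_spacers=len({m.spacer_id for m in per_contig[cid]}),
            )
        )
    # cross-targeting: identical protospacer sequence in >= 2 phages
    by_proto: dict[str, set] = {}
    for m in matches:
        by_proto.setdefault(m.protospacer_seq, set()).add(m.contig_id)
    cross = [
        (seq, tuple(sorted(cids)))
        for seq, cids in sorted(by_proto.items())
        if len(cids) >= 2
    ]
    return preds, cross


@dataclass(frozen=True)
class AcrCandidate:
    protein_id: str
    mean_cluster_score: float
    directon_length: int
    directon_has_hth: bool
    strong_db_hit: bool
    verdict: bool


def build_directons(orfs: list[Orf], max_gap: int = 250) -> list[list[Orf]]:
    """Directons: maximal runs of adjacent co-oriented ORFs with intergenic
    gap <= max_gap bp, per contig."""
    by_contig: dict[str, list[Orf]] = {}
    for o in orfs:
        by_contig.setdefault(o.contig_id, []).append(o)
    directons = []
    for cid in sorted(by_contig):
        run: list[Orf] = []
        for o in sorted(by_contig[cid], key=lambda x: (x.start, x.end)):
            if run and (o.strand != run[-1].strand or o.start - run[-1].end > max_gap):
                directons.append(run)
                run = []
            run.append(o)
        if run:
            directons.append(run)
    return directons


def acr_gate(
    mean_score: float, directon_length: int, has_hth: bool, strong_db_hit: bool,
    score_min: float = 0.9, directon_max: int = 5,
) -> bool:
    """The four-criterion Acr conjunction."""
    return (
        mean_score >= score_min
        and directon_length <= directon_max
        and has_hth
        and not strong_db_hit
    )


def screen_acr(
    proteins: dict[str, str],
    scores: dict[str, float],
    orfs: list[Orf],
    hth_flags: set[str] | frozenset[str] = frozenset(),
    strong_db_hits: set[str] | frozenset[str] = frozenset(),
    score_min: float = 0.9,
    directon_max: int = 5,
    cluster_id_min: float = 50.0,
    directon_gap: int = 250,
) -> list[AcrCandidate]:
    """Apply the Acr candidate filter.

    ``scores`` are per-protein model scores in [0, 1] (supplied externally);
    ``hth_flags`` / ``strong_db_hits`` are protein-id annotation sets.
    """
    for pid, s in scores.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score for {pid} outside [0, 1]: {s}")
    clusters = cluster_proteins(proteins, id_min=cluster_id_min, cov_min=50.0)
    cluster_of: dict[str, tuple] = {}
    for cl in clusters:
        mean = sum(scores.get(m, 0.0) for m in cl.members) / len(cl.members)
        db = any(m in strong_db_hits for m in cl.members)
        for m in cl.members:
            cluster_of[m] = (mean, db)
    directon_of: dict[str, list[Orf]] = {}
    for d in build_directons(orfs, directon_gap):
        for o in d:
            directon_of[o.protein_id] = d
    out = []
    for pid in sorted(proteins):
        mean, db = cluster_of.get(pid, (scores.get(pid, 0.0), False))
        d = directon_of.get(pid, [])
        dlen = len(d) if d else 1
        hth = any(o.protein_id in hth_flags for o in d) or pid in hth_flags
        out.append(
            AcrCandidate(
                pid, mean, dlen, hth, db,
                acr_gate(mean, dlen, hth, db, score_min, directon_max),
            )
        )
    return out
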