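"""Synthetic gut-metagenome communities with planted ground truth.

Every downstream stage of the pipeline is exercised on communities generated
here: circular phage genomes carrying terminal direct repeats and marker
genes emitted from the packaged marker profiles, circular plasmid decoys
(repeats, no markers), linear fragments, genomes recoded with in-frame
TAG->Gln read-through codons, DGR cassettes with adenine-restricted
variable-repeat mutations, CRISPR spacers targeting the planted phages, and
error-free reads drawn from a chosen abundance vector.

Genomes are gene-dense (short intergenic spacers), as real phage and plasmid
sequences are; this matters for the coding-density heuristic that detects
amber recoding.  All generation is driven by one seeded generator and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .hosts import Spacer
from .markers import ProfileModel, emit_sequence, load_packaged_profiles
from .util import DNA, random_dna, random_protein, revcomp

# codons by amino acid, bacterial table, stops excluded
_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
GENE_STOPS = ("TAA", "TGA")  # TAG reserved for engineered read-through


@dataclass(frozen=True)
class DgrSpec:
    tr_length: int = 120
    n_vr: int = 1
    adenine_mutation_fraction: float = 0.5
    vr_identity: float | None = None  # informational; recorded, not enforced
    vr_distance_from_rt: int = 4000
    background_noise: float = 0.0  # per-non-adenine substitution probability

    def validate(self):
        if self.tr_length < 20:
            raise ValueError("tr_length must be >= 20")
        for f in (self.adenine_mutation_fraction, self.background_noise):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_vr < 1:
            raise ValueError("n_vr must be >= 1")


@dataclass(frozen=True)
class CommunityConfig:
    n_phage_circular: int = 20
    n_plasmid_circular: int = 5
    n_linear_fragment: int = 10
    phage_length_range: tuple[int, int] = (15_000, 35_000)
    plasmid_length_range: tuple[int, int] = (8_000, 15_000)
    linear_length_range: tuple[int, int] = (4_000, 10_000)
    repeat_length_range: tuple[int, int] = (50, 200)
    n_recoded: int = 3
    dgr_specs: tuple[DgrSpec, ...] = ()
    spacer_specs: dict = field(default_factory=dict)  # genus -> (n_target, n_decoy)
    gc: float = 0.5
    seed: int = 0

    def validate(self):
        for name in ("n_phage_circular", "n_plasmid_circular", "n_linear_fragment",
                     "n_recoded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.repeat_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid repeat_length_range")
        if hi > self.phage_length_range[0] // 2:
            raise ValueError("repeat_length_range must fit within half the "
                             "shortest phage length")
        if self.n_recoded > self.n_phage_circular:
            raise ValueError("n_recoded exceeds n_phage_circular")
        for spec in self.dgr_specs:
            spec.validate()


@dataclass
class TruthTable:
    contigs: pd.DataFrame   # contig_id, label, length, repeat_length, genetic_code
    markers: pd.DataFrame   # contig_id, marker, start, end, strand
    dgrs: pd.DataFrame      # contig_id, rt_*, tr_*, per-VR coords + mutated positions
    protospacers: pd.DataFrame  # contig_id, spacer_id, start, end, strand, targeting
    abundance: dict         # contig_id -> true fractional abundance (phages)
    spacers: list = field(default_factory=list)  # hosts.Spacer objects

    def to_dir(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.contigs.to_csv(out / "truth_contigs.tsv", sep="\t", index=False)
        self.markers.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
        self.dgrs.to_csv(out / "truth_dgrs.tsv", sep="\t", index=False)
        self.protospacers.to_csv(out / "truth_protospacers.tsv", sep="\t", index=False)
        pd.Series(self.abundance, name="fraction").rename_axis("contig_id").to_csv(
            out / "truth_abundance.tsv", sep="\t"
        )
        if self.spacers:
            pd.DataFrame(
                [
                    {"spacer_id": s.id, "sequence": s.seq,
                     **{r: s.lineage.get(r, "") for r in
                        ("phylum", "class", "order", "family", "genus")}}
                    for s in self.spacers
                ]
            ).to_csv(out / "spacers.tsv", sep="\t", index=False)


def reverse_translate(
    rng: np.random.Generator, aa_seq: str, tag_positions: frozenset[int] = frozenset()
) -> str:
    """DNA for a protein, choosing random synonymous codons; residues listed
    in ``tag_positions`` (must be Q) are written as the amber codon TAG."""
    codons = []
    for i, aa in enumerate(aa_seq):
        if i in tag_positions:
            if aa != "Q":
                raise ValueError("TAG read-through positions must be glutamine")
            codons.append("TAG")
        else:
            opts = CODONS_BY_AA[aa]
            codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def _make_gene(
    rng: np.random.Generator,
    aa_seq: str,
    recode: str = "none",  # none | single-mid | random
    recode_prob: float = 0.8,
) -> str:
    """Gene DNA: ATG + codons + TAA/TGA stop, optionally with TAG read-through
    glutamines (one mid-gene, or each Q with probability recode_prob)."""
    qs = [i for i, a in enumerate(aa_seq) if a == "Q"]
    tag_pos: set[int] = set()
    if recode == "single-mid" and qs:
        tag_pos = {min(qs, key=lambda i: abs(i - len(aa_seq) // 2))}
    elif recode == "random" and qs:
        tag_pos = {i for i in qs if rng.random() < recode_prob}
        if not tag_pos:
            tag_pos = {qs[rng.integers(0, len(qs))]}
    body = reverse_translate(rng, aa_seq, frozenset(tag_pos))
    stop = GENE_STOPS[rng.integers(0, 2)]
    return "ATG" + body + stop


def make_tr(rng: np.random.Generator, tr_length: int, min_adenines: int = 5) -> str:
    if tr_length < min_adenines:
        raise ValueError(f"tr_length {tr_length} cannot hold {min_adenines} adenines")
    for _ in range(100):
        tr = random_dna(rng, tr_length)
        if tr.count("A") >= min_adenines:
            return tr
    raise RuntimeError("could not draw a template repeat with enough adenines")


def mutate_vr(
    rng: np.random.Generator, tr: str, adenine_fraction: float, noise: float = 0.0
) -> tuple[str, list[int]]:
    """VR copy of TR: a chosen fraction of TR adenines mutated (to a non-A
    base), plus optional uniform background noise at non-adenine positions.
    Returns (vr, mutated adenine positions)."""
    a_pos = [i for i, b in enumerate(tr) if b == "A"]
    if len(a_pos) < 5:
        raise ValueError("template repeat has fewer than 5 adenines")
    n_mut = int(round(adenine_fraction * len(a_pos)))
    chosen = sorted(rng.choice(len(a_pos), size=n_mut, replace=False)) if n_mut else []
    mutated = [a_pos[i] for i in chosen]
    vr = list(tr)
    non_a = [b for b in DNA if b != "A"]
    for i in mutated:
        vr[i] = non_a[rng.integers(0, 3)]
    if noise > 0:
        for i, b in enumerate(tr):
            if b != "A" and rng.random() < noise:
                alts = [x for x in DNA if x != b]
                vr[i] = alts[rng.integers(0, 3)]
    return "".join(vr), mutated


class _GenomeBuilder:
    """Assembles a gene-dense genome core left to right, recording loci."""

    def __init__(self, rng: np.random.Generator, gc: float = 0.5):
        self.rng = rng
        self.gc = gc
        self.parts: list[str] = []
        self.pos = 0
        self.markers: list[dict] = []
        self.rt_locus: tuple[int, int] | None = None
        self.tr_locus: tuple[int, int] | None = None
        self.vr_loci: list[tuple[int, int, list[int]]] = []

    def _emit(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def spacer(self, lo: int = 15, hi: int = 40):
        self._emit(random_dna(self.rng, int(self.rng.integers(lo, hi + 1)), self.gc))

    def gene(self, aa_seq: str, recode: str = "none", label: str | None = None,
             forward: bool | None = None) -> tuple[int, int, str]:
        dna = _make_gene(self.rng, aa_seq, recode)
        if forward is None:
            forward = bool(self.rng.random() < 0.5)
        strand = "+" if forward else "-"
        s, e = self._emit(dna if forward else revcomp(dna))
        if label is not None:
            self.markers.append(
                {"marker": label, "start": s, "end": e, "strand": strand}
            )
        return s, e, strand

    def random_gene(self, recode: str = "none"):
        n = int(self.rng.integers(120, 301))
        self.gene(random_protein(self.rng, n), recode)

    def dgr_cassette(self, spec: DgrSpec):
        """RT gene + template repeat; VRs are placed later via place_vr."""
        rt_aa = random_protein(self.rng, 200)
        s, e, _ = self.gene(rt_aa, forward=True)
        self.rt_locus = (s, e)
        self.spacer(150, 250)
        tr = make_tr(self.rng, spec.tr_length)
        self.tr_locus = self._emit(tr)
        return tr

    def place_vr(self, tr: str, spec: DgrSpec):
        vr, mutated = mutate_vr(
            self.rng, tr, spec.adenine_mutation_fraction, spec.background_noise
        )
        s, e = self._emit(vr)
        self.vr_loci.append((s, e, mutated))

    def sequence(self) -> str:
        return "".join(self.parts)


def generate_dgr_genome(
    spec: DgrSpec, seed: int, genome_length: int = 30_000, gc: float = 0.5
) -> tuple[str, dict]:
    """A genome carrying one DGR cassette: RT gene, template repeat, and
    n_vr variable repeats at the requested distance from the RT.

    Returns (sequence, truth) where truth records the RT/TR/VR loci and the
    mutated adenine positions (TR-relative) per VR.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rt_start = genome_length // 3
    rt_aa = random_protein(rng, 200)
    rt_dna = "ATG" + reverse_translate(rng, rt_aa) + "TAA"
    tr = make_tr(rng, spec.tr_length)
    vrs = [
        mutate_vr(rng, tr, spec.adenine_mutation_fraction, spec.background_noise)
        for _ in range(spec.n_vr)
    ]
    tr_start = rt_start + len(rt_dna) + 200
    layout = [(rt_start, rt_dna), (tr_start, tr)]
    rt_center = rt_start + len(rt_dna) // 2
    vr_pos = []
    pos = None
    for i, (vr, _) in enumerate(vrs):
        p = rt_center + spec.vr_distance_from_rt + i * (len(tr) + 400)
        if p + len(vr) > genome_length:
            raise ValueError("vr_distance_from_rt does not fit in the genome")
        if p < tr_start + len(tr) + 50:
            p = tr_start + len(tr) + 50 + i * (len(tr) + 400)
        layout.append((p, vr))
        vr_pos.append(p)
    seq = list(random_dna(rng, genome_length, gc))
    for start, frag in layout:
        seq[start : start + len(frag)] = list(frag)
    truth = {
        "rt_locus": (rt_start, rt_start + len(rt_dna)),
        "tr_locus": (tr_start, tr_start + len(tr)),
        "tr_seq": tr,
        "vrs": [
            {"locus": (p, p + len(v)), "seq": v, "mutated_adenine_positions": mut}
            for p, (v, mut) in zip(vr_pos, vrs)
        ],
    }
    return "".join(seq), truth


def generate_community(config: CommunityConfig):
    """Generate a community of contigs with a complete truth table.

    Returns (contigs, truth): ``contigs`` is an ordered dict contig_id ->
    sequence, ``truth`` a TruthTable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = load_packaged_profiles(calibrate=False)
    contigs: dict[str, str] = {}
    contig_rows, marker_rows, dgr_rows = [], [], []

    recoded_idx = set(range(config.n_recoded))
    dgr_assign: dict[int, DgrSpec] = {
        config.n_phage_circular - 1 - i: s for i, s in enumerate(config.dgr_specs)
        if config.n_phage_circular - 1 - i >= 0
    }

    for i in range(config.n_phage_circular):
        cid = f"phage_{i:04d}"
        length = int(rng.integers(*config.phage_length_range))
        recoded = i in recoded_idx
        b = _GenomeBuilder(rng, config.gc)
        _assemble(b, length, profiles, recoded, dgr_assign.get(i))
        core = b.sequence()
        r = int(rng.integers(config.repeat_length_range[0],
                             config.repeat_length_range[1] + 1))
        contigs[cid] = core + core[:r]
        contig_rows.append(
            {"contig_id": cid, "label": "phage", "length": len(contigs[cid]),
             "repeat_length": r,
             "genetic_code": "amber-gln" if recoded else "standard-bacterial"}
        )
        for m in b.markers:
            marker_rows.append({"contig_id": cid, **m})
        if b.rt_locus is not None:
            for j, (vs, ve, mut) in enumerate(b.vr_loci):
                dgr_rows.append(
                    {"contig_id": cid, "rt_start": b.rt_locus[0],
                     "rt_end": b.rt_locus[1], "tr_start": b.tr_locus[0],
                     "tr_end": b.tr_locus[1], "vr_index": j, "vr_start": vs,
                     "vr_end": ve,
                     "mutated_adenine_positions": ",".join(map(str, mut))}
                )

    for i in range(config.n_plasmid_circular):
        cid = f"plasmid_{i:04d}"
        length = int(rng.integers(*config.plasmid_length_range))
        b = _GenomeBuilder(rng, config.gc)
        _assemble(b, length, (), False, None)
        core = b.sequence()
        r = int(rng.integers(config.repeat_length_range[0],
                             config.repeat_length_range[1] + 1))
        contigs[cid] = core + core[:r]
        contig_rows.append(
            {"contig_id": cid, "label": "plasmid", "length": len(contigs[cid]),
             "repeat_length": r, "genetic_code": "standard-bacterial"}
        )

    for i in range(config.n_linear_fragment):
        cid = f"linear_{i:04d}"
        length = int(rng.integers(*config.linear_length_range))
        b = _GenomeBuilder(rng, config.gc)
        _assemble(b, length, (), False, None)
        contigs[cid] = b.sequence()
        contig_rows.append(
            {"contig_id": cid, "label": "linear", "length": len(contigs[cid]),
             "repeat_length": 0, "genetic_code": "standard-bacterial"}
        )

    # abundance over phage genomes (viromes are phage-particle samples)
    phage_ids = [c["contig_id"] for c in contig_rows if c["label"] == "phage"]
    if phage_ids:
        vec = rng.dirichlet(np.ones(len(phage_ids)))
        abundance = dict(zip(phage_ids, vec.tolist()))
    else:
        abundance = {}

    # CRISPR spacers
    spacers, proto_rows = [], []
    for genus in sorted(config.spacer_specs):
        n_t, n_nt = config.spacer_specs[genus]
        for j in range(n_t):
            sid = f"{genus}_sp{j:03d}"
            target = phage_ids[int(rng.integers(0, len(phage_ids)))]
            seq = contigs[target]
            pos = int(rng.integers(0, len(seq) - 32))
            proto = seq[pos : pos + 32]
            strand = "+" if rng.random() < 0.5 else "-"
            sp_seq = proto if strand == "+" else revcomp(proto)
            spacers.append(Spacer(sid, sp_seq, {"genus": genus}))
            proto_rows.append(
                {"contig_id": target, "spacer_id": sid, "start": pos,
                 "end": pos + 32, "strand": strand, "targeting": True}
            )
        for j in range(n_nt):
            sid = f"{genus}_decoy{j:03d}"
            spacers.append(Spacer(sid, random_dna(rng, 32, config.gc),
                                  {"genus": genus}))

    truth = TruthTable(
        contigs=pd.DataFrame(contig_rows),
        markers=pd.DataFrame(
            marker_rows, columns=["contig_id", "marker", "start", "end", "strand"]
        ),
        dgrs=pd.DataFrame(
            dgr_rows,
            columns=["contig_id", "rt_start", "rt_end", "tr_start", "tr_end",
                     "vr_index", "vr_start", "vr_end", "mutated_adenine_positions"],
        ),
        protospacers=pd.DataFrame(
            proto_rows,
            columns=["contig_id", "spacer_id", "start", "end", "strand", "targeting"],
        ),
        abundance=abundance,
        spacers=spacers,
    )
    return contigs, truth


def _assemble(
    b: _GenomeBuilder,
    length: int,
    marker_profiles: tuple[ProfileModel, ...],
    recoded: bool,
    dgr_spec: DgrSpec | None,
):
    """Fill builder ``b`` with genes up to ``length`` bp, planting marker
    genes, an optional DGR cassette, and TAG read-through codons."""
    recode_mode = "random" if recoded else "none"
    marker_recode = "single-mid" if recoded else "none"
    pending_markers = list(marker_profiles)
    # plant markers at roughly even spacing with jitter
    marker_at = sorted(
        int(x) for x in
        (np.arange(1, len(pending_markers) + 1) / (len(pending_markers) + 1) * length
         + b.rng.integers(-500, 501, size=len(pending_markers)))
    ) if pending_markers else []
    tr = None
    vr_targets: list[int] = []
    while b.pos < length:
        if dgr_spec is not None and tr is None and b.pos >= length // 3:
            tr = b.dgr_cassette(dgr_spec)
            vr_targets = [
                b.rt_locus[0] + dgr_spec.vr_distance_from_rt
                + i * (dgr_spec.tr_length + 400)
                for i in range(dgr_spec.n_vr)
            ]
            b.spacer()
            continue
        if tr is not None and vr_targets and b.pos >= vr_targets[0]:
            b.place_vr(tr, dgr_spec)
            vr_targets.pop(0)
            b.spacer()
            continue
        if marker_at and b.pos >= marker_at[0]:
            prof = pending_markers.pop(0)
            marker_at.pop(0)
            aa = emit_sequence(prof, b.rng)
            s, e, strand = b.gene(aa, recode=marker_recode)
            b.markers.append(
                {"marker": prof.category, "start": s, "end": e, "strand": strand}
            )
            b.spacer()
            continue
        b.random_gene(recode=recode_mode)
        b.spacer()
    # any marker not yet placed (short genome): append now
    for prof in pending_markers:
        aa = emit_sequence(prof, b.rng)
        s, e, strand = b.gene(aa, recode=marker_recode)
        b.markers.append(
            {"marker": prof.category, "start": s, "end": e, "strand": strand}
        )


def generate_reads(
    genomes: dict[str, str],
    abundance: dict[str, float],
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
    circular: bool = True,
) -> list[tuple[str, str]]:
    """Error-free (optionally uniformly mutated) reads from a community.

    Genomes are sampled with probability proportional to abundance x length,
    so that the expected *length-normalized* fractional abundance recovered
    by the recruitment stage equals the input vector.  Reads from circular
    genomes may span the origin.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    ids = sorted(genomes)
    a = np.array([abundance[g] for g in ids], dtype=float)
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError("abundance vector must sum to 1")
    if any(len(genomes[g]) < read_length for g in ids):
        raise ValueError("read_length exceeds the shortest genome")
    rng = np.random.default_rng(seed)
    lens = np.array([len(genomes[g]) for g in ids], dtype=float)
    p = a * lens
    p /= p.sum()
    counts = rng.multinomial(n_reads, p)
    reads = []
    for gid, c in zip(ids, counts):
        seq = genomes[gid]
        L = len(seq)
        work = seq + seq[: read_length - 1] if circular else seq
        hi = L if circular else L - read_length + 1
        starts = rng.integers(0, hi, size=c)
        strands = rng.random(c) < 0.5
        for j, (s, fwd) in enumerate(zip(starts, strands)):
            r = work[s : s + read_length]
            if not fwd:
                r = revcomp(r)
            if error_rate > 0:
                arr = list(r)
                for pos in np.nonzero(rng.random(read_length) < error_rate)[0]:
                    alts = [x for x in DNA if x != arr[pos]]
                    arr[pos] = alts[rng.integers(0, 3)]
                r = "".join(arr)
            reads.append((f"{gid}_r{j:06d}", r))
    return reads


# ------------------------------------------------------------------ writers

def write_fasta(seqs: dict[str, str], path):
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def write_fastq(reads: list[tuple[str, str]], path):
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
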