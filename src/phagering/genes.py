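"""ORF prediction under selectable genetic codes, including amber (TAG->Gln)
stop-codon reassignment as observed in a subset of human gut phages.

Deterministic maximal-ORF calling: every start-codon(ATG/GTG/TTG)-to-stop
reading frame segment of at least ``min_aa`` codons, on both strands, with
origin-spanning ORFs on circular sequences.  Stop-codon reassignment is
assessed either from an externally supplied suppressor-tRNA annotation or,
failing that, from the coding-density gain obtained by re-reading TAG as
glutamine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .util import revcomp

START_CODONS = frozenset({"ATG", "GTG", "TTG"})

# vectorized translation machinery: base -> 0..3 (4 = ambiguous), codon ->
# index in a 125-entry lookup table of amino-acid byte codes (table 11)
_BASE_IDX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i
    _BASE_IDX[ord(_b.lower())] = _i
_LUT11 = np.full(125, ord("X"), dtype=np.uint8)
_T11 = CodonTable.unambiguous_dna_by_id[11]
for _codon in [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]:
    _idx = 25 * _BASE_IDX[ord(_codon[0])] + 5 * _BASE_IDX[ord(_codon[1])] + _BASE_IDX[ord(_codon[2])]
    _LUT11[_idx] = ord("*") if _codon in _T11.stop_codons else ord(_T11.forward_table[_codon])
_TAG_IDX = 25 * _BASE_IDX[ord("T")] + 5 * _BASE_IDX[ord("A")] + _BASE_IDX[ord("G")]
_START_IDX = frozenset(
    int(25 * _BASE_IDX[ord(c[0])] + 5 * _BASE_IDX[ord(c[1])] + _BASE_IDX[ord(c[2])])
    for c in START_CODONS
)


@dataclass(frozen=True)
class GeneticCode:
    """Translation table: 'standard-bacterial' or 'amber-gln' (TAG -> Q)."""

    id: str
    stop_codons: frozenset[str]
    tag_translation: str  # '*' or 'Q'


STANDARD_CODE = GeneticCode("standard-bacterial", frozenset({"TAA", "TAG", "TGA"}), "*")
AMBER_GLN_CODE = GeneticCode("amber-gln", frozenset({"TAA", "TGA"}), "Q")

CODES = {c.id: c for c in (STANDARD_CODE, AMBER_GLN_CODE)}


@dataclass(frozen=True)
class Orf:
    """0-based half-open forward-strand coordinates; the stop codon is included
    in [start, end); end may exceed the contig length on circular contigs
    (origin wrap).  ``partial`` marks an ORF running off the contig edge
    without a stop codon (the edge acts as the boundary; no stop included)."""

    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str
    code_id: str
    partial: bool = False

    @property
    def protein_id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}({self.strand})"


def _codon_indices(base_idx: np.ndarray, frame: int) -> np.ndarray:
    n = (len(base_idx) - frame) // 3
    b = base_idx[frame : frame + 3 * n].reshape(n, 3)
    return 25 * b[:, 0] + 5 * b[:, 1] + b[:, 2]


def translate_frame(seq: str, code: GeneticCode) -> str:
    """Translate one reading frame; TAG rendered per the genetic code."""
    base_idx = _BASE_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    cod = _codon_indices(base_idx, 0)
    aa = _LUT11[cod]
    if code.tag_translation != "*":
        aa = aa.copy()
        aa[cod == _TAG_IDX] = ord(code.tag_translation)
    return aa.tobytes().decode()


def translate_codon(codon: str, code: GeneticCode) -> str:
    return translate_frame(codon, code)


def _scan_strand(work: str, code: GeneticCode, min_aa: int, limit: int):
    """Maximal ORFs on the forward strand of ``work``; yields (start, end, aa).

    Only ORFs starting before ``limit`` are yielded (used to de-duplicate on
    doubled circular sequences).  ORFs running off the end without a stop are
    not emitted.
    """
    base_idx = _BASE_IDX[np.frombuffer(work.encode(), dtype=np.uint8)]
    for frame in range(3):
        cod = _codon_indices(base_idx, frame)
        if len(cod) == 0:
            continue
        aa = _LUT11[cod]
        if code.tag_translation != "*":
            aa[cod == _TAG_IDX] = ord(code.tag_translation)
        is_stop = aa == ord("*")
        stop_pos = np.nonzero(is_stop)[0]
        is_start = np.isin(cod, tuple(_START_IDX))
        start_pos = np.nonzero(is_start)[0]
        aa_str = aa.tobytes().decode()
        prev = -1
        for st in stop_pos:
            k = np.searchsorted(start_pos, prev + 1)
            if k < len(start_pos) and start_pos[k] < st:
                s0 = int(start_pos[k])
                s = frame + 3 * s0
                if st - s0 >= min_aa and s < limit:
                    yield s, frame + 3 * int(st) + 3, aa_str[s0:st], False
            prev = int(st)
        # an ORF running off the contig edge without a stop (partial)
        n_cod = len(cod)
        k = np.searchsorted(start_pos, prev + 1)
        if k < len(start_pos) and start_pos[k] < n_cod:
            s0 = int(start_pos[k])
            s = frame + 3 * s0
            if n_cod - s0 >= min_aa and s < limit:
                yield s, frame + 3 * n_cod, aa_str[s0:], True


def call_orfs(
    seq: str,
    code: GeneticCode = STANDARD_CODE,
    min_aa: int = 30,
    circular: bool = False,
    contig_id: str = "contig",
) -> list[Orf]:
    """All maximal start-to-stop ORFs of >= min_aa residues on both strands.

    On circular sequences the contig is scanned doubled so that ORFs may span
    the origin; coordinates are reported on the forward strand with
    start in [0, L) and end possibly > L.
    """
    L = len(seq)
    if L == 0:
        return []
    work = seq + seq if circular else seq
    limit = L if circular else len(work)
    out: dict[tuple, Orf] = {}

    for s, e, aa, partial in _scan_strand(work, code, min_aa, limit):
        if circular and (partial or e - s > L):
            continue  # wrap artifacts: partials and over-long ORFs
        key = (s % L if circular else s, e - s, "+")
        out.setdefault(key, Orf(contig_id, s, e, "+", aa, code.id, partial))

    rc = revcomp(work)
    nw = len(work)
    for s_rc, e_rc, aa, partial in _scan_strand(rc, code, min_aa, nw):
        if circular and (partial or e_rc - s_rc > L):
            continue
        s_f, e_f = nw - e_rc, nw - s_rc
        if circular:
            shift = (s_f // L) * L
            s_f, e_f = s_f - shift, e_f - shift
            if s_f >= L:
                s_f, e_f = s_f - L, e_f - L
            if s_f < 0 or s_f >= L:
                continue
        key = (s_f % L if circular else s_f, e_f - s_f, "-")
        if key not in out:
            out[key] = Orf(contig_id, s_f, e_f, "-", aa, code.id, partial)

    orfs = sorted(out.values(), key=lambda o: (o.start, o.end, o.strand))
    return orfs


def coding_density(
    seq: str, code: GeneticCode, min_aa: int = 30, circular: bool = False
) -> float:
    """Fraction of bases covered by at least one called ORF (either strand)."""
    L = len(seq)
    if L == 0:
        return 0.0
    cov = np.zeros(L, dtype=bool)
    for orf in call_orfs(seq, code, min_aa, circular):
        if orf.end <= L:
            cov[orf.start : orf.end] = True
        else:  # origin wrap
            cov[orf.start :] = True
            cov[: orf.end - L] = True
    return float(cov.mean())


def assess_code_reassignment(
    seq: str,
    suppressor_trna_flag: bool = False,
    gain_threshold: float = 0.10,
    min_aa: int = 60,
    circular: bool = False,
) -> GeneticCode:
    """Choose the genetic code for a contig.

    An externally supplied amber-suppressor-tRNA annotation dominates.  The
    fallback heuristic selects amber-gln when re-reading TAG as glutamine
    raises coding density by at least ``gain_threshold`` (default 10
    percentage points), the signature of a genome whose genes are riddled
    with in-frame read-through TAG codons under the standard code.

    Density is measured over ORFs of >= ``min_aa`` residues; the default of
    60 is deliberately higher than the ORF-calling default because short
    spurious open frames (which arise on either code) would otherwise mask
    the fragmentation signal that read-through TAG codons leave behind.
    """
    if suppressor_trna_flag:
        return AMBER_GLN_CODE
    d_std = coding_density(seq, STANDARD_CODE, min_aa, circular)
    d_amb = coding_density(seq, AMBER_GLN_CODE, min_aa, circular)
    return AMBER_GLN_CODE if d_amb - d_std >= gain_threshold else STANDARD_CODE
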