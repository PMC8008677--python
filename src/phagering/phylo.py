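"""Profile-profile distances between marker clusters, UPGMA guide dendrogram
with depth-based tip merging, alignment column filtering, and the
gene-sharing network.

Cluster alignments are compared by their column frequency vectors: the
similarity of two profiles is the best ungapped sliding sum of per-column
log-odds dot products, and the distance between clusters A and B is
d = -ln(S_AB / min(S_AA, S_BB)), clamped at zero.  The UPGMA dendrogram over
these distances guides progressive merging; tips whose subtree root sits at
depth (node height) < 1.5 are grouped.  Alignment columns with > 50% gaps or
homogeneity < 0.1 are removed before downstream tree building.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio.Align import substitution_matrices

from .util import AA_ALPHABET, AA_INDEX

_GAP_CHARS = set("-.")


# ---------------------------------------------------------------- distances

def column_frequencies(msa: list[tuple[str, str]], smoothing: float = 0.05) -> np.ndarray:
    """(ncol, 20) column frequency vectors: raw per-column residue
    frequencies (gaps excluded) mixed with the uniform background at weight
    ``smoothing``.  The mixture form keeps the vectors invariant under
    duplicating every sequence of the alignment."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0][1])
    if any(len(s) != width for _, s in msa):
        raise ValueError("ragged alignment")
    counts = np.zeros((width, 20))
    for _, s in msa:
        for j, ch in enumerate(s.upper()):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    raw = np.divide(counts, totals, out=np.full_like(counts, 1 / 20),
                    where=totals > 0)
    return (1 - smoothing) * raw + smoothing / 20


def _profile_similarity(fa: np.ndarray, fb: np.ndarray, min_overlap: int = 10) -> float:
    """Best ungapped sliding alignment of two column-frequency profiles;
    column pair score = ln(sum_r fa_r * fb_r / q_r), uniform background."""
    q = 1 / 20
    na, nb = fa.shape[0], fb.shape[0]
    best = -math.inf
    for off in range(-(nb - min_overlap), na - min_overlap + 1):
        a0, b0 = max(0, off), max(0, -off)
        n = min(na - a0, nb - b0)
        if n < min_overlap:
            continue
        dots = np.einsum("ij,ij->i", fa[a0 : a0 + n], fb[b0 : b0 + n])
        s = float(np.sum(np.log(dots / q)))
        if s > best:
            best = s
    return best


@dataclass(frozen=True)
class ProfilePair:
    id_a: str
    id_b: str
    s_ab: float
    s_aa: float
    s_bb: float

    @property
    def distance(self) -> float:
        return distance_from_scores(self.s_ab, self.s_aa, self.s_bb)


def distance_from_scores(
    s_ab: float, s_aa: float, s_bb: float, max_distance: float = 10.0
) -> float:
    """d = -ln(S_AB / min(S_AA, S_BB)), clamped to [0, max_distance]."""
    if s_aa <= 0 or s_bb <= 0:
        raise ValueError("self-similarities must be positive")
    ref = min(s_aa, s_bb)
    if s_ab <= 0:
        return max_distance
    return float(min(max(-math.log(s_ab / ref), 0.0), max_distance))


def profile_distance(
    msa_a: list[tuple[str, str]],
    msa_b: list[tuple[str, str]],
    id_a: str = "A",
    id_b: str = "B",
    min_overlap: int = 10,
) -> ProfilePair:
    """Profile-profile distance between two cluster alignments."""
    for name, msa in ((id_a, msa_a), (id_b, msa_b)):
        if not msa or len(msa[0][1]) < min_overlap:
            raise ValueError(f"alignment {name}: shorter than {min_overlap} columns")
    fa, fb = column_frequencies(msa_a), column_frequencies(msa_b)
    s_aa = _profile_similarity(fa, fa, min_overlap)
    s_bb = _profile_similarity(fb, fb, min_overlap)
    s_ab = _profile_similarity(fa, fb, min_overlap)
    return ProfilePair(id_a, id_b, s_ab, s_aa, s_bb)


# ------------------------------------------------------------------- UPGMA

@dataclass
class DendroNode:
    height: float
    labels: tuple[str, ...]
    children: tuple["DendroNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GuideDendrogram:
    root: DendroNode
    merge_depth: float
    groups: list[tuple[str, ...]]  # merged-tip groups at depth < merge_depth


def _validate_matrix(d: np.ndarray):
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("diagonal must be zero")
    return d


def upgma(dist: np.ndarray, labels: list[str]) -> DendroNode:
    """UPGMA with lexicographic tie-breaking; node height = join distance / 2."""
    d = _validate_matrix(dist)
    nodes = {i: DendroNode(0.0, (labels[i],)) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    dd = {(i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    nxt = len(labels)
    while len(nodes) > 1:
        # smallest distance; ties broken by the lexicographically least label pair
        best = min(
            dd.items(),
            key=lambda kv: (kv[1], tuple(sorted(nodes[kv[0][0]].labels + nodes[kv[0][1]].labels))),
        )
        (i, j), dij = best
        a, b = nodes.pop(i), nodes.pop(j)
        merged = DendroNode(
            dij / 2.0, tuple(sorted(a.labels + b.labels)), (a, b)
        )
        for k in list(nodes):
            if k == nxt:
                continue
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            dd[(min(k, nxt), max(k, nxt))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dd.pop((i, j))
        nodes[nxt] = merged
        sizes[nxt] = sizes.pop(i) + sizes.pop(j)
        nxt += 1
    return nodes.popitem()[1]


def _tip_groups(node: DendroNode, merge_depth: float) -> list[tuple[str, ...]]:
    if node.height < merge_depth:
        return [node.labels]
    out = []
    for ch in node.children:
        out.extend(_tip_groups(ch, merge_depth))
    return out


def build_guide_dendrogram(
    dist: np.ndarray, labels: list[str], merge_depth: float = 1.5
) -> GuideDendrogram:
    """UPGMA guide dendrogram; maximal subtrees with root height < merge_depth
    become merged-tip groups (ordered by their lexicographically first tip)."""
    root = upgma(dist, labels)
    groups = sorted(_tip_groups(root, merge_depth), key=lambda g: g[0])
    return GuideDendrogram(root, merge_depth, groups)


def to_newick(node: DendroNode) -> str:
    def rec(n: DendroNode, parent_height: float) -> str:
        bl = parent_height - n.height
        if n.is_leaf:
            return f"{n.labels[0]}:{bl:.6f}"
        inner = ",".join(rec(c, n.height) for c in n.children)
        return f"({inner}):{bl:.6f}"

    if node.is_leaf:
        return f"{node.labels[0]};"
    inner = ",".join(rec(c, node.height) for c in node.children)
    return f"({inner});"


def leaf_root_distances(node: DendroNode) -> dict[str, float]:
    """Path length from each leaf to the root (ultrametricity check)."""
    out: dict[str, float] = {}

    def rec2(n: DendroNode, dist_from_root: float):
        if n.is_leaf:
            out[n.labels[0]] = dist_from_root
            return
        for c in n.children:
            rec2(c, dist_from_root + (n.height - c.height))

    rec2(node, 0.0)
    return out


# -------------------------------------------------------- column filtering

@dataclass
class FilteredAlignment:
    msa: list[tuple[str, str]]
    kept_columns: list[int]
    gap_fraction: np.ndarray
    homogeneity: np.ndarray


def column_homogeneity(residues: list[str], matrix=None) -> float:
    """Normalized conservation of a column in [0, 1].

    h = (mean pairwise substitution score - expected random-pair score) /
        (mean self score of the residues present - expected random-pair score),
    clipped to [0, 1]; an all-identical column scores exactly 1, a column of
    residues drawn at random from the background scores ~0.
    """
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    res = [r for r in residues if r in AA_INDEX]
    if len(res) < 2:
        return 0.0
    q = 1 / 20
    e_rand = sum(
        q * q * matrix[a, b] for a in AA_ALPHABET for b in AA_ALPHABET
    )
    pair_scores = [
        matrix[res[i], res[j]]
        for i in range(len(res))
        for j in range(i + 1, len(res))
    ]
    mean_pair = float(np.mean(pair_scores))
    mean_self = float(np.mean([matrix[r, r] for r in res]))
    denom = mean_self - e_rand
    if denom <= 0:
        return 0.0
    return float(np.clip((mean_pair - e_rand) / denom, 0.0, 1.0))


def filter_alignment(
    msa: list[tuple[str, str]],
    max_gap_frac: float = 0.5,
    min_homogeneity: float = 0.1,
) -> FilteredAlignment:
    """Remove columns with > max_gap_frac gaps or homogeneity < min_homogeneity."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0][1])
    nseq = len(msa)
    matrix = substitution_matrices.load("BLOSUM62")
    gap_frac = np.empty(width)
    homog = np.empty(width)
    kept = []
    for j in range(width):
        col = [s[j].upper() for _, s in msa]
        gap_frac[j] = sum(c in _GAP_CHARS for c in col) / nseq
        homog[j] = column_homogeneity(col, matrix)
        if gap_frac[j] <= max_gap_frac and homog[j] >= min_homogeneity:
            kept.append(j)
    out = [(name, "".join(s[j] for j in kept)) for name, s in msa]
    return FilteredAlignment(out, kept, gap_frac, homog)


# ---------------------------------------------------- gene-sharing network

def gene_sharing_network(
    genome_clusters: dict[str, set],
    n_universe: int | None = None,
    weight_min: float = 2.0,
):
    """Edges between genomes weighted by -log10 hypergeometric tail
    probability of sharing at least the observed number of protein clusters.

    ``genome_clusters`` maps genome id -> set of protein-cluster ids;
    ``n_universe`` defaults to the number of distinct clusters observed.
    Returns a networkx Graph; edges below ``weight_min`` are dropped.
    """
    import networkx as nx

    universe = set()
    for cl in genome_clusters.values():
        universe |= cl
    m = n_universe if n_universe is not None else len(universe)
    g = nx.Graph()
    g.add_nodes_from(sorted(genome_clusters))
    ids = sorted(genome_clusters)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            k = len(genome_clusters[ga] & genome_clusters[gb])
            if k == 0:
                continue
            na, nb = len(genome_clusters[ga]), len(genome_clusters[gb])
            p = float(stats.hypergeom.sf(k - 1, m, na, nb))
            w = -math.log10(max(p, 1e-300))
            if w >= weight_min:
                g.add_edge(ga, gb, weight=w, shared=k)
    return g
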