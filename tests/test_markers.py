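"""Profile construction, search calibration, and phage classification."""

import numpy as np
import pytest

from phagering import markers
from phagering.circular import Contig, find_terminal_repeat
from phagering.synthetic import _make_gene, reverse_translate
from phagering.util import AA_ALPHABET, random_dna, random_protein, revcomp


def _toy_msa(rng, n=12, width=80, rate=0.1):
    aas = np.array(list(AA_ALPHABET))
    anc = rng.integers(0, 20, size=width)
    seqs = []
    for i in range(n):
        s = anc.copy()
        mut = rng.random(width) < rate
        s[mut] = rng.integers(0, 20, size=int(mut.sum()))
        seqs.append((f"s{i}", "".join(aas[s])))
    return seqs


class TestBuildProfile:
    def test_identical_sequences_maximal_self_score(self, rng):
        seq = random_protein(rng, 60)
        prof = markers.build_profile([("a", seq), ("b", seq)], "p")
        best_possible = float(prof.log_odds.max(axis=1).sum())
        assert markers.score_protein(prof, seq) == pytest.approx(best_possible)

    def test_half_and_half_column_symmetric(self):
        msa = [("a", "A" * 12), ("b", "V" * 12)]
        prof = markers.build_profile(msa, "p")
        i_a, i_v = AA_ALPHABET.index("A"), AA_ALPHABET.index("V")
        assert np.allclose(prof.log_odds[:, i_a], prof.log_odds[:, i_v])

    def test_absent_residue_negative_log_odds(self, rng):
        msa = _toy_msa(rng)
        prof = markers.build_profile(msa, "p")
        # a residue absent from a column of 12 sequences: count 0 + pseudocount
        counts_w = AA_ALPHABET.index("W")
        col0_residues = {s[0] for _, s in msa}
        if "W" not in col0_residues:
            assert prof.log_odds[0, counts_w] < 0

    def test_high_gap_columns_dropped(self, rng):
        msa = _toy_msa(rng, n=10, width=40)
        gappy = [(n, s[:5] + "-" * 6 + s[11:]) if i < 8 else (n, s)
                 for i, (n, s) in enumerate(msa)]
        prof = markers.build_profile(gappy, "p")
        assert prof.ncol == 34  # 6 columns at 80% gaps removed

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            markers.build_profile([("a", "ACDEFGHIKLMN"), ("b", "ACDEF")], "p")


class TestSearch:
    def test_emitted_protein_found_among_decoys(self, profiles, rng):
        terl = profiles[0]
        prots = {f"d{i}": random_protein(rng, 140) for i in range(500)}
        prots["planted"] = markers.emit_sequence(terl, rng)
        hits = markers.search_profiles(prots, [terl], e_cutoff=0.01)
        assert any(h.protein_id == "planted" and h.evalue < 0.01 for h in hits)

    def test_decoys_rarely_hit(self, profiles, rng):
        # >= 99% of shuffled proteins produce no hit at e < 0.01
        prots = {f"d{i}": random_protein(rng, 140) for i in range(1000)}
        hits = markers.search_profiles(prots, list(profiles), e_cutoff=0.01)
        assert len({h.protein_id for h in hits}) <= 10

    def test_search_deterministic(self, profiles, rng):
        prots = {f"d{i}": random_protein(rng, 100) for i in range(20)}
        prots["m"] = markers.emit_sequence(profiles[1], rng)
        h1 = markers.search_profiles(prots, list(profiles), 0.05)
        h2 = markers.search_profiles(prots, list(profiles), 0.05)
        assert h1 == h2

    def test_evalue_cutoff_monotonic(self, profiles, rng):
        prots = {f"d{i}": random_protein(rng, 120) for i in range(30)}
        prots["m"] = markers.emit_sequence(profiles[2], rng)
        loose = {(h.protein_id, h.profile_name)
                 for h in markers.search_profiles(prots, list(profiles), 0.05)}
        strict = {(h.protein_id, h.profile_name)
                  for h in markers.search_profiles(prots, list(profiles), 0.001)}
        assert strict <= loose

    def test_batch_scoring_matches_reference(self, profiles, rng):
        prof = profiles[0]

        def brute(seq):
            from phagering.util import AA_INDEX
            idx = [AA_INDEX.get(a, -1) for a in seq]
            best = 0.0
            for d in range(-(prof.ncol - 1), len(idx)):
                run = 0.0
                for j in range(prof.ncol):
                    i = d + j
                    if i < 0:
                        continue
                    if i >= len(idx):
                        break
                    s = prof.log_odds[j, idx[i]] if idx[i] >= 0 else 0.0
                    run = max(run, 0.0) + s
                    best = max(best, run)
            return best

        seqs = [random_protein(rng, int(rng.integers(5, 120))) for _ in range(8)]
        seqs.append(markers.emit_sequence(prof, rng)[30:90])
        got = markers.score_proteins_batch(prof, seqs)
        assert np.allclose(got, [brute(s) for s in seqs], atol=1e-5)


def _contig_with_gene(rng, length, aa_seq, pad_left=None):
    gene = _make_gene(rng, aa_seq)
    left = pad_left if pad_left is not None else (length - len(gene)) // 2
    right = length - len(gene) - left
    return random_dna(rng, left) + gene + random_dna(rng, right)


class TestClassify:
    def test_short_contig_rejected_despite_marker(self, profiles, rng):
        terl = profiles[0]
        seq = _contig_with_gene(rng, 2900, markers.emit_sequence(terl, rng))
        calls = markers.classify_contigs({"c": seq}, list(profiles))
        assert calls[0].round2_pass and not calls[0].is_phage

    def test_long_contig_with_marker_accepted(self, profiles, rng):
        portal = profiles[2]
        seq = _contig_with_gene(rng, 8000, markers.emit_sequence(portal, rng))
        calls = markers.classify_contigs({"c": seq}, list(profiles))
        assert calls[0].is_phage and "portal" in calls[0].markers_found

    def test_nonmarker_profile_hits_do_not_qualify(self, profiles, rng):
        other = markers.calibrate_profile(
            markers.build_profile(_toy_msa(rng, n=16, width=120), "other",
                                  category="other-phage")
        )
        seq = _contig_with_gene(rng, 8000, markers.emit_sequence(other, rng))
        calls = markers.classify_contigs({"c": seq}, list(profiles) + [other])
        (call,) = calls
        assert call.round1_pass and call.round2_pass and not call.is_phage

    def test_cutoff_ordering_enforced(self, profiles):
        with pytest.raises(ValueError):
            markers.classify_contigs({"c": "ACGT" * 1000}, list(profiles),
                                     e1=0.01, e2=0.05)

    def test_classification_rotation_invariant(self, profiles, rng):
        terl = profiles[0]
        core = _contig_with_gene(rng, 6000, markers.emit_sequence(terl, rng))
        results = []
        for shift in (0, 2500):
            rot = core[shift:] + core[:shift]
            contig = rot + rot[:80]
            call = find_terminal_repeat(Contig("c", contig))
            assert call.is_circular
            out = markers.classify_contigs(
                {"c": call.canonical_seq}, list(profiles),
                circular_flags={"c": True},
            )
            results.append((out[0].is_phage, out[0].markers_found))
        assert results[0] == results[1]

    def test_community_sensitivity_and_specificity(
        self, profiles, small_community
    ):
        """>=95% sensitivity, <=5% FPR for phage/plasmid discrimination."""
        contigs, truth = small_community
        calls = markers.classify_contigs(
            contigs, list(profiles),
            circular_flags={c: True for c in contigs if not c.startswith("linear")},
        )
        labels = dict(zip(truth.contigs.contig_id, truth.contigs.label))
        phage = [c for c in calls if labels[c.contig_id] == "phage"]
        decoy = [c for c in calls if labels[c.contig_id] != "phage"]
        assert sum(c.is_phage for c in phage) / len(phage) >= 0.95
        assert sum(c.is_phage for c in decoy) / len(decoy) <= 0.05
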