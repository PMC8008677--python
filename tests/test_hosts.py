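"""CRISPR spacer matching, host prediction, anti-CRISPR gate."""

import itertools

import numpy as np
import pytest

from phagering.genes import Orf
from phagering.hosts import (
    Spacer,
    acr_gate,
    build_directons,
    match_spacers,
    predict_hosts,
    screen_acr,
)
from phagering.util import random_dna, revcomp


def brute_force_matches(spacer_seq, genome, id_min=95.0, cov_min=95.0):
    """Sliding-window oracle over every offset and both strands."""
    out = set()
    slen = len(spacer_seq)
    for strand, q in (("+", spacer_seq), ("-", revcomp(spacer_seq))):
        for o in range(-slen + 1, len(genome)):
            a_s, a_e = max(0, -o), min(slen, len(genome) - o)
            if a_e <= a_s:
                continue
            seg = genome[o + a_s : o + a_e]
            m = sum(x == y for x, y in zip(q[a_s:a_e], seg))
            span = a_e - a_s
            if 100 * m / span >= id_min and 100 * span / slen >= cov_min:
                out.add((o + a_s, o + a_e, strand))
    return out


class TestMatchSpacers:
    def test_exact_match_full_scores(self, rng):
        g = random_dna(rng, 20000)
        sp = Spacer("s", g[500:532], {})
        (m,) = match_spacers([sp], {"g": g})
        assert (m.start, m.end) == (500, 532)
        assert m.identity == 100.0 and m.coverage == 100.0

    def test_one_mismatch_accepted_two_rejected(self, rng):
        g = random_dna(rng, 10000)
        proto = g[400:432]

        def with_mismatches(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
            return "".join(out)

        one = match_spacers([Spacer("s1", with_mismatches(proto, [10]), {})], {"g": g})
        two = match_spacers([Spacer("s2", with_mismatches(proto, [10, 20]), {})], {"g": g})
        assert len(one) == 1 and one[0].identity == pytest.approx(100 * 31 / 32)
        assert len(two) == 0  # 30/32 = 93.75 < 95

    def test_equals_sliding_window_oracle(self, rng):
        g = random_dna(rng, 3000)
        spacers = [Spacer(f"s{i}", g[i * 50 : i * 50 + 32], {}) for i in range(5)]
        spacers.append(Spacer("rc", revcomp(g[777:809]), {}))
        spacers.append(Spacer("rand", random_dna(rng, 32), {}))
        got = {
            (m.spacer_id, m.start, m.end, m.strand)
            for m in match_spacers(spacers, {"g": g})
        }
        want = {
            (sp.id, s, e, strand)
            for sp in spacers
            for (s, e, strand) in brute_force_matches(sp.seq, g)
        }
        assert got == want

    def test_reverse_complement_genome_mirrors_matches(self, rng):
        g = random_dna(rng, 5000)
        spacers = [Spacer("s", g[1000:1032], {})]
        fwd = match_spacers(spacers, {"g": g})
        rev = match_spacers(spacers, {"g": revcomp(g)})
        n = len(g)
        assert {(n - m.end, n - m.start) for m in rev} == {
            (m.start, m.end) for m in fwd
        }

    def test_circular_match_across_origin(self, rng):
        g = random_dna(rng, 4000)
        proto = g[-16:] + g[:16]
        got = match_spacers([Spacer("s", proto, {})], {"g": g}, circular=True)
        assert any(m.start == 4000 - 16 for m in got)
        linear = match_spacers([Spacer("s", proto, {})], {"g": g}, circular=False)
        assert not linear


class TestPredictHosts:
    def _matches(self, rng, genera):
        g = random_dna(rng, 8000)
        spacers, phages = [], {"p1": g}
        for i, genus in enumerate(genera):
            spacers.append(Spacer(f"s{i}", g[100 + 40 * i : 132 + 40 * i],
                                  {"genus": genus, "phylum": "Bacteroidota"}))
        return spacers, phages

    def test_single_genus_propagated(self, rng):
        spacers, phages = self._matches(rng, ["Bacteroides"])
        preds, _ = predict_hosts(match_spacers(spacers, phages), spacers)
        assert preds[0].taxa_by_rank["genus"] == {"Bacteroides"}
        assert not preds[0].multi_genus

    def test_multi_genus_flag(self, rng):
        spacers, phages = self._matches(rng, ["Bacteroides", "Prevotella"])
        preds, _ = predict_hosts(match_spacers(spacers, phages), spacers)
        assert preds[0].multi_genus

    def test_cross_targeting_reported(self, rng):
        core = random_dna(rng, 6000)
        shared = core[100:132]
        phages = {"p1": core, "p2": random_dna(rng, 3000) + shared + random_dna(rng, 3000)}
        spacers = [Spacer("s", shared, {"genus": "Bacteroides"})]
        _, cross = predict_hosts(match_spacers(spacers, phages), spacers)
        assert cross and cross[0][1] == ("p1", "p2")

    def test_unknown_spacer_rejected(self, rng):
        spacers, phages = self._matches(rng, ["Bacteroides"])
        matches = match_spacers(spacers, phages)
        with pytest.raises(KeyError):
            predict_hosts(matches, [])


class TestAcr:
    def test_gate_truth_table_exhaustive(self, rng):
        """All 16 combinations of the four criteria, randomized instances."""
        for hi_score, small_directon, hth, db_hit in itertools.product(
            [True, False], repeat=4
        ):
            for _ in range(5):
                score = (0.9 + 0.1 * rng.random()) if hi_score else 0.89 * rng.random()
                dlen = int(rng.integers(1, 6)) if small_directon else int(rng.integers(6, 12))
                expected = hi_score and small_directon and hth and not db_hit
                assert acr_gate(score, dlen, hth, db_hit) is expected

    def test_directon_construction(self):
        orfs = [
            Orf("c", 0, 300, "+", "M" * 99, "standard-bacterial"),
            Orf("c", 350, 650, "+", "M" * 99, "standard-bacterial"),
            Orf("c", 1200, 1500, "+", "M" * 99, "standard-bacterial"),  # gap > 250
            Orf("c", 1550, 1850, "-", "M" * 99, "standard-bacterial"),  # strand flip
        ]
        d = build_directons(orfs)
        assert [len(x) for x in d] == [2, 1, 1]

    def test_screen_acr_examples(self, rng):
        from phagering.util import random_protein

        prots = {"a": random_protein(rng, 80), "b": random_protein(rng, 90),
                 "c": random_protein(rng, 100)}
        orfs = [
            Orf("c", 0, 250, "+", prots["a"], "standard-bacterial"),
            Orf("c", 300, 580, "+", prots["b"], "standard-bacterial"),
            Orf("c", 600, 910, "+", prots["c"], "standard-bacterial"),
        ]
        orfs = [Orf("ctg", o.start, o.end, o.strand, prots[pid], "standard-bacterial")
                for o, pid in zip(orfs, prots)]
        ids = {o.protein_id: pid for o, pid in zip(orfs, prots)}
        prot_by_orf = {o.protein_id: prots[ids[o.protein_id]] for o in orfs}
        scores = {o.protein_id: s for o, s in zip(orfs, (0.95, 0.85, 0.95))}
        hth = {orfs[2].protein_id}
        out = {c.protein_id: c for c in screen_acr(
            prot_by_orf, scores, orfs, hth_flags=hth, strong_db_hits=set()
        )}
        assert out[orfs[0].protein_id].verdict is True       # 0.95, directon 3, HTH
        assert out[orfs[1].protein_id].verdict is False      # score 0.85
        out2 = {c.protein_id: c for c in screen_acr(
            prot_by_orf, scores, orfs, hth_flags=hth,
            strong_db_hits={orfs[0].protein_id},
        )}
        assert out2[orfs[0].protein_id].verdict is False     # strong DB hit

    def test_oversized_directon_rejected(self, rng):
        from phagering.util import random_protein

        orfs = [Orf("c", i * 300, i * 300 + 250, "+", random_protein(rng, 80),
                    "standard-bacterial") for i in range(6)]
        prots = {o.protein_id: o.aa_seq for o in orfs}
        scores = {o.protein_id: 0.95 for o in orfs}
        hth = {orfs[0].protein_id}
        out = screen_acr(prots, scores, orfs, hth_flags=hth)
        assert all(c.verdict is False for c in out)  # directon of 6 genes

    def test_score_validation(self, rng):
        with pytest.raises(ValueError):
            screen_acr({"a": "MKL" * 30}, {"a": 1.2}, [])
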