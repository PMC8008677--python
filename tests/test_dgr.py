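"""DGR repeat-pair discovery and the adenine-bias hallmark test."""

import numpy as np
import pytest
from scipy import stats

from phagering.dgr import (
    adenine_bias_test,
    count_substituted_adenine_sites,
    find_repeat_pairs,
    render_alignment,
)
from phagering.synthetic import DgrSpec, generate_dgr_genome, make_tr, mutate_vr
from phagering.util import random_dna


def _interval_close(iv, truth, min_cover=0.9, max_slack=40):
    """The reported interval covers most of the planted one; qualifying
    segments may extend a few bases into accidentally matching flanks."""
    ov = max(0, min(iv[1], truth[1]) - max(iv[0], truth[0]))
    extra = (iv[1] - iv[0]) - ov
    return ov >= min_cover * (truth[1] - truth[0]) and extra <= max_slack


class TestFindRepeatPairs:
    def test_planted_pair_found_in_stage1(self):
        spec = DgrSpec(tr_length=120, adenine_mutation_fraction=0.5,
                       vr_distance_from_rt=4000)
        genome, truth = generate_dgr_genome(spec, seed=11)
        pairs = find_repeat_pairs(genome, truth["rt_locus"])
        hit = [p for p in pairs
               if _interval_close((p.tr_start, p.tr_end), truth["tr_locus"])
               and _interval_close((p.vr_start, p.vr_end), truth["vrs"][0]["locus"])]
        assert hit and hit[0].within_10kb_window and hit[0].identity >= 75

    def test_distal_vr_found_only_in_stage2(self):
        # first VR near the RT anchors stage 1; a second copy planted 20 kb
        # away is only reachable by the genome-wide template search
        spec = DgrSpec(tr_length=120, adenine_mutation_fraction=0.4, n_vr=1,
                       vr_distance_from_rt=4_000)
        genome, truth = generate_dgr_genome(spec, seed=5, genome_length=40_000)
        rng = np.random.default_rng(8)
        distal_vr, _ = mutate_vr(rng, truth["tr_seq"], 0.4)
        pos = truth["rt_locus"][0] + 20_000
        genome = genome[:pos] + distal_vr + genome[pos + len(distal_vr):]
        pairs = find_repeat_pairs(genome, truth["rt_locus"])
        distal = [p for p in pairs
                  if _interval_close((p.vr_start, p.vr_end), (pos, pos + 120))]
        assert distal and not distal[0].within_10kb_window
        near = [p for p in pairs
                if _interval_close((p.vr_start, p.vr_end), truth["vrs"][0]["locus"])]
        assert near and near[0].within_10kb_window

    def test_low_identity_pair_rejected(self, rng):
        # 70% identity < the 75% floor of the genome-wide search
        genome = list(random_dna(rng, 20000))
        tr = make_tr(rng, 100)
        vr = list(tr)
        for i in rng.choice(100, size=30, replace=False):  # 70% identity
            vr[i] = "ACGT"[("ACGT".index(vr[i]) + 1) % 4]
        genome[5000:5100] = list(tr)
        genome[9000:9100] = vr
        pairs = find_repeat_pairs("".join(genome), (4000, 4600))
        assert not any(
            _interval_close((p.vr_start, p.vr_end), (9000, 9100)) for p in pairs
        )

    def test_missing_rt_locus_rejected(self, rng):
        with pytest.raises(ValueError):
            find_repeat_pairs(random_dna(rng, 5000), None)

    def test_matches_diagonal_scan_oracle(self, rng):
        """Naive full-diagonal oracle on a small genome."""
        genome = list(random_dna(rng, 8000))
        tr = make_tr(rng, 100)
        vr, _ = mutate_vr(rng, tr, 0.4)
        genome[2000:2100] = list(tr)
        genome[5000:5100] = list(vr)
        g = "".join(genome)
        pairs = find_repeat_pairs(g, (1500, 2000))
        found = any(
            _interval_close((p.tr_start, p.tr_end), (2000, 2100))
            and _interval_close((p.vr_start, p.vr_end), (5000, 5100))
            for p in pairs
        )
        # oracle: direct comparison of the two planted loci
        m = np.array([a == b for a, b in zip(tr, vr)])
        assert found == (m.mean() >= 0.85)


class TestAdenineBias:
    def test_strong_adenine_bias_detected(self):
        """Substitutions at 15 of 40 adenines, none elsewhere."""
        rng = np.random.default_rng(2)
        tr = "".join(rng.permutation(list("A" * 40 + "C" * 30 + "G" * 30 + "T" * 20)))
        a_pos = [i for i, b in enumerate(tr) if b == "A"]
        vr = list(tr)
        for i in rng.choice(len(a_pos), size=15, replace=False):
            vr[a_pos[i]] = "C"
        rep = adenine_bias_test(tr, ["".join(vr)])
        expected_p = stats.binom.sf(14, 15, 40 / 120)
        assert rep.n_a_substituted == 15 and rep.n_nona_substituted == 0
        assert rep.p_value == pytest.approx(expected_p, rel=1e-9)
        assert rep.p_value < 1e-6 and rep.hypervariable

    def test_identical_repeats_not_hypervariable(self, rng):
        tr = make_tr(rng, 100)
        rep = adenine_bias_test(tr, [tr])
        assert rep.p_value == 1.0 and not rep.hypervariable

    def test_vr_order_exchangeable(self, rng):
        tr = make_tr(rng, 120)
        vrs = [mutate_vr(rng, tr, 0.5)[0] for _ in range(3)]
        r1 = adenine_bias_test(tr, vrs)
        r2 = adenine_bias_test(tr, vrs[::-1])
        assert r1 == r2

    def test_type_one_error_controlled(self):
        """Uniform-substitution null: false-positive rate <= alpha-ish."""
        rng = np.random.default_rng(7)
        fp = 0
        n_rep = 200
        for _ in range(n_rep):
            tr = make_tr(rng, 150)
            vr = list(tr)
            for i in rng.choice(150, size=8, replace=False):
                vr[i] = "ACGT"[("ACGT".index(vr[i]) + int(rng.integers(1, 4))) % 4]
            if adenine_bias_test(tr, ["".join(vr)], alpha=0.01).hypervariable:
                fp += 1
        assert fp / n_rep <= 0.05

    def test_power_on_generator_dgrs(self):
        """>=95% detection at adenine fraction 0.3 with >=40 template adenines."""
        rng = np.random.default_rng(13)
        detected = 0
        n_rep = 60
        for _ in range(n_rep):
            tr = make_tr(rng, 160, min_adenines=40)
            vrs = [mutate_vr(rng, tr, 0.3)[0] for _ in range(2)]
            if adenine_bias_test(tr, vrs).hypervariable:
                detected += 1
        assert detected / n_rep >= 0.95

    def test_empty_vr_set_rejected(self, rng):
        with pytest.raises(ValueError):
            adenine_bias_test(make_tr(rng, 100), [])


def test_count_substituted_adenine_sites():
    msa = [
        ("TR", "AACGTA"),
        ("VR1", "GACGTA"),   # substitution at adenine column 0
        ("VR2", "AACGTC"),   # substitution at adenine column 5
        ("VR3", "A-CGTC"),   # gap ignored; column 5 already counted
    ]
    assert count_substituted_adenine_sites(msa) == 2


def test_render_alignment_marks_substitutions(rng):
    tr = make_tr(rng, 60)
    vr, muts = mutate_vr(rng, tr, 0.5)
    text = render_alignment(tr, [vr])
    assert "TR" in text and "VR1" in text and "*" in text
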