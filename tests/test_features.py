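"""Log-odds scanning, feature vectorization and presence calls."""

import numpy as np
import pytest

from motifreg.features import (
    LogOddsMatrix,
    best_match_score,
    build_log_odds,
    build_match_map,
    presence_calls,
    reverse_complement,
    scan_matches,
    shift_and_normalize,
    vectorize,
)

from conftest import make_motif, make_peak_seq, random_dna

IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_best(seq, lom, strands="both"):
    """Exhaustive enumeration over offsets x strands (independent oracle)."""
    L = lom.lom.shape[0]
    candidates = []
    for strand, matrix in [("+", lom.lom), ("-", lom.lom[::-1, ::-1])]:
        if strands == "one" and strand == "-":
            continue
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            score = sum(matrix[p, IDX[a]] if a != "N" else 0.0
                        for p, a in enumerate(window))
            candidates.append((score, off, strand))
    # ties: forward strand first, then smallest offset
    return max(candidates, key=lambda c: (c[0], c[2] == "+", -c[1]))


class TestBuildLogOdds:
    def test_consensus_two_bits(self):
        lom = build_log_odds(make_motif("m", "AC"))
        assert lom.lom[0, IDX["A"]] == pytest.approx(2.0)
        assert lom.lom[1, IDX["C"]] == pytest.approx(2.0)
        assert lom.max_score == pytest.approx(4.0)

    def test_uniform_motif_all_zero(self):
        lom = build_log_odds(make_motif("m", "AC", p=0.25))
        assert np.allclose(lom.lom, 0.0)
        assert lom.max_score == 0.0

    def test_zero_probability_gives_minus_inf(self):
        lom = build_log_odds(make_motif("m", "A", p=1.0, pseudocount=0.0))
        assert np.isneginf(lom.lom[0, IDX["T"]])

    def test_max_score_is_row_max_sum(self, rng):
        probs = rng.dirichlet(np.ones(4), size=6)
        from motifreg.io import MotifModel
        motif = MotifModel(id="m", probs=probs, pseudocount=0.01)
        lom = build_log_odds(motif)
        expected = sum(max(lom.lom[p, a] for a in range(4)) for p in range(6))
        assert lom.max_score == pytest.approx(expected, abs=1e-9)


class TestBestMatch:
    def test_consensus_found_at_offset(self):
        lom = build_log_odds(make_motif("m", "AC"))
        score, offset, strand = best_match_score("TTACG", lom)
        assert (score, offset, strand) == (pytest.approx(4.0), 2, "+")

    def test_uniform_motif_scores_zero(self):
        lom = build_log_odds(make_motif("m", "ACG", p=0.25))
        score, _, _ = best_match_score("TTTTTTTT", lom)
        assert score == 0.0

    def test_reverse_strand_match(self):
        # consensus ACG appears only as reverse complement (CGT on forward)
        lom = build_log_odds(make_motif("m", "ACG"))
        score, offset, strand = best_match_score("TTCGTTT", lom)
        assert strand == "-" and score == pytest.approx(6.0) and offset == 2

    def test_too_short_sequence(self):
        lom = build_log_odds(make_motif("m", "ACGT"))
        with pytest.raises(ValueError):
            best_match_score("AC", lom)

    def test_exhaustive_oracle_100_random_pairs(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 9))
            seq = random_dna(rng, int(rng.integers(L, 40)))
            probs = rng.dirichlet(np.ones(4) * 0.5, size=L)
            from motifreg.io import MotifModel
            lom = build_log_odds(MotifModel(id="m", probs=probs, pseudocount=0.01))
            got = best_match_score(seq, lom, strands="both")
            exp_score, exp_off, exp_strand = brute_force_best(seq, lom)
            assert got[0] == pytest.approx(exp_score, abs=1e-9)
            assert (got[1], got[2]) == (exp_off, exp_strand)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 50)
            probs = rng.dirichlet(np.ones(4), size=5)
            from motifreg.io import MotifModel
            lom = build_log_odds(MotifModel(id="m", probs=probs, pseudocount=0.01))
            s1, _, _ = best_match_score(seq, lom, strands="both")
            s2, _, _ = best_match_score(reverse_complement(seq), lom, strands="both")
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_n_bases_score_zero(self):
        lom = build_log_odds(make_motif("m", "AA", p=1.0, pseudocount=0.0))
        score, _, _ = best_match_score("NN", lom, strands="one")
        assert score == 0.0


def naive_vectorize(seqs, motifs, strands="both"):
    """Triple-loop reimplementation of the vectorization recipe."""
    loms = [build_log_odds(m) for m in motifs]
    raw = np.array([
        [brute_force_best(seq, lom, strands)[0] - lom.max_score for lom in loms]
        for seq in seqs
    ])
    shifted = raw - raw.min(axis=1, keepdims=True)
    V = shifted / np.linalg.norm(shifted, axis=1, keepdims=True)
    return raw, V


class TestVectorize:
    def motifs(self):
        # 8-bp motifs: chance double-perfect matches (which degenerate a
        # feature row) are vanishingly rare in short random fixtures
        return [make_motif("m1", "ACGTACGT", p=0.97, pseudocount=0.01),
                make_motif("m2", "GGGGAAAA", p=0.92, pseudocount=0.01)]

    def test_perfect_consensus_raw_zero_and_row_max(self):
        peaks = [make_peak_seq("TTACGTACGTTT")]
        motifs = [make_motif("m1", "ACGTACGT", p=0.97, pseudocount=0.01),
                  make_motif("m2", "GGGGAAAA", p=0.97, pseudocount=0.01)]
        fm = vectorize(peaks, motifs, strands="one")
        assert fm.raw[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert fm.raw[0, 1] < 0
        assert fm.V[0, 0] == fm.V[0].max()

    def test_shift_normalize_arithmetic(self):
        V = shift_and_normalize(np.array([[-2.0, -6.0]]))
        assert np.allclose(V, [[1.0, 0.0]])

    def test_unit_row_norms_random_fixture(self, rng):
        peaks = [make_peak_seq(random_dna(rng, 60), score=float(rng.uniform(1, 50)),
                               pid=f"p{i}") for i in range(50)]
        fm = vectorize(peaks, self.motifs())
        assert np.allclose(np.linalg.norm(fm.V, axis=1), 1.0, atol=1e-9)
        assert (fm.raw <= 1e-12).all()
        assert (fm.V >= 0).all()
        assert np.allclose(fm.y, [np.log(ps.peak.score) for ps in peaks])

    def test_matches_naive_triple_loop(self, rng):
        from motifreg.io import MotifModel
        motifs = [MotifModel(id=f"m{j}", probs=rng.dirichlet(np.ones(4), size=int(rng.integers(2, 10))),
                             pseudocount=0.01) for j in range(10)]
        peaks = [make_peak_seq(random_dna(rng, 50), score=float(rng.uniform(1, 50)),
                               pid=f"p{i}") for i in range(20)]
        fm = vectorize(peaks, motifs)
        raw_exp, V_exp = naive_vectorize([ps.seq for ps in peaks], motifs)
        assert np.allclose(fm.raw, raw_exp, atol=1e-9)
        assert np.allclose(fm.V, V_exp, atol=1e-9)

    def test_scaling_all_loms_leaves_V_invariant(self, rng):
        peaks = [make_peak_seq(random_dna(rng, 40), pid=f"p{i}") for i in range(5)]
        motifs = self.motifs()
        loms = [build_log_odds(m) for m in motifs]
        fm1 = vectorize(peaks, motifs, loms=loms)
        scaled = [LogOddsMatrix(lom.motif_id, 3.7 * lom.lom) for lom in loms]
        fm2 = vectorize(peaks, motifs, loms=scaled)
        assert np.allclose(fm2.raw, 3.7 * fm1.raw, atol=1e-9)
        assert np.allclose(fm2.V, fm1.V, atol=1e-9)

    def test_single_motif_degenerate_row_rejected(self):
        with pytest.raises(ValueError, match="2 motifs"):
            vectorize([make_peak_seq("TTACGTTT")], [make_motif("m1", "ACGT")])

    def test_mixed_widths_rejected(self):
        peaks = [make_peak_seq("ACGTACGT"), make_peak_seq("ACGT", start=100)]
        with pytest.raises(ValueError, match="width"):
            vectorize(peaks, self.motifs())


class TestPresenceCalls:
    def test_perfect_match_always_present(self):
        peaks = [make_peak_seq("TTACGTTT", pid="p0")]
        mm = build_match_map(peaks, [make_motif("m1", "ACGT"), make_motif("m2", "GGGG")])
        B = presence_calls(mm, alpha=1.0)
        assert B[0, 0] == 1 and B[0, 1] == 0

    def test_threshold_arithmetic(self):
        # best match 3 of max 4 bits => present at alpha 0.7, absent at 0.8
        peaks = [make_peak_seq("TTANG", pid="p0")]
        mm = build_match_map(peaks, [make_motif("m1", "AC"), make_motif("m2", "TT")])
        score = mm.best[("p0", "m1")].score
        alpha_lo = (score / 4.0) - 0.05
        alpha_hi = (score / 4.0) + 0.05
        assert presence_calls(mm, alpha=alpha_lo)[0, 0] == 1
        assert presence_calls(mm, alpha=alpha_hi)[0, 0] == 0

    def test_monotone_in_alpha(self, rng):
        peaks = [make_peak_seq(random_dna(rng, 30), pid=f"p{i}") for i in range(10)]
        motifs = [make_motif(f"m{j}", random_dna(rng, 4), p=0.9, pseudocount=0.01)
                  for j in range(4)]
        mm = build_match_map(peaks, motifs)
        prev = presence_calls(mm, alpha=0.1)
        for alpha in [0.3, 0.5, 0.7, 0.9, 1.0]:
            cur = presence_calls(mm, alpha=alpha)
            assert (cur <= prev).all()
            prev = cur

    def test_uniform_motif_always_present(self):
        peaks = [make_peak_seq("ACGTACGT", pid="p0")]
        mm = build_match_map(peaks, [make_motif("u", "AA", p=0.25), make_motif("c", "GG")])
        assert presence_calls(mm, alpha=0.8)[0, 0] == 1


def test_scan_matches_returns_all_hits_above_floor():
    lom = build_log_odds(make_motif("m", "AC"))
    hits = scan_matches("ACACAC", lom, min_score=4.0 - 1e-9, strands="one")
    assert [h.offset for h in hits] == [0, 2, 4]
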