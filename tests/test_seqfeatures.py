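"""Sequence features against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest

from lincscout.core import GenomeInterval, reverse_complement
from lincscout.seqfeatures import (
    Pwm,
    _distribution,
    coverage_fraction,
    cpg_oe,
    find_palindromes,
    kmer_names,
    kmer_vector,
    obs_exp_words,
    palindrome_coverage,
    pwm_scan,
    read_jaspar,
    read_meme,
    sliding_profile,
    write_meme,
)


def brute_kmer_freq(seq, k):
    counts = {}
    total = 0
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        counts[word] = counts.get(word, 0) + 1
        total += 1
    return {w: c / total for w, c in counts.items()}


class TestKmers:
    def test_acgt_dinucleotide_frequencies(self):
        vec = dict(zip(kmer_names([2]), kmer_vector("ACGT", [2])))
        assert vec["AC"] == vec["CG"] == vec["GT"] == pytest.approx(1 / 3)
        assert sum(v > 0 for v in vec.values()) == 3

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        names = kmer_names()
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=300))
            vec = dict(zip(names, kmer_vector(seq)))
            for k in (2, 3, 4):
                brute = brute_kmer_freq(seq, k)
                for word in itertools.product("ACGT", repeat=k):
                    word = "".join(word)
                    assert vec[word] == pytest.approx(brute.get(word, 0.0))

    def test_simplex_sum_without_n(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        assert kmer_vector(seq).sum() == pytest.approx(3.0)


class TestCpgOe:
    def test_hand_counted_example(self):
        # N_CG=3 (overlapping), N_C=N_G=3, L=6 -> 3*6/9 = 2.0
        assert cpg_oe("CGCGCG") == pytest.approx(2.0)

    def test_no_c_or_g_gives_zero(self):
        assert cpg_oe("AAAA") == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            n_cg = sum(seq[i : i + 2] == "CG" for i in range(len(seq) - 1))
            expected = (
                n_cg * len(seq) / (seq.count("C") * seq.count("G"))
                if seq.count("C") and seq.count("G")
                else 0.0
            )
            assert cpg_oe(seq) == pytest.approx(expected)


class TestCoverage:
    def test_full_and_empty(self):
        region = GenomeInterval("chr1", 100, 200)
        assert coverage_fraction(region, [GenomeInterval("chr1", 0, 500)]) == 1.0
        assert coverage_fraction(region, [GenomeInterval("chr1", 300, 400)]) == 0.0

    def test_half_overlapping_annotations_are_merged(self):
        region = GenomeInterval("chr1", 0, 100)
        ann = [GenomeInterval("chr1", 10, 50), GenomeInterval("chr1", 30, 70)]
        assert coverage_fraction(region, ann) == pytest.approx(60 / 100)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        region = GenomeInterval("chr1", 0, 300)
        for _ in range(30):
            ann = [
                GenomeInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 280, 8), rng.integers(1, 60, 8))
            ]
            per_base = np.zeros(300, dtype=bool)
            for iv in ann:
                per_base[iv.start : min(iv.end, 300)] = True
            assert coverage_fraction(region, ann) == pytest.approx(per_base.mean())


def brute_palindromes(seq, min_len, max_len):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for i in range(len(seq)):
        for j in range(i + min_len, min(i + max_len, len(seq)) + 1, 2):
            sub = seq[i:j]
            if any(b not in comp for b in sub):
                continue
            if sub != reverse_complement(sub):
                continue
            # maximal: not extendable by one base each side
            if (
                i > 0
                and j < len(seq)
                and seq[i - 1] in comp
                and comp[seq[i - 1]] == seq[j]
            ):
                continue
            out.append((i, j - i))
    return sorted(out)


class TestPalindromes:
    def test_ecori_site(self):
        assert find_palindromes("GAATTC", 6, 20) == [(0, 6)]

    def test_homopolymer_has_none(self):
        assert find_palindromes("AAAAAA", 4, 20) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert sorted(find_palindromes(seq, 6, 20)) == brute_palindromes(seq, 6, 20)


class TestSlidingProfile:
    def test_constant_feature_gives_flat_profile(self):
        anchors = [("chr1", 5000, "+"), ("chr1", 9000, "-")]
        prof = sliding_profile(anchors, lambda c, s, e: 3.5, flank=500, n_boot=50)
        assert np.allclose(prof.mean, 3.5)
        assert np.allclose(prof.lo, 3.5) and np.allclose(prof.hi, 3.5)

    def test_single_region_band_collapses(self):
        prof = sliding_profile(
            [("chr1", 2000, "+")], lambda c, s, e: float(s), flank=300, n_boot=50
        )
        assert np.allclose(prof.lo, prof.mean) and np.allclose(prof.hi, prof.mean)

    def test_mean_matches_per_window_average(self):
        rng = np.random.default_rng(5)
        anchors = [("chr1", int(t), "+") for t in rng.integers(3000, 9000, 20)]
        feat = lambda c, s, e: float((s * 31 + e) % 97)
        prof = sliding_profile(anchors, feat, flank=400, window=300, step=50, n_boot=10)
        for j, center in enumerate(prof.centers):
            vals = [feat("chr1", t + center - 150, t + center + 150) for _, t, _ in anchors]
            assert prof.mean[j] == pytest.approx(np.mean(vals))


class TestObsExpWords:
    def test_identical_sets_select_nothing(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(5)]
        frame = obs_exp_words(seqs, seqs)
        assert np.allclose(frame["fold_change"], 1.0)
        assert not frame["selected"].any()

    def test_constructed_cg_enrichment_is_selected(self):
        rng = np.random.default_rng(7)
        base = ["".join(rng.choice(list("ACGT"), size=500)) for _ in range(6)]
        enriched = []
        for seq in base:
            s = list(seq)
            for pos in rng.integers(0, 498, size=60):
                s[pos : pos + 2] = "CG"
            enriched.append("".join(s))
        frame = obs_exp_words(enriched, base).set_index("word")
        assert frame.loc["CG", "fold_change"] > 1.2
        assert frame.loc["CG", "selected"]

    def test_swapping_sets_inverts_fold_changes(self):
        rng = np.random.default_rng(8)
        a = ["".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.2, 0.3], size=300))]
        b = ["".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=300))]
        fwd = obs_exp_words(a, b).set_index("word")
        rev = obs_exp_words(b, a).set_index("word")
        common = fwd.index.intersection(rev.index)
        assert np.allclose(
            fwd.loc[common, "fold_change"], 1 / rev.loc[common, "fold_change"]
        )
        # selection is symmetric when the gates are reciprocal (lo = 1/hi);
        # the default 1.2 / 0.8 gates are slightly asymmetric by design
        # (restricted to words defined in both directions: a word unobserved in
        # one set has fold change 0 one way and no defined ratio the other way)
        fwd_r = obs_exp_words(a, b, fc_lo=1 / 1.2).set_index("word")
        rev_r = obs_exp_words(b, a, fc_lo=1 / 1.2).set_index("word")
        common_r = fwd_r.index.intersection(rev_r.index)
        sel_fwd = {w for w in common_r if fwd_r.loc[w, "selected"]}
        sel_rev = {w for w in common_r if rev_r.loc[w, "selected"]}
        assert sel_fwd == sel_rev


class TestPwm:
    def test_consensus_sequence_attains_maximum_score(self):
        pwm = Pwm.from_consensus("m", "ACGTACGT", 0.9)
        hit = pwm_scan(pwm.consensus(), pwm)
        dist = _distribution(pwm)
        assert hit.score == pytest.approx(
            dist.to_real(int(dist._scaled.max(axis=0).sum()))
        )
        assert hit.pvalue == min(
            dist.pvalue_scaled(s) for s in range(dist._sf.size - 1)
        )

    def test_width4_pvalues_match_enumeration(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 20, size=(4, 4))
        pwm = Pwm.from_counts("w4", counts)
        dist = _distribution(pwm)
        scores = []
        for word in itertools.product(range(4), repeat=4):
            scores.append(dist.score_window(np.array(word)))
        scores = np.array(scores)
        for s in np.unique(scores):
            p_enum = np.mean(scores >= s)  # uniform background
            assert dist.pvalue_scaled(int(s)) == pytest.approx(p_enum)

    def test_reverse_complement_input_same_best_score(self):
        rng = np.random.default_rng(10)
        pwm = Pwm.from_consensus("m", "GGGGCGGGGC", 0.85)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            a = pwm_scan(seq, pwm)
            b = pwm_scan(reverse_complement(seq), pwm)
            assert a.score == pytest.approx(b.score)

    def test_pvalues_monotone_in_score(self):
        pwm = Pwm.from_consensus("m", "ACGTAC", 0.8)
        dist = _distribution(pwm)
        sf = dist._sf
        assert np.all(np.diff(sf) <= 1e-15)

    def test_meme_round_trip(self, tmp_path):
        pwms = [Pwm.from_consensus("a", "ACGTACGT"), Pwm.from_consensus("b", "GGGCCC")]
        p = tmp_path / "m.meme"
        write_meme(pwms, p)
        back = read_meme(p)
        assert [m.id for m in back] == ["a", "b"]
        for x, y in zip(back, pwms):
            assert np.allclose(x.matrix, y.matrix, atol=1e-6)

    def test_jaspar_parse(self, tmp_path):
        text = (
            ">MA0001.1 test\n"
            "A [ 1 2 3 4 ]\n"
            "C [ 4 3 2 1 ]\n"
            "G [ 1 1 1 1 ]\n"
            "T [ 4 4 4 4 ]\n"
        )
        p = tmp_path / "j.pfm"
        p.write_text(text)
        (pwm,) = read_jaspar(p)
        assert pwm.width == 4
        assert pwm.matrix[0, 3] == pytest.approx(4 / 10)
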