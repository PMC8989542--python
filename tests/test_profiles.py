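"""Feature-anchored analytics: dinucleotide profiles, aligned signal means,
quartiles, poly(dA:dT) tracts, PWM site refinement."""

import re

import numpy as np
import pytest

from dnabend.genome import CScoreTrack
from dnabend.markov import PWM
from dnabend.profiles import (
    FeatureAnchorSet,
    SS_DINUCLEOTIDES,
    WW_DINUCLEOTIDES,
    aligned_mean_profile,
    dinucleotide_profile,
    find_polyA_tracts,
    pwm_refine_sites,
    quartile_stratify,
    standardize_track,
)

from conftest import random_seqs


def naive_dinucleotide_profile(seqs, motif_class):
    L = len(seqs[0])
    out = []
    for t in range(L - 1):
        out.append(sum(s[t : t + 2] in motif_class for s in seqs) / len(seqs))
    return np.array(out)


def naive_polyA_tracts(seq, exact_len):
    """Regex enumeration of maximal pure runs of exactly exact_len."""
    hits = []
    for base, strand in (("A", "+"), ("T", "-")):
        pat = f"(?<!{base}){base}{{{exact_len}}}(?!{base})"
        for m in re.finditer(pat, seq):
            start = m.start() + 1  # 1-based
            hits.append((start + (exact_len - 1) // 2, strand))
    return sorted(hits)


class TestDinucleotideProfile:
    def test_hand_counted_example(self):
        prof = dinucleotide_profile(["AATT", "AAGG"], WW_DINUCLEOTIDES)
        assert np.allclose(prof, [1.0, 0.5, 0.5])

    def test_three_classes_partition_to_one(self):
        seqs = random_seqs(50, 30, seed=0)
        ww = dinucleotide_profile(seqs, WW_DINUCLEOTIDES)
        ss = dinucleotide_profile(seqs, SS_DINUCLEOTIDES)
        rest = {a + b for a in "ACGT" for b in "ACGT"} - WW_DINUCLEOTIDES - SS_DINUCLEOTIDES
        other = dinucleotide_profile(seqs, rest)
        assert np.allclose(ww + ss + other, 1.0, atol=1e-12)

    def test_single_sequence_gives_indicators(self):
        prof = dinucleotide_profile(["ATGC"], WW_DINUCLEOTIDES)
        assert list(prof) == [1.0, 0.0, 0.0]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        seqs = random_seqs(40, 25, seed=seed)
        assert np.allclose(
            dinucleotide_profile(seqs, WW_DINUCLEOTIDES),
            naive_dinucleotide_profile(seqs, WW_DINUCLEOTIDES),
        )

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_profile(["AA", "AAA"], WW_DINUCLEOTIDES)


def _track(scores, start=1, chrom="c"):
    scores = np.asarray(scores, dtype=float)
    return CScoreTrack(chrom, np.arange(start, start + len(scores)), scores)


def _anchors(positions, strands=None, scores=None):
    n = len(positions)
    return FeatureAnchorSet(
        chrom=np.full(n, "c", dtype=object),
        position=np.array(positions),
        strand=None if strands is None else np.array(strands, dtype=object),
        score=None if scores is None else np.array(scores, dtype=float),
    )


class TestAlignedMeanProfile:
    def test_constant_track(self):
        prof = aligned_mean_profile(_track([3.0] * 20), _anchors([10, 11]), flank=2)
        assert np.allclose(prof.mean, 3.0)
        assert (prof.count == 2).all()

    def test_plus_minus_pair_averages_signal_and_mirror(self):
        sig = np.arange(1, 12, dtype=float)  # asymmetric signal at 1..11
        prof = aligned_mean_profile(
            _track(sig), _anchors([6, 6], strands=["+", "-"]), flank=3
        )
        fwd = sig[5 - 3 : 5 + 4]
        assert np.allclose(prof.mean, 0.5 * (fwd + fwd[::-1]))

    def test_edge_anchor_reduces_count_without_error(self):
        prof = aligned_mean_profile(_track([1.0] * 10), _anchors([1, 5]), flank=3)
        # offsets -3..-1 only reachable from the anchor at 5
        assert list(prof.count) == [1, 1, 1, 2, 2, 2, 2]

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=40)
        anchors = _anchors([10, 20, 30], strands=["+", "-", "+"])
        p1 = aligned_mean_profile(_track(sig), anchors, flank=5)
        p2 = aligned_mean_profile(_track(2.5 * sig + 1.0), anchors, flank=5)
        assert np.allclose(p2.mean, 2.5 * p1.mean + 1.0)

    def test_mirrored_genome_and_flipped_strands_leave_profile_unchanged(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=50)
        pos = np.array([12, 25, 40])
        strands = np.array(["+", "-", "+"], dtype=object)
        p1 = aligned_mean_profile(_track(sig), _anchors(pos, strands), flank=6)
        L = len(sig)
        flipped = np.where(strands == "+", "-", "+")
        p2 = aligned_mean_profile(
            _track(sig[::-1]), _anchors(L + 1 - pos, flipped), flank=6
        )
        assert np.allclose(p1.mean, p2.mean)
        assert np.array_equal(p1.count, p2.count)

    def test_no_overlap_error(self):
        with pytest.raises(ValueError):
            aligned_mean_profile(_track([1.0, 2.0]), _anchors([100]), flank=1)


class TestQuartiles:
    def test_eight_distinct_scores_split_two_each(self):
        a = _anchors(list(range(1, 9)), scores=[3, 1, 7, 5, 8, 2, 6, 4])
        qs = quartile_stratify(a)
        assert [len(q) for q in qs] == [2, 2, 2, 2]
        assert sorted(np.concatenate([q.score for q in qs])) == list(range(1, 9))
        assert set(qs[0].score) == {1, 2} and set(qs[3].score) == {7, 8}

    def test_union_is_input(self):
        rng = np.random.default_rng(0)
        a = _anchors(list(range(1, 42)), scores=rng.normal(size=41))
        qs = quartile_stratify(a)
        assert sum(len(q) for q in qs) == 41

    def test_boundary_ties_go_to_lower_quartile(self):
        scores = [1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0]
        qs = quartile_stratify(_anchors(list(range(1, 9)), scores=scores))
        # 25th percentile = 1, 50th = 1.5, 75th = 2: the 2.0 ties sit at the
        # 75th-percentile boundary and fall in Q3, leaving Q4 empty
        assert [len(q) for q in qs] == [4, 0, 4, 0]

    def test_matches_naive_selection(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=103)
        qs = quartile_stratify(_anchors(list(range(1, 104)), scores=scores))
        cuts = np.percentile(scores, [25, 50, 75])
        naive = [
            np.sort(scores[(scores > lo if lo is not None else np.ones_like(scores, bool))
                           & (scores <= hi if hi is not None else np.ones_like(scores, bool))])
            for lo, hi in [(None, cuts[0]), (cuts[0], cuts[1]),
                           (cuts[1], cuts[2]), (cuts[2], None)]
        ]
        for q, expect in zip(qs, naive):
            assert np.allclose(np.sort(q.score), expect)

    def test_missing_scores_error(self):
        with pytest.raises(ValueError):
            quartile_stratify(_anchors([1, 2, 3]))


class TestPolyATracts:
    def test_worked_example(self):
        hits = find_polyA_tracts("TTAAAAAGG", 5)
        assert list(hits.position) == [5]  # run at 3..7, center 5
        assert list(hits.strand) == ["+"]

    def test_maximality_excludes_longer_runs(self):
        assert len(find_polyA_tracts("AAAAAA", 5)) == 0

    def test_alternating_has_no_runs(self):
        assert len(find_polyA_tracts("ATATAT", 2)) == 0

    def test_t_runs_reported_on_minus_strand(self):
        hits = find_polyA_tracts("GGTTTTTGG", 5)
        assert list(hits.position) == [5]
        assert list(hits.strand) == ["-"]

    @pytest.mark.parametrize("exact_len", range(1, 11))
    def test_matches_regex_enumeration_on_random_sequence(self, exact_len):
        seq = random_seqs(1, 10000, seed=exact_len)[0]
        hits = find_polyA_tracts(seq, exact_len)
        assert sorted(zip(hits.position, hits.strand)) == naive_polyA_tracts(
            seq, exact_len
        )


class TestPWMRefinement:
    def test_planted_motif_recovery(self):
        rng = np.random.default_rng(0)
        width = 19
        mat = np.full((width, 4), 0.05)
        dom = rng.integers(0, 4, width)
        mat[np.arange(width), dom] = 0.85
        pwm = PWM(mat / mat.sum(axis=1, keepdims=True))
        consensus = "".join("ACGT"[d] for d in dom)
        genome = list(random_seqs(1, 50000, seed=1)[0])
        planted = []
        for i in range(100):
            pos = 300 + i * 450  # 0-based plant start, well separated
            genome[pos : pos + width] = consensus
            planted.append(pos + 1 + (width - 1) // 2)
        genome = "".join(genome)
        regions = FeatureAnchorSet(
            chrom=np.full(100, "c", dtype=object),
            position=np.array(planted) + rng.integers(-50, 51, size=100),
        )
        refined = pwm_refine_sites(genome, regions, pwm, radius=200)
        recovered = sum(
            p in set(refined.position) for p in planted
        )
        assert recovered >= 99
        assert (refined.strand[np.isin(refined.position, planted)] == "+").all()

    def test_uniform_pwm_returns_leftmost(self):
        pwm = PWM(np.full((4, 4), 0.25))
        genome = random_seqs(1, 200, seed=2)[0]
        regions = _anchors([100])
        refined = pwm_refine_sites(genome, regions, pwm, radius=20)
        # log-odds 0 everywhere: leftmost window of the region, + strand
        assert refined.position[0] == 80 + (4 - 1) // 2
        assert refined.strand[0] == "+"

    def test_palindromic_pwm_strand_tie_resolves_plus(self):
        # a self-reverse-complementary point-mass motif: ACGT
        mat = np.eye(4)
        pwm = PWM(mat)
        genome = "GGGGACGTGGGG"
        refined = pwm_refine_sites(genome, _anchors([6]), pwm, radius=5)
        assert refined.strand[0] == "+"

    def test_short_region_skipped_with_warning(self, caplog):
        pwm = PWM(np.full((10, 4), 0.25))
        with caplog.at_level("WARNING"):
            refined = pwm_refine_sites("ACGTACGT", _anchors([4]), pwm, radius=3)
        assert len(refined) == 0
        assert "skipped" in caplog.text


class TestTrackStandardization:
    def test_zero_mean_unit_sd(self):
        t = standardize_track(_track([1.0, 2.0, 3.0, 4.0]))
        assert abs(t.scores.mean()) < 1e-12
        assert abs(t.scores.std() - 1.0) < 1e-12


class TestBed6RoundTrip:
    def test_round_trip(self, tmp_path):
        a = _anchors([10, 20], strands=["+", "-"], scores=[1.5, -0.5])
        p = tmp_path / "a.bed"
        a.to_bed6(p)
        b = FeatureAnchorSet.from_bed6(p)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.strand, b.strand)
        assert np.allclose(a.score, b.score)
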