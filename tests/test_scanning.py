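import itertools
import math

import numpy as np
import pytest

from rbpscan.motifs import Motif, _floor_matrix, parse_iupac_consensus
from rbpscan.scanning import (
    ANALYTIC_BIN,
    BackgroundModel,
    STRINGENCY,
    analytic_score_distribution,
    build_background,
    empirical_pvalue,
    match_score,
    scan_scores,
    scan_sequence,
    theoretical_threshold,
    threshold_for,
)


def _pssm(rows, id="m"):
    raw = np.asarray(rows, dtype=float)
    raw = raw / raw.sum(axis=1, keepdims=True)
    return Motif(id=id, protein=id, probs=_floor_matrix(raw), raw_probs=raw,
                 origin="pssm")


def _bg(sample, mu=0.8, sd=0.05, n_wr=200):
    return BackgroundModel(motif_id="m", region_class="mid_intron_intergenic",
                           match_scores=np.asarray(sample, dtype=float),
                           wr_mean=mu, wr_sd=sd, n_wr=n_wr)


HAND_MOTIF = _pssm([[0.5, 0.3, 0.1, 0.1],
                    [0.25, 0.25, 0.25, 0.25],
                    [0.1, 0.2, 0.3, 0.4]], id="hand3")


class TestMatchScore:
    def test_best_and_worst_kmers_hit_the_bounds(self, motif):
        assert match_score(motif, motif.best_kmer()) == pytest.approx(1.0)
        assert match_score(motif, motif.worst_kmer()) == pytest.approx(0.0)

    def test_all_n_motif_degenerate_branch(self):
        m = parse_iupac_consensus("NNNN", id="n")
        assert match_score(m, "ACGU") == 1.0

    def test_hand_evaluated_three_column_example(self):
        # independent arithmetic on the floored matrix of HAND_MOTIF
        p = HAND_MOTIF.probs
        raw = math.log2(p[0, 1] / 0.25) + math.log2(p[1, 2] / 0.25) + math.log2(p[2, 0] / 0.25)
        smax = sum(math.log2(p[i].max() / 0.25) for i in range(3))
        smin = sum(math.log2(p[i].min() / 0.25) for i in range(3))
        expected = (raw - smin) / (smax - smin)
        assert match_score(HAND_MOTIF, "CGA") == pytest.approx(expected, abs=1e-12)

    def test_ambiguous_kmer_rejected(self, motif):
        with pytest.raises(ValueError, match="ambiguous"):
            match_score(motif, "ANGCUAA")


class TestScanning:
    def test_window_count(self):
        m = parse_iupac_consensus("ACGUA", id="m5")
        positions = scan_sequence(m, "A" * 21)
        assert [p.offset for p in positions] == list(range(17))

    def test_ambiguous_window_exclusion(self):
        m = parse_iupac_consensus("ACGUA", id="m5")
        positions = scan_sequence(m, "N" + "A" * 20)
        assert [p.offset for p in positions] == list(range(1, 17))

    def test_too_short_sequence_is_empty(self, motif):
        assert scan_sequence(motif, "ACG") == []

    def test_planted_consensus_is_unique_maximum(self):
        m = parse_iupac_consensus("ACGUA", id="m5")
        seq = "UUGUU" * 3 + "ACGUA" + "GGUUG" * 3
        positions = scan_sequence(m, seq)
        perfect = [p for p in positions if p.match_score == pytest.approx(1.0)]
        assert len(perfect) == 1 and perfect[0].offset == 15
        assert perfect[0].kmer == "ACGUA"

    def test_score_depends_only_on_kmer(self, motif):
        seq1 = "UCGA" * 10
        seq2 = "GGGG" + seq1
        s1, o1 = scan_scores(motif, seq1)
        s2, o2 = scan_scores(motif, seq2)
        # identical k-mers at shifted offsets score identically
        assert np.allclose(s1, s2[4:])


class TestEmpiricalPvalue:
    def test_counting_oracle(self, rng):
        sample = rng.random(1500)
        bg = _bg(sample)
        for score in [0.0, 0.3, 0.77, 1.01]:
            brute = (1 + np.sum(sample >= score)) / (1 + len(sample))
            assert empirical_pvalue(bg, score) == pytest.approx(brute, abs=1e-15)

    def test_extremes(self):
        bg = _bg(np.linspace(0.1, 0.9, 1000))
        assert empirical_pvalue(bg, 0.05) == 1.0
        assert empirical_pvalue(bg, 0.95) == pytest.approx(1 / 1001)

    def test_monotone_non_increasing(self):
        bg = _bg(np.linspace(0, 1, 1200))
        scores = np.linspace(-0.1, 1.1, 101)
        p = empirical_pvalue(bg, scores)
        assert np.all(np.diff(p) <= 0)


class TestThresholds:
    def test_near_one_p_gives_background_minimum(self):
        bg = _bg(np.linspace(0.1, 0.9, 1000))
        t = threshold_for(bg, 0.999)
        assert 0.1 <= t <= 0.102

    def test_quantile_oracle_on_uniform_grid(self):
        sample = np.arange(1000) / 1000.0
        bg = _bg(sample)
        t = threshold_for(bg, 0.01)
        # defining property: t is the smallest score with p < 0.01
        assert empirical_pvalue(bg, t) < 0.01
        below = np.nextafter(t, -np.inf)
        assert empirical_pvalue(bg, below) >= 0.01
        # consistent with the top 1% of the sample
        assert 0.985 <= t <= 0.995

    def test_monotone_in_p(self, mid_bg):
        assert threshold_for(mid_bg, 0.005) >= threshold_for(mid_bg, 0.01)

    def test_unattainable_p_gives_inf(self):
        bg = _bg(np.linspace(0, 1, 1000))
        assert threshold_for(bg, 1e-9) == math.inf


def _enumerate_match_scores(m, base_freqs):
    """Exhaustive 4^k oracle: (sorted scores, probabilities)."""
    k = m.length
    out = []
    for combo in itertools.product(range(4), repeat=k):
        s = match_score(m, "".join("ACGU"[b] for b in combo))
        p = math.prod(base_freqs[b] for b in combo)
        out.append((s, p))
    out.sort()
    return np.array([s for s, _ in out]), np.array([p for _, p in out])


class TestAnalyticDistribution:
    @pytest.mark.parametrize("freqs", [(0.25, 0.25, 0.25, 0.25), (0.4, 0.1, 0.1, 0.4)])
    def test_matches_enumeration_k3(self, freqs):
        dist = analytic_score_distribution(HAND_MOTIF, freqs)
        scores, probs = _enumerate_match_scores(HAND_MOTIF, freqs)
        # compare tail probabilities at cut points safely between atoms
        uniq = np.unique(scores)
        cuts = (uniq[:-1] + uniq[1:]) / 2
        gaps = np.diff(uniq)
        cuts = cuts[gaps > 10 * HAND_MOTIF.length * ANALYTIC_BIN]
        for c in cuts:
            exact_tail = probs[scores >= c].sum()
            assert dist.sf(c) == pytest.approx(exact_tail, abs=1e-9)

    def test_total_mass_and_support_range(self, motif):
        dist = analytic_score_distribution(motif)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.support[0] >= -1e-6 and dist.support[-1] <= 1 + 1e-3

    def test_all_n_motif_point_mass_at_one(self):
        dist = analytic_score_distribution(parse_iupac_consensus("NNN", id="n"))
        assert list(dist.support) == [1.0] and list(dist.pmf) == [1.0]

    def test_deterministic_motif_best_kmer_mass(self):
        m = parse_iupac_consensus("ACG", id="d")
        dist = analytic_score_distribution(m)
        # the single best k-mer carries mass 1/64 at score 1
        assert dist.sf(0.999) == pytest.approx(1 / 64, abs=1e-9)


class TestTheoreticalThreshold:
    def test_significant_at_least_suboptimal(self, motif):
        for level in STRINGENCY.values():
            t_sig, t_sub = theoretical_threshold(motif, level)
            assert t_sig >= t_sub

    def test_all_n_motif_never_significant(self):
        m = parse_iupac_consensus("NNNN", id="n")
        t_sig, _ = theoretical_threshold(m)
        # every window scores 1.0 and can never reach the threshold
        assert match_score(m, "ACGU") < t_sig

    def test_boundary_isolates_single_best_kmer(self):
        m = parse_iupac_consensus("ACG", id="d")
        dist = analytic_score_distribution(m)
        t = dist.quantile_above(1 / 64 + 1e-9)
        assert match_score(m, "ACG") >= t
        for combo in itertools.product("ACGU", repeat=3):
            kmer = "".join(combo)
            if kmer != "ACG":
                assert match_score(m, kmer) < t


class TestBuildBackground:
    def test_match_sample_accounting(self, motif):
        from rbpscan.synth import background_corpus

        seqs = background_corpus("internal_exon", n=300, length=250, seed=3)
        bg = build_background(motif, seqs, "internal_exon")
        expected = sum(len(s) - motif.length + 1 for s in seqs)
        assert bg.n_match == expected

    def test_split_half_stability(self, motif):
        from rbpscan.synth import background_corpus

        seqs = background_corpus("mid_intron_intergenic", n=1200, length=250, seed=9)
        bg1 = build_background(motif, seqs[:600], "mid_intron_intergenic")
        bg2 = build_background(motif, seqs[600:], "mid_intron_intergenic")
        se = math.hypot(bg1.wr_sd / math.sqrt(bg1.n_wr), bg2.wr_sd / math.sqrt(bg2.n_wr))
        assert abs(bg1.wr_mean - bg2.wr_mean) < 3 * se

    def test_degenerate_all_n_motif_rejected(self, rng):
        m = parse_iupac_consensus("NNNNN", id="n")
        from rbpscan.synth import random_sequences

        seqs = random_sequences(rng, 50, 250, (0.25,) * 4)
        with pytest.raises(ValueError):
            build_background(m, seqs, "ncRNA")

    def test_insufficient_background_rejected(self, motif):
        with pytest.raises(ValueError, match="insufficient"):
            build_background(motif, ["ACGUACGUACGUACGU"], "ncRNA")

    def test_empirical_quantiles_converge_to_analytic(self, motif, rng):
        """KS distance < 0.05 between a 10k-window background built from the
        analytic base frequencies and the analytic distribution."""
        from rbpscan.synth import random_sequences

        freqs = (0.25, 0.25, 0.25, 0.25)
        seqs = random_sequences(rng, 45, 250, freqs)
        scores = np.sort(np.concatenate([scan_scores(motif, s)[0] for s in seqs]))
        assert len(scores) >= 10_000
        dist = analytic_score_distribution(motif, freqs)
        cdf = np.cumsum(dist.pmf)
        ecdf_at = np.searchsorted(scores, dist.support, side="right") / len(scores)
        ks = np.max(np.abs(ecdf_at - cdf))
        assert ks < 0.05
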