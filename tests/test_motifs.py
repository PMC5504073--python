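"""Motif machinery: background training, exact p-value DP vs enumeration,
strand-symmetric scanning, ZOOPS EM recovery, and the two-part pipeline."""

import itertools

import numpy as np
import pytest

from ctcf_landscape import motifs as M
from ctcf_landscape import synthetic_data as S
from ctcf_landscape import peaks as P


def random_seqs(rng, n, L):
    return ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]


class TestMarkovBackground:
    def test_order0_degenerate(self):
        bg = M.train_markov_background(["AAAA"], order=0, pseudo=0.0)
        assert bg.probs0[0] == pytest.approx(1.0)

    def test_order1_alternating(self):
        bg = M.train_markov_background(["ACACAC"], order=1, pseudo=0.0)
        assert bg.cond[0, 1] == pytest.approx(1.0)  # P(C|A)
        assert bg.cond[1, 0] == pytest.approx(1.0)  # P(A|C)

    def test_hand_counted_transitions_with_pseudo(self):
        # "AACGT": transitions AA, AC, CG, GT; base counts A2 C1 G1 T1
        bg = M.train_markov_background(["AACGT"], order=1, pseudo=0.01)
        assert bg.probs0[0] == pytest.approx((2 + 0.01) / (5 + 0.04))
        # row A: AA=1, AC=1 -> P(A|A) = 1.01 / 2.04
        assert bg.cond[0, 0] == pytest.approx(1.01 / 2.04)
        assert bg.cond[0, 1] == pytest.approx(1.01 / 2.04)
        assert bg.cond[0, 2] == pytest.approx(0.01 / 2.04)

    def test_n_windows_skipped(self):
        bg = M.train_markov_background(["ANA"], order=1, pseudo=0.0)
        # no valid transition pairs; A row falls back without error
        assert bg.probs0[0] == pytest.approx(1.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            M.train_markov_background([], order=1)


class TestScorePvalueTable:
    def test_width1_single_column_enumeration(self):
        # one column with score ordering A > C = G > T under uniform
        # background: p(score >= s_A) = P(A) = 0.25, and so on
        pwm = M.PWM(probs=np.array([[0.4], [0.25], [0.25], [0.1]]))
        bg0 = np.full(4, 0.25)
        t = M.ScorePvalueTable(pwm, bg0)
        assert t.pvalue_from_int(t.int_scores[0, 0]) == pytest.approx(0.25)
        assert t.pvalue_from_int(t.int_scores[1, 0]) == pytest.approx(0.75)
        assert t.pvalue_from_int(t.int_scores[3, 0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 3, 5])
    def test_dp_matches_enumeration(self, width, rng):
        probs = rng.dirichlet(np.ones(4) * 2, size=width).T
        pwm = M.PWM(probs=probs)
        bg0 = rng.dirichlet(np.ones(4) * 10)
        t = M.ScorePvalueTable(pwm, bg0)
        # independent oracle: enumerate all 4^w sequences on the same
        # integer grid and sum background probabilities
        table = {}
        for word in itertools.product(range(4), repeat=width):
            k = sum(t.int_scores[b, c] for c, b in enumerate(word))
            p = float(np.prod([bg0[b] for b in word]))
            table[k] = table.get(k, 0.0) + p
        for k0 in sorted(table):
            exact = sum(p for k, p in table.items() if k >= k0)
            assert t.pvalue_from_int(k0) == pytest.approx(exact, abs=1e-6)

    def test_map_non_increasing(self, rng):
        pwm = M.PWM(probs=rng.dirichlet(np.ones(4), size=6).T)
        t = M.ScorePvalueTable(pwm, np.full(4, 0.25))
        ps = t.pvalue_from_int(np.arange(t.max_int + 1))
        assert np.all(np.diff(ps) <= 1e-15)

    def test_granularity_floor(self):
        pwm = M.PWM(probs=np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            M.ScorePvalueTable(pwm, np.full(4, 0.25), granularity=10)


def sharp_pwm(word, match=0.97):
    probs = np.full((4, len(word)), (1 - match) / 3)
    for c, ch in enumerate(word):
        probs["ACGT".index(ch), c] = match
    return M.PWM(probs=probs)


class TestScan:
    WORD = "CCACCAGGTG"

    def test_planted_word_single_hit(self, rng):
        pwm = sharp_pwm(self.WORD)
        seq = "".join(rng.choice(list("AT"), 40)) + self.WORD + "".join(rng.choice(list("AT"), 30))
        win = M.ScanWindow("p1", "chr1", 1000, seq)
        hits = M.scan([win], pwm, np.full(4, 0.25), 1e-4)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (1040, 1050, "+")

    def test_strand_symmetry(self, rng):
        pwm = M.PWM(probs=rng.dirichlet(np.ones(4), size=8).T)
        bg0 = rng.dirichlet(np.ones(4) * 5)
        wins = [M.ScanWindow(f"p{i}", "c", 0, "".join(rng.choice(list("ACGT"), 60)))
                for i in range(20)]
        rc_wins = [M.ScanWindow(w.peak_id, w.chrom, w.start, M.revcomp(w.seq)) for w in wins]
        L = 60
        hits = M.scan(wins, pwm, bg0, 0.05)
        rc_hits = M.scan(rc_wins, pwm, bg0, 0.05)
        fwd = {(h.peak_id, h.start, h.end, h.strand, round(h.pvalue, 12)) for h in hits}
        mirrored = {
            (h.peak_id, L - h.end, L - h.start, "+" if h.strand == "-" else "-",
             round(h.pvalue, 12))
            for h in rc_hits
        }
        assert fwd == mirrored

    def test_threshold_one_reports_all_candidates(self):
        win = M.ScanWindow("p", "c", 0, "ACGTACGTACGT")
        pwm = sharp_pwm("ACGT")
        hits = M.scan([win], pwm, np.full(4, 0.25), 1.0)
        assert len(hits) == 2 * (12 - 4 + 1)

    def test_n_positions_skipped(self):
        win = M.ScanWindow("p", "c", 0, "ACGTNACGT")
        pwm = sharp_pwm("ACGT")
        hits = M.scan([win], pwm, np.full(4, 0.25), 1.0)
        # windows [1..4] (covering the N) are skipped on both strands
        assert len(hits) == 2 * 2
        assert all("N" not in win.seq[h.start : h.end] for h in hits)


class TestBestHit:
    def mk(self, pid="p", start=0, strand="+", score=5.0, p=1e-5):
        return M.MotifHit(pid, "c", start, start + 16, strand, score, p)

    def test_lowest_p_adopted(self):
        best = M.best_hit_per_peak([self.mk(p=1e-5), self.mk(start=50, p=1e-6)])
        assert best["p"].start == 50

    def test_single_hit_is_itself(self):
        h = self.mk()
        assert M.best_hit_per_peak([h])["p"] is h

    def test_tie_order_score_position_strand(self):
        # equal p: higher score wins; equal score: leftmost; then + strand
        a = self.mk(start=10, score=5.0)
        b = self.mk(start=20, score=6.0)
        assert M.best_hit_per_peak([a, b])["p"] is b
        c = self.mk(start=10, score=5.0, strand="-")
        d = self.mk(start=5, score=5.0, strand="-")
        assert M.best_hit_per_peak([c, d])["p"] is d
        e = self.mk(start=10, score=5.0, strand="-")
        f = self.mk(start=10, score=5.0, strand="+")
        assert M.best_hit_per_peak([e, f])["p"] is f


class TestUpstreamWindows:
    @pytest.fixture()
    def genome(self):
        from ctcf_landscape.formats import GenomeSequence

        seq = "".join("ACGT"[(i // 3) % 4] for i in range(300))
        return GenomeSequence({"c": seq})

    def test_plus_hit_left_window(self, genome):
        h = M.MotifHit("p", "c", 100, 116, "+", 1.0, 1e-5)
        (w,) = M.upstream_windows([h], genome)
        assert (w.start, w.seq) == (80, genome.fetch("c", 80, 100))

    def test_minus_hit_right_window_revcomp(self, genome):
        h = M.MotifHit("p", "c", 100, 116, "-", 1.0, 1e-5)
        (w,) = M.upstream_windows([h], genome)
        assert (w.start, w.seq) == (116, M.revcomp(genome.fetch("c", 116, 136)))

    def test_contig_edge_dropped(self, genome):
        h = M.MotifHit("p", "c", 5, 21, "+", 1.0, 1e-5)
        assert M.upstream_windows([h], genome) == []


class TestEMDiscover:
    def test_exact_planted_word_recovered(self, rng):
        core = "CCACCAGGGGGCGCTA"
        seqs = []
        for _ in range(200):
            s = list(rng.choice(list("ACGT"), 200))
            off = int(rng.integers(0, 184))
            s[off : off + 16] = list(core)
            seqs.append("".join(s))
        bg = M.train_markov_background(seqs, order=1)
        res = M.em_discover(seqs, 16, bg, n_starts=3, seed=0)
        assert res.pwm.consensus == core
        assert res.significant

    def test_mutated_motif_close_in_total_variation(self, rng):
        core = "CCACCAGGGGGCGCTA"
        planted = np.full((4, 16), 0.1 / 3)
        for c, ch in enumerate(core):
            planted["ACGT".index(ch), c] = 0.9
        seqs = []
        for _ in range(300):
            s = list(rng.choice(list("ACGT"), 200))
            off = int(rng.integers(0, 184))
            inst = [
                ch if rng.random() > 0.1 else rng.choice([x for x in "ACGT" if x != ch])
                for ch in core
            ]
            s[off : off + 16] = inst
            seqs.append("".join(s))
        bg = M.train_markov_background(seqs, order=1)
        res = M.em_discover(seqs, 16, bg, n_starts=3, seed=0)
        pwm = res.pwm if res.pwm.consensus == core else res.pwm.reverse_complement()
        tv = 0.5 * np.abs(pwm.probs - planted).sum(axis=0)
        assert tv.max() < 0.15

    def test_pure_background_yields_flat_pwm(self, rng):
        seqs = random_seqs(rng, 200, 200)
        bg = M.train_markov_background(seqs, order=1)
        res = M.em_discover(seqs, 16, bg, n_starts=3, seed=0)
        assert not res.significant
        assert res.pwm.information_content().max() < 0.5

    def test_log_likelihood_non_decreasing(self, rng):
        core = "CCACCAGGGGGCGCTA"
        seqs = []
        for _ in range(100):
            s = list(rng.choice(list("ACGT"), 120))
            s[40:56] = list(core)
            seqs.append("".join(s))
        bg = M.train_markov_background(seqs, order=1)
        res = M.em_discover(seqs, 16, bg, n_starts=2, seed=0)
        diffs = np.diff(res.ll_trace)
        assert np.all(diffs >= -1e-6 * (np.abs(res.ll_trace[:-1]) + 1))

    def test_width_below_four_errors(self, rng):
        seqs = random_seqs(rng, 5, 30)
        bg = M.train_markov_background(seqs)
        with pytest.raises(ValueError):
            M.em_discover(seqs, 3, bg)


class TestTwoPartPipeline:
    def test_recovers_both_planted_motifs(self, bundle, two_part):
        cfg = bundle.cfg
        assert two_part.core_pwm.consensus in (
            cfg.core_consensus,
            M.revcomp(cfg.core_consensus),
        )
        assert two_part.upstream_pwm.consensus == cfg.upstream_consensus

    def test_core_flags_agree_with_truth_on_high_fe_peaks(self, bundle, embryo_consensus,
                                                          two_part):
        sites = sorted(bundle.truth.sites, key=lambda s: (s.chrom, s.center))
        import bisect

        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        ok = tot = 0
        for p in embryo_consensus.peaks:
            if p.fold_enrichment < 10:
                continue
            arr = by_chrom.get(p.chrom, [])
            centers = [s.center for s in arr]
            i = bisect.bisect_left(centers, p.summit)
            near = [arr[j] for j in (i - 1, i) if 0 <= j < len(arr)
                    and abs(arr[j].center - p.summit) < 60]
            if not near:
                continue
            tot += 1
            ok += (p.name in two_part.best_core_hit) == near[0].has_core
        assert tot > 300
        assert ok / tot >= 0.95

    def test_upstream_hits_lie_in_extension_windows(self, bundle, two_part):
        # geometric invariant: the upstream stage only ever scans the 20-bp
        # 5' extension, so every flagged peak must have a best core hit
        for peak_id, flagged in two_part.upstream_flag.items():
            if flagged:
                assert peak_id in two_part.best_core_hit

    def test_upstream_null_gives_uninformative_motif(self):
        """Generating without the upstream motif (and without repeat-borne
        carriage, which would otherwise leave conserved flanks) must yield a
        near-flat upstream PWM and no upstream flags."""
        cfg = S.GeneratorConfig(
            seed=13, genome_length=1_500_000, n_chroms=1, n_true_sites=400,
            upstream_fraction=0.0, fraction_in_family=0.0, n_noise_peaks=80,
        )
        b = S.simulate_bundle(cfg)
        runs = b.peak_calls["embryo"]
        cons = P.consensus_peaks(runs["rep1"], runs["rep2"], runs["merged"])
        tp = M.two_part_pipeline(cons, b.genome, M.TwoPartConfig(seed=1))
        assert tp.upstream_pwm.information_content().max() < 0.5
        assert sum(tp.upstream_flag.values()) == 0

    def test_fe_bin_proportions_invariants(self, embryo_consensus, two_part):
        edges = [0, 5, 10, 20, 40, float("inf")]
        df = M.fe_bin_proportions(embryo_consensus.peaks, two_part, edges)
        assert int(df.n_peaks.sum()) == len(embryo_consensus.peaks)
        assert (df.frac_core_plus_upstream <= df.frac_core + 1e-12).all()

    def test_fe_bin_core_fraction_non_decreasing(self, embryo_consensus, two_part):
        """Motif-bearing peaks have up-shifted FE in the generator, so the
        core-motif fraction rises across FE bins; with finite bins the
        comparison allows binomial noise (2 s.e.) per adjacent pair."""
        edges = [0, 5, 10, 20, 40, float("inf")]
        df = M.fe_bin_proportions(embryo_consensus.peaks, two_part, edges)
        fc = df.frac_core.to_numpy()
        n = df.n_peaks.to_numpy()
        for i in range(len(fc) - 1):
            pool = (fc[i] * n[i] + fc[i + 1] * n[i + 1]) / (n[i] + n[i + 1])
            se = np.sqrt(pool * (1 - pool) * (1 / max(n[i], 1) + 1 / max(n[i + 1], 1)))
            assert fc[i + 1] >= fc[i] - 2 * se
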