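"""Generator correctness: determinism, planted-parameter recovery, bundle IO
and validation."""

import json

import numpy as np
import pytest

from ctcf_landscape import peaks as P
from ctcf_landscape import synthetic_data as S
from ctcf_landscape.motifs import revcomp


def small_families():
    return [
        S.RepeatFamilySpec("274", "DNA/hAT-Tip100", 180, 0, 0.08, carries_motif=True),
        S.RepeatFamilySpec("101", "LTR/Gypsy", 400, 18, 0.12),
        S.RepeatFamilySpec("352", "DNA/hAT-Charlie", 300, 14, 0.10),
        S.RepeatFamilySpec("515", "SINE/tRNA-V", 200, 20, 0.15),
        S.RepeatFamilySpec("620", "Unknown", 350, 10, 0.10),
    ]


def small_cfg(seed, **kw):
    base = dict(genome_length=400_000, n_chroms=2, n_true_sites=120,
                n_noise_peaks=30, n_block_length=200, families=small_families(),
                seed=seed)
    base.update(kw)
    return S.GeneratorConfig(**base)


class TestMakeGenome:
    def test_identity_on_a_transition(self):
        t = np.zeros((4, 4))
        t[:, 0] = 1.0  # every state moves to A
        cfg = S.GeneratorConfig(genome_length=3_000, n_chroms=1, transition=t,
                                n_block_length=0, seed=0)
        g = S.make_genome(cfg)
        assert set(g.records["chr1"]) == {"A"}

    def test_uniform_transition_base_frequencies(self):
        cfg = S.GeneratorConfig(genome_length=1_000_000, n_chroms=1,
                                transition=np.full((4, 4), 0.25),
                                n_block_length=0, seed=1)
        g = S.make_genome(cfg)
        seq = g.records["chr1"]
        for b in "ACGT":
            assert abs(seq.count(b) / len(seq) - 0.25) < 0.01

    def test_same_seed_same_sequence(self):
        cfg = S.GeneratorConfig(genome_length=50_000, n_chroms=1, seed=4)
        assert S.make_genome(cfg).records == S.make_genome(cfg).records

    def test_n_block_present(self):
        cfg = S.GeneratorConfig(genome_length=50_000, n_chroms=1, seed=4)
        assert "N" * cfg.n_block_length in S.make_genome(cfg).records["chr1"]


@pytest.fixture(scope="module")
def planted():
    cfg = small_cfg(21)
    genome = S.make_genome(cfg, np.random.default_rng(21))
    return cfg, S.plant_repeats_and_sites(genome, cfg, np.random.default_rng(22))


@pytest.fixture(scope="module")
def outdirs(tmp_path_factory):
    cfg = small_cfg(31)
    d1 = tmp_path_factory.mktemp("bundle1")
    d2 = tmp_path_factory.mktemp("bundle2")
    S.write_dataset(d1, cfg)
    S.write_dataset(d2, cfg)
    return d1, d2


class TestPlanting:
    def test_zero_divergence_copies_identical(self):
        cfg = small_cfg(5)
        for f in cfg.families:
            f.divergence = 0.0
        genome = S.make_genome(cfg, np.random.default_rng(5))
        g2, copies, _ = S.plant_repeats_and_sites(genome, cfg, np.random.default_rng(6))
        by_fam = {}
        for c in copies:
            seq = g2.fetch(c.chrom, c.start, c.end)
            if c.strand == "-":
                seq = revcomp(seq)
            by_fam.setdefault(c.family_id, set()).add(seq)
        for fam, seqs in by_fam.items():
            # upstream planting varies the motif family's copies; others are clones
            if fam != "274":
                assert len(seqs) == 1

    def test_all_sites_in_family_when_fraction_one(self):
        # full sharing keeps the repeat-borne sites within the shared budget
        cfg = small_cfg(5, fraction_in_family=1.0, shared_fraction=1.0)
        genome = S.make_genome(cfg, np.random.default_rng(5))
        _, _, truth = S.plant_repeats_and_sites(genome, cfg, np.random.default_rng(6))
        motif_sites = [s for s in truth.sites if s.has_core]
        assert all(s.family_id is not None for s in motif_sites)

    def test_observed_divergence_near_configured(self, planted):
        cfg, (_, copies, _) = planted
        for spec in cfg.families:
            if spec.carries_motif:
                continue  # upstream/core planting perturbs the rate
            obs = np.array([c.divergence_pct / 100 for c in copies
                            if c.family_id == spec.family_id])
            se = np.sqrt(spec.divergence * (1 - spec.divergence)
                         / (len(obs) * spec.consensus_length))
            assert abs(obs.mean() - spec.divergence) < 2 * se + 1e-9

    def test_core_sequences_recorded_faithfully(self, planted):
        _, (genome, _, truth) = planted
        for s in truth.sites:
            if s.has_core:
                assert genome.fetch(s.chrom, s.core_start, s.core_end) == s.core_seq

    def test_sharing_budget(self, planted):
        cfg, (_, _, truth) = planted
        sa, sb = cfg.samples
        a = set(truth.samples[sa].site_ids)
        b = set(truth.samples[sb].site_ids)
        assert len(a) == len(b) == cfg.n_true_sites
        assert len(a & b) == round(cfg.shared_fraction * cfg.n_true_sites)


class TestPeakSimulation:
    def test_noiseless_limit_recovers_sites_exactly(self):
        cfg = small_cfg(9, replicate_detection_prob=1.0,
                        summit_jitter_sd=0.0, n_noise_peaks=0)
        b = S.simulate_bundle(cfg)
        runs = b.peak_calls["embryo"]
        cons = P.consensus_peaks(runs["rep1"], runs["rep2"], runs["merged"])
        centers = {(s.chrom, s.center) for s in b.truth.sites
                   if s.site_id in b.truth.samples["embryo"].site_ids}
        got = {(p.chrom, p.summit) for p in cons.peaks}
        assert got == centers

    def test_consensus_recovery_matches_p_squared(self, bundle):
        """Sites detected in both replicates follow Binomial(n, p^2)."""
        cfg = bundle.cfg
        st = bundle.truth.samples["embryo"]
        both = set(st.detected_rep1) & set(st.detected_rep2)
        p2 = cfg.replicate_detection_prob ** 2
        n = len(st.site_ids)
        se = np.sqrt(p2 * (1 - p2) / n)
        assert abs(len(both) / n - p2) <= 3 * se

    def test_motif_peaks_have_higher_fe(self, bundle):
        st = bundle.truth.samples["embryo"]
        site = {s.site_id: s for s in bundle.truth.sites}
        fe_motif = [fe for sid, fe in st.fe_merged.items() if site[sid].has_core]
        fe_less = [fe for sid, fe in st.fe_merged.items() if not site[sid].has_core]
        assert np.mean(fe_motif) > np.mean(fe_less)


class TestToyHox:
    def test_presets_differ_only_in_hox1_4(self):
        lam = S.make_toy_hox("lamprey", seed=3)
        gna = S.make_toy_hox("gnathostome", seed=3)
        for cname in ("A", "B"):
            assert lam.truth[cname].hox1_4_count >= 3
            assert gna.truth[cname].hox1_4_count == 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            S.make_toy_hox("fish")

    def test_planted_cores_present_in_genome(self):
        cfg = S.GeneratorConfig()
        lam = S.make_toy_hox("lamprey", cfg, seed=3)
        # every planted site region contains a near-exact core or its rc
        core = cfg.core_consensus
        for cname, tr in lam.truth.items():
            for npos in tr.site_positions:
                gpos = npos if tr.axis == "+" else 110_000 - npos
                region = lam.genome.fetch(tr.chrom, gpos - 20, gpos + 20)
                best = max(
                    max(sum(a == b for a, b in zip(region[i:], core))
                        for i in range(len(region) - len(core) + 1))
                    for core in (core, revcomp(core))
                )
                assert best >= 13  # 16 bp at 3% mutation


class TestBundleIO:
    def test_bundle_validates(self, outdirs):
        S.validate_dataset(outdirs[0])

    def test_same_seed_byte_identical(self, outdirs):
        d1, d2 = outdirs
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files == sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_missing_file_named(self, outdirs, tmp_path):
        import shutil

        d = tmp_path / "broken"
        shutil.copytree(outdirs[0], d)
        (d / "repeats.bed").unlink()
        with pytest.raises(ValueError, match="repeats.bed"):
            S.validate_dataset(d)

    def test_corrupted_genome_detected(self, outdirs, tmp_path):
        import shutil

        d = tmp_path / "corrupt"
        shutil.copytree(outdirs[0], d)
        with open(d / "truth.json") as fh:
            truth = json.load(fh)
        site = next(s for s in truth["sites"] if s["has_core"])
        site["core_seq"] = "A" * 16 if site["core_seq"][0] != "A" else "C" * 16
        with open(d / "truth.json", "w") as fh:
            json.dump(truth, fh)
        with pytest.raises(ValueError, match="core sequence"):
            S.validate_dataset(d)
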