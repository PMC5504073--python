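"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the structure of a CTCF ChIP-seq study on a
repeat-rich genome without any read-level simulation: peak lists are drawn
directly, since the pipeline's own computation begins at peak calls.

What is emulated:

* an order-1 Markov genome with optional N blocks;
* several repeat families as divergent copies of family consensus
  sequences, one of which carries the 16-bp core CTCF motif in its
  consensus so that binding sites propagate with the repeat
  (hAT-Tip100-style carriage);
* true binding sites of three kinds — repeat-borne motif sites, dispersed
  motif sites, and motif-less sites — with the upstream (M2) motif planted
  20 bp 5' of a configurable fraction of cores;
* two samples ("embryo", "liver") sharing a configurable fraction of true
  sites, each with two replicate peak calls plus a merged-replicates call;
  fold enrichment is log-normal with the motif-bearing class shifted up,
  and summits are jittered;
* toy Hox clusters with planted binding-site orientations, in a
  "lamprey-like" variant (repeat-borne sites between paralog groups 1-4)
  and a "gnathostome-like" variant (none).

All randomness flows from one seed through named spawned streams, so the
emitted bundle is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ctcf_landscape.formats import (
    GeneRecord,
    GenomeSequence,
    PeakRecord,
    RepeatCopy,
    parse_hox_name,
    read_fasta,
    read_gene_annotation,
    read_narrowpeak,
    read_repeat_annotation,
    write_fasta,
    write_gene_annotation,
    write_narrowpeak,
    write_repeat_annotation,
)
from intervaltree import IntervalTree

from ctcf_landscape.intervals import CapacityError
from ctcf_landscape.motifs import PWM, encode

logger = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode_arr(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def consensus_pwm(consensus: str, match: float = 0.85) -> PWM:
    """A sharp PWM for a planted consensus (match probability per column)."""
    enc = encode(consensus)
    probs = np.full((4, len(enc)), (1.0 - match) / 3.0)
    for c, b in enumerate(enc):
        probs[b, c] = match
    return PWM(probs=probs)


@dataclass
class RepeatFamilySpec:
    family_id: str
    class_label: str
    consensus_length: int
    n_copies: int
    divergence: float
    carries_motif: bool = False


def _default_families() -> list[RepeatFamilySpec]:
    return [
        # n_copies of the motif-carrying family is derived from the site
        # budget (fraction_in_family * motif-bearing sites)
        RepeatFamilySpec("274", "DNA/hAT-Tip100", 180, 0, 0.08, carries_motif=True),
        RepeatFamilySpec("101", "LTR/Gypsy", 400, 200, 0.12),
        RepeatFamilySpec("352", "DNA/hAT-Charlie", 300, 150, 0.10),
        RepeatFamilySpec("515", "SINE/tRNA-V", 200, 250, 0.15),
        RepeatFamilySpec("620", "Unknown", 350, 120, 0.10),
    ]


def _default_transition() -> np.ndarray:
    return np.array(
        [
            [0.30, 0.22, 0.26, 0.22],
            [0.26, 0.28, 0.20, 0.26],
            [0.24, 0.26, 0.28, 0.22],
            [0.20, 0.26, 0.26, 0.28],
        ]
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bundle (all knobs seeded)."""

    genome_length: int = 6_000_000
    n_chroms: int = 3
    transition: np.ndarray = field(default_factory=_default_transition)
    n_block_length: int = 1000  # one N block per chromosome (0 disables)
    families: list[RepeatFamilySpec] = field(default_factory=_default_families)
    n_true_sites: int = 1500  # per sample
    motif_fraction: float = 0.7
    fraction_in_family: float = 0.4
    upstream_fraction: float = 0.5
    core_consensus: str = "CCACCAGGGGGCGCTA"
    upstream_consensus: str = "TTCAGCATAC"
    upstream_gap: int = 4
    core_offset: int = 60  # core position within the motif family consensus
    site_mutation_rate: float = 0.08
    fe_noise: tuple[float, float] = (1.10, 0.3)  # ln-scale (mu, sigma)
    fe_motifless: tuple[float, float] = (1.79, 0.5)
    fe_motif: tuple[float, float] = (2.89, 0.5)
    replicate_detection_prob: float = 0.99
    peak_halfwidth: int = 150
    summit_jitter_sd: float = 5.0
    n_noise_peaks: int = 300
    shared_fraction: float = 0.75
    samples: tuple[str, str] = ("embryo", "liver")
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.motif_fraction, self.fraction_in_family, self.upstream_fraction,
                  self.replicate_detection_prob, self.shared_fraction,
                  self.site_mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.genome_length, self.n_chroms, self.n_true_sites) <= 0:
            raise ValueError("lengths and counts must be positive")


@dataclass
class SiteTruth:
    site_id: str
    chrom: str
    center: int
    strand: str
    has_core: bool
    has_upstream: bool
    family_id: str | None
    core_start: int | None
    core_end: int | None
    core_seq: str | None = None  # forward-strand genomic sequence of the core


@dataclass
class SampleTruth:
    site_ids: list[str]
    detected_rep1: list[str]
    detected_rep2: list[str]
    fe_merged: dict[str, float]


@dataclass
class GroundTruth:
    seed: int
    sites: list[SiteTruth]
    copies: list[RepeatCopy]
    samples: dict[str, SampleTruth] = field(default_factory=dict)
    shared_site_ids: list[str] = field(default_factory=list)
    true_shared_fraction: float = 0.0

    def site(self, site_id: str) -> SiteTruth:
        return next(s for s in self.sites if s.site_id == site_id)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    v = np.full(4, 0.25)
    for _ in range(200):
        v = v @ transition
    return v / v.sum()


def _markov_chrom(length: int, transition: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pi = stationary_distribution(transition)
    cum = np.cumsum(transition, axis=1)
    # per-state candidate draws, then a linear scan through the chain
    cands = np.empty((4, length), dtype=np.uint8)
    u = rng.random((4, length))
    for s in range(4):
        cands[s] = np.searchsorted(cum[s], u[s]).astype(np.uint8)
    out = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(np.cumsum(pi), rng.random()))
    out[0] = state
    c = cands
    for i in range(1, length):
        state = c[state, i]
        out[i] = state
    return out


def make_genome(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> GenomeSequence:
    """Order-1 Markov genome with one central N block per chromosome."""
    rng = rng or np.random.default_rng(cfg.seed)
    if np.any(np.abs(cfg.transition.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition rows must sum to 1")
    per = cfg.genome_length // cfg.n_chroms
    records = {}
    for i in range(cfg.n_chroms):
        arr = _markov_chrom(per, cfg.transition, rng)
        if cfg.n_block_length > 0 and per > 3 * cfg.n_block_length:
            mid = int(0.45 * per)
            arr[mid : mid + cfg.n_block_length] = 4
        records[f"chr{i + 1}"] = _decode_arr(arr)
    return GenomeSequence(records)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


class _Placer:
    """Rejection placement of disjoint features with exclusion margins."""

    def __init__(self, chrom_arrays: dict[str, np.ndarray], rng: np.random.Generator):
        self.arrays = chrom_arrays
        self.rng = rng
        self.occupied = {c: IntervalTree() for c in chrom_arrays}
        self.chroms = sorted(chrom_arrays)
        lens = np.array([len(chrom_arrays[c]) for c in self.chroms], dtype=float)
        self.weights = lens / lens.sum()

    def place(self, body_len: int, margin: int, max_tries: int = 2000) -> tuple[str, int]:
        for _ in range(max_tries):
            chrom = self.chroms[int(self.rng.choice(len(self.chroms), p=self.weights))]
            arr = self.arrays[chrom]
            hi = len(arr) - body_len - margin
            if hi <= margin:
                continue
            start = int(self.rng.integers(margin, hi))
            lo, up = start - margin, start + body_len + margin
            if self.occupied[chrom].overlap(lo, up):
                continue
            if np.any(arr[lo:up] == 4):
                continue
            self.occupied[chrom].addi(lo, up)
            return chrom, start
        raise CapacityError(
            f"could not place a {body_len} bp feature after {max_tries} tries"
        )


def _mutate(enc: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = enc.copy()
    mask = rng.random(len(enc)) < rate
    out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return out


def _random_seq(length: int, probs0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs0), rng.random(length)).astype(np.uint8)


def plant_repeats_and_sites(
    genome: GenomeSequence, cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[RepeatCopy], GroundTruth]:
    """Insert repeat copies and true binding sites; return full ground truth.

    Repeat copies are per-base mutated clones of their family consensus; the
    motif-carrying family holds the core motif at a fixed consensus offset so
    every copy is a candidate binding site.  Dispersed sites are planted
    outside repeats.  The total site universe covers both samples
    (n_true_sites per sample with the configured sharing).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    arrays = {c: encode(s).copy() for c, s in genome.records.items()}
    placer = _Placer(arrays, rng)
    pi = stationary_distribution(cfg.transition)

    n_total = int(round(cfg.n_true_sites * (2.0 - cfg.shared_fraction)))
    n_motif = int(round(n_total * cfg.motif_fraction))
    n_family = int(round(n_motif * cfg.fraction_in_family))
    n_dispersed = n_motif - n_family
    n_motifless = n_total - n_motif

    core = encode(cfg.core_consensus)
    upstream = encode(cfg.upstream_consensus)
    w, ulen, gap = len(core), len(upstream), cfg.upstream_gap

    planted_bp = 0
    copies: list[RepeatCopy] = []
    sites: list[SiteTruth] = []

    for spec in cfg.families:
        n_copies = n_family if spec.carries_motif else spec.n_copies
        if spec.carries_motif and spec.consensus_length < cfg.core_offset + w + 10:
            raise ValueError("motif-family consensus too short for the core offset")
        consensus = _random_seq(spec.consensus_length, pi, rng)
        if spec.carries_motif:
            consensus[cfg.core_offset : cfg.core_offset + w] = core
        for k in range(n_copies):
            copy = _mutate(consensus, spec.divergence, rng)
            has_up = False
            if spec.carries_motif and rng.random() < cfg.upstream_fraction:
                has_up = True
                up_inst = _mutate(upstream, cfg.site_mutation_rate, rng)
                copy[cfg.core_offset - gap - ulen : cfg.core_offset - gap] = up_inst
            strand = "+" if rng.random() < 0.5 else "-"
            margin = 300 if spec.carries_motif else 20
            chrom, start = placer.place(len(copy), margin)
            inserted = copy if strand == "+" else (3 - copy[::-1]).astype(np.uint8)
            arrays[chrom][start : start + len(copy)] = inserted
            end = start + len(copy)
            div_obs = float(np.mean(copy != consensus)) * 100.0
            copies.append(
                RepeatCopy(
                    family_id=spec.family_id,
                    class_label=spec.class_label,
                    chrom=chrom,
                    start=start,
                    end=end,
                    divergence_pct=div_obs,
                    strand=strand,
                )
            )
            if spec.carries_motif:
                if strand == "+":
                    cs = start + cfg.core_offset
                else:
                    cs = end - cfg.core_offset - w
                sites.append(
                    SiteTruth(
                        site_id=f"site_{len(sites):05d}",
                        chrom=chrom,
                        center=cs + w // 2,
                        strand=strand,
                        has_core=True,
                        has_upstream=has_up,
                        family_id=spec.family_id,
                        core_start=cs,
                        core_end=cs + w,
                    )
                )
        planted_bp += n_copies * spec.consensus_length
    if planted_bp > 0.2 * genome.total_length():
        raise CapacityError("planted repeat material exceeds 20% of the genome")

    site_body = ulen + gap + w
    for _ in range(n_dispersed):
        strand = "+" if rng.random() < 0.5 else "-"
        has_up = rng.random() < cfg.upstream_fraction
        chrom, start = placer.place(site_body, 300)
        region = arrays[chrom][start : start + site_body]
        layout = region.copy()
        core_inst = _mutate(core, cfg.site_mutation_rate, rng)
        layout[ulen + gap :] = core_inst
        if has_up:
            layout[:ulen] = _mutate(upstream, cfg.site_mutation_rate, rng)
        if strand == "-":
            layout = (3 - layout[::-1]).astype(np.uint8)
            cs = start
        else:
            cs = start + ulen + gap
        arrays[chrom][start : start + site_body] = layout
        sites.append(
            SiteTruth(
                site_id=f"site_{len(sites):05d}",
                chrom=chrom,
                center=cs + w // 2,
                strand=strand,
                has_core=True,
                has_upstream=has_up,
                family_id=None,
                core_start=cs,
                core_end=cs + w,
            )
        )

    for _ in range(n_motifless):
        chrom, start = placer.place(30, 300)
        sites.append(
            SiteTruth(
                site_id=f"site_{len(sites):05d}",
                chrom=chrom,
                center=start + 15,
                strand=".",
                has_core=False,
                has_upstream=False,
                family_id=None,
                core_start=None,
                core_end=None,
            )
        )

    new_genome = GenomeSequence({c: _decode_arr(arrays[c]) for c in genome.records})
    for s in sites:
        if s.has_core:
            s.core_seq = new_genome.fetch(s.chrom, s.core_start, s.core_end)
    truth = GroundTruth(seed=cfg.seed, sites=sites, copies=copies)
    _assign_samples(truth, cfg, rng)
    return new_genome, copies, truth


def _assign_samples(truth: GroundTruth, cfg: GeneratorConfig, rng: np.random.Generator) -> None:
    n = cfg.n_true_sites
    n_shared = int(round(cfg.shared_fraction * n))
    n_uniq = n - n_shared
    family_ids = [s.site_id for s in truth.sites if s.family_id is not None]
    others = [s.site_id for s in truth.sites if s.family_id is None]
    if len(family_ids) > n_shared:
        raise ValueError("repeat-borne sites exceed the shared-site budget")
    perm = list(np.array(others)[rng.permutation(len(others))])
    shared = family_ids + perm[: n_shared - len(family_ids)]
    rest = perm[n_shared - len(family_ids) :]
    if len(rest) < 2 * n_uniq:
        raise ValueError("site universe too small for the requested sharing")
    a_only, b_only = rest[:n_uniq], rest[n_uniq : 2 * n_uniq]
    truth.shared_site_ids = sorted(shared)
    truth.true_shared_fraction = n_shared / n
    order = {s.site_id: i for i, s in enumerate(truth.sites)}
    sa, sb = cfg.samples
    truth.samples[sa] = SampleTruth(
        site_ids=sorted(shared + a_only, key=order.get),
        detected_rep1=[], detected_rep2=[], fe_merged={},
    )
    truth.samples[sb] = SampleTruth(
        site_ids=sorted(shared + b_only, key=order.get),
        detected_rep1=[], detected_rep2=[], fe_merged={},
    )


# ---------------------------------------------------------------------------
# peak simulation
# ---------------------------------------------------------------------------


def simulate_peak_calls(
    truth: GroundTruth,
    cfg: GeneratorConfig,
    sample: str,
    rng: np.random.Generator,
    genome: GenomeSequence,
) -> dict[str, list[PeakRecord]]:
    """Replicate and merged-run peak lists for one sample.

    Each true site is detected independently per replicate with the
    configured probability; the merged run detects the union and draws its
    own fold enrichment.  Noise peaks are run-specific uniform placements
    with low FE and no planted motif.
    """
    st = truth.samples[sample]
    site_map = {s.site_id: s for s in truth.sites}
    lengths = genome.lengths
    hw = cfg.peak_halfwidth
    runs: dict[str, list[PeakRecord]] = {"rep1": [], "rep2": [], "merged": []}
    st.detected_rep1 = []
    st.detected_rep2 = []
    st.fe_merged = {}

    def _mk_peak(run: str, idx: int, chrom: str, summit: int, fe: float) -> PeakRecord:
        L = lengths[chrom]
        summit = min(max(summit, 1), L - 2)
        start, end = max(0, summit - hw), min(L, summit + hw)
        return PeakRecord(
            chrom=chrom,
            start=start,
            end=end,
            name=f"{sample}_{run}_{idx:05d}",
            score=int(min(1000, fe * 10)),
            strand=".",
            fold_enrichment=round(fe, 4),
            summit_offset=summit - start,
        )

    p_det = cfg.replicate_detection_prob
    for site_id in st.site_ids:
        site = site_map[site_id]
        mu, sigma = cfg.fe_motif if site.has_core else cfg.fe_motifless
        fe_m = float(np.exp(rng.normal(mu, sigma)))
        d1 = rng.random() < p_det
        d2 = rng.random() < p_det
        jit = rng.normal(0.0, cfg.summit_jitter_sd, 3)
        fe_r = np.exp(rng.normal(mu, sigma, 2))
        if d1:
            st.detected_rep1.append(site_id)
            runs["rep1"].append(_mk_peak("rep1", len(runs["rep1"]), site.chrom,
                                         site.center + int(round(jit[0])), float(fe_r[0])))
        if d2:
            st.detected_rep2.append(site_id)
            runs["rep2"].append(_mk_peak("rep2", len(runs["rep2"]), site.chrom,
                                         site.center + int(round(jit[1])), float(fe_r[1])))
        if d1 or d2:
            st.fe_merged[site_id] = fe_m
            runs["merged"].append(_mk_peak("merged", len(runs["merged"]), site.chrom,
                                           site.center + int(round(jit[2])), fe_m))
    chroms = sorted(lengths)
    lens = np.array([lengths[c] for c in chroms], dtype=float)
    wts = lens / lens.sum()
    mu0, s0 = cfg.fe_noise
    for run in runs:
        for _ in range(cfg.n_noise_peaks):
            chrom = chroms[int(rng.choice(len(chroms), p=wts))]
            summit = int(rng.integers(hw, lengths[chrom] - hw))
            fe = float(np.exp(rng.normal(mu0, s0)))
            runs[run].append(_mk_peak(run, len(runs[run]), chrom, summit, fe))
    for run in runs:
        runs[run].sort(key=lambda p: (p.chrom, p.start))
    return runs


# ---------------------------------------------------------------------------
# toy Hox clusters
# ---------------------------------------------------------------------------


@dataclass
class HoxClusterTruth:
    cluster_name: str
    chrom: str
    axis: str
    site_positions: list[int]  # normalised
    site_orientations: list[str]
    site_repeat_flags: list[bool]
    site_segments: list[tuple]
    hox1_4_count: int
    outward_3prime: bool
    outward_5prime: bool


@dataclass
class HoxToyData:
    preset: str
    genome: GenomeSequence
    genes: list[GeneRecord]
    repeats: list[RepeatCopy]
    peaks: dict[str, list[PeakRecord]]
    truth: dict[str, HoxClusterTruth]


_HOX_LEAD = 10_000
_HOX_GENE_LEN = 2_000
_HOX_SPACING = 8_000
_HOX_N_GROUPS = 10
_HOX_CHROM_LEN = 110_000


def _hox_layout() -> list[tuple[str, int, int]]:
    """(name-suffix, norm_start, norm_end) for groups 1..10 plus Evx."""
    out = []
    for g in range(1, _HOX_N_GROUPS + 1):
        s = _HOX_LEAD + (g - 1) * _HOX_SPACING
        out.append((str(g), s, s + _HOX_GENE_LEN))
    evx_start = _HOX_LEAD + _HOX_N_GROUPS * _HOX_SPACING + 4_000
    out.append(("Evx", evx_start, evx_start + _HOX_GENE_LEN))
    return out


def _hox_sites(preset: str) -> list[tuple[int, str, bool, tuple]]:
    """(norm_pos, orientation, repeat_borne, segment_key) per planted site."""
    base = [
        (7_000, "reverse", False, ("flank3",)),
        (47_000, "forward", False, ("between", 5, 6)),
        (71_000, "reverse", False, ("between", 8, 9)),
        (99_000, "forward", False, ("flank5",)),
    ]
    if preset == "lamprey":
        base += [
            (15_000, "forward", True, ("between", 1, 2)),
            (23_000, "reverse", True, ("between", 2, 3)),
            (25_000, "forward", True, ("between", 2, 3)),
            (31_000, "forward", True, ("between", 3, 4)),
        ]
    elif preset != "gnathostome":
        raise ValueError(f"unknown Hox preset {preset!r}")
    return sorted(base)


def make_toy_hox(
    preset: str, cfg: GeneratorConfig | None = None, seed: int | None = None
) -> HoxToyData:
    """Two toy Hox clusters (opposite genomic axes) with planted site
    orientations; the 'lamprey' preset adds repeat-borne sites between
    paralog groups 1-4, the 'gnathostome' preset has none there."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 1_000_003 if seed is None else seed)
    pi = stationary_distribution(cfg.transition)
    core = encode(cfg.core_consensus)
    w = len(core)
    layout = _hox_layout()
    sites = _hox_sites(preset)
    clusters = [("A", "hoxI", "+"), ("B", "hoxII", "-")]

    records: dict[str, str] = {}
    genes: list[GeneRecord] = []
    repeats: list[RepeatCopy] = []
    peaks: dict[str, list[PeakRecord]] = {"rep1": [], "rep2": [], "merged": []}
    truth: dict[str, HoxClusterTruth] = {}

    for cname, chrom, axis in clusters:
        arr = _random_seq(_HOX_CHROM_LEN, pi, rng)

        def to_genomic(norm: int) -> int:
            return norm if axis == "+" else _HOX_CHROM_LEN - norm

        for suffix, ns, ne in layout:
            gs, ge = sorted((to_genomic(ns), to_genomic(ne)))
            name = f"Evx{cname}" if suffix == "Evx" else f"Hox{cname}{suffix}"
            genes.append(
                GeneRecord(name=name, chrom=chrom, start=gs, end=ge, strand="+",
                           paralog_group=parse_hox_name(name))
            )

        positions, orientations, rep_flags, segments = [], [], [], []
        for i, (npos, orientation, repeat_borne, seg) in enumerate(sites):
            gpos = to_genomic(npos)
            strand_fwd = orientation == "forward"
            strand = ("+" if strand_fwd else "-") if axis == "+" else ("-" if strand_fwd else "+")
            inst = _mutate(core, 0.03, rng)
            cs = gpos - w // 2
            arr[cs : cs + w] = inst if strand == "+" else (3 - inst[::-1]).astype(np.uint8)
            if repeat_borne:
                repeats.append(
                    RepeatCopy(
                        family_id="274",
                        class_label="DNA/hAT-Tip100",
                        chrom=chrom,
                        start=max(0, cs - 80),
                        end=cs + w + 80,
                        divergence_pct=5.0,
                        strand=strand,
                    )
                )
            fe = float(np.exp(rng.normal(3.6, 0.25)))  # well above the cutoff
            for run in peaks:
                jit = int(round(rng.normal(0.0, 2.0)))
                summit = gpos + jit
                start, end = summit - 150, summit + 150
                peaks[run].append(
                    PeakRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        name=f"hox_{cname}_{run}_{i:03d}",
                        score=500,
                        strand=".",
                        fold_enrichment=round(fe, 4),
                        summit_offset=summit - start,
                    )
                )
            positions.append(npos)
            orientations.append(orientation)
            rep_flags.append(repeat_borne)
            segments.append(seg)

        records[chrom] = _decode_arr(arr)
        truth[cname] = HoxClusterTruth(
            cluster_name=cname,
            chrom=chrom,
            axis=axis,
            site_positions=positions,
            site_orientations=orientations,
            site_repeat_flags=rep_flags,
            site_segments=segments,
            hox1_4_count=sum(
                1 for s in segments
                if s[0] == "between" and s[1] >= 1 and s[2] <= 4
            ),
            outward_3prime=True,
            outward_5prime=True,
        )
    for run in peaks:
        peaks[run].sort(key=lambda p: (p.chrom, p.start))
    return HoxToyData(
        preset=preset, genome=GenomeSequence(records), genes=genes,
        repeats=repeats, peaks=peaks, truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedBundle:
    cfg: GeneratorConfig
    genome: GenomeSequence
    repeats: list[RepeatCopy]
    truth: GroundTruth
    peak_calls: dict[str, dict[str, list[PeakRecord]]]
    hox: dict[str, HoxToyData]


def simulate_bundle(cfg: GeneratorConfig | None = None) -> SimulatedBundle:
    """Generate the full in-memory dataset: genome + repeats + two samples'
    peak calls + both toy Hox variants, all from cfg.seed."""
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(cfg.seed)
    r_genome, r_plant, r_peaks, r_hox = [np.random.default_rng(s) for s in ss.spawn(4)]
    genome = make_genome(cfg, r_genome)
    genome, repeats, truth = plant_repeats_and_sites(genome, cfg, r_plant)
    peak_calls = {}
    for sample in cfg.samples:
        peak_calls[sample] = simulate_peak_calls(truth, cfg, sample, r_peaks, genome)
    hox = {
        "lamprey": make_toy_hox("lamprey", cfg, seed=int(ss.generate_state(1)[0] % (2**31))),
        "gnathostome": make_toy_hox(
            "gnathostome", cfg, seed=int((ss.generate_state(2)[1] + 7) % (2**31))
        ),
    }
    return SimulatedBundle(cfg=cfg, genome=genome, repeats=repeats, truth=truth,
                           peak_calls=peak_calls, hox=hox)


def _truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["copies"] = [dataclasses.asdict(c) for c in truth.copies]
    return d


def write_dataset(outdir: str | Path, cfg: GeneratorConfig | None = None) -> SimulatedBundle:
    """Emit the bundle as plain-text files plus a structured truth file."""
    cfg = cfg or GeneratorConfig()
    bundle = simulate_bundle(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, out / "genome.fa")
    write_repeat_annotation(bundle.repeats, out / "repeats.bed", dialect="bed")
    write_repeat_annotation(bundle.repeats, out / "repeats.out", dialect="rmout")
    for sample, runs in bundle.peak_calls.items():
        for run, plist in runs.items():
            write_narrowpeak(plist, out / f"{sample}.{run}.narrowPeak")
    with open(out / "truth.json", "w") as fh:
        json.dump(_truth_to_dict(bundle.truth), fh, sort_keys=True, indent=1)
    for preset, hox in bundle.hox.items():
        hdir = out / f"hox_{preset}"
        hdir.mkdir(exist_ok=True)
        write_fasta(hox.genome, hdir / "genome.fa")
        write_gene_annotation(hox.genes, hdir / "genes.bed", format="bed")
        write_gene_annotation(hox.genes, hdir / "genes.gff3", format="gff3")
        write_repeat_annotation(hox.repeats, hdir / "repeats.bed", dialect="bed")
        for run, plist in hox.peaks.items():
            write_narrowpeak(plist, hdir / f"{run}.narrowPeak")
        with open(hdir / "truth.json", "w") as fh:
            json.dump(
                {k: dataclasses.asdict(v) for k, v in hox.truth.items()},
                fh, sort_keys=True, indent=1, default=list,
            )
    return bundle


def validate_dataset(outdir: str | Path) -> None:
    """Re-read an emitted bundle and assert internal consistency.

    Raises ValueError naming the missing or inconsistent piece.
    """
    out = Path(outdir)
    if not (out / "truth.json").exists():
        raise ValueError("dataset invalid: missing file truth.json")
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    expected = ["genome.fa", "repeats.bed", "repeats.out"]
    samples = sorted(truth["samples"])
    for sample in samples:
        for run in ("rep1", "rep2", "merged"):
            expected.append(f"{sample}.{run}.narrowPeak")
    for preset in ("lamprey", "gnathostome"):
        for name in ("genome.fa", "genes.bed", "genes.gff3", "repeats.bed",
                     "rep1.narrowPeak", "rep2.narrowPeak", "merged.narrowPeak",
                     "truth.json"):
            expected.append(f"hox_{preset}/{name}")
    for rel in expected:
        if not (out / rel).exists():
            raise ValueError(f"dataset invalid: missing file {rel}")

    genome = read_fasta(out / "genome.fa")
    bed = read_repeat_annotation(out / "repeats.bed", dialect="bed")
    rm = read_repeat_annotation(out / "repeats.out", dialect="rmout")
    if [(c.chrom, c.start, c.end, c.family_id) for c in bed] != [
        (c.chrom, c.start, c.end, c.family_id) for c in rm
    ]:
        raise ValueError("dataset invalid: repeats.bed and repeats.out disagree")
    fam_counts: dict[str, int] = {}
    for c in bed:
        fam_counts[c.family_id] = fam_counts.get(c.family_id, 0) + 1
    truth_counts: dict[str, int] = {}
    for c in truth["copies"]:
        truth_counts[c["family_id"]] = truth_counts.get(c["family_id"], 0) + 1
    if fam_counts != truth_counts:
        raise ValueError("dataset invalid: per-family copy counts do not match truth")
    for s in truth["sites"]:
        if s["has_core"] and genome.fetch(s["chrom"], s["core_start"], s["core_end"]) != s["core_seq"]:
            raise ValueError(f"dataset invalid: core sequence mismatch at {s['site_id']}")
    site_by_id = {s["site_id"]: s for s in truth["sites"]}
    for sample in samples:
        st = truth["samples"][sample]
        for run, det in (("rep1", st["detected_rep1"]), ("rep2", st["detected_rep2"]),
                         ("merged", sorted(st["fe_merged"]))):
            peaks = read_narrowpeak(out / f"{sample}.{run}.narrowPeak")
            if len(peaks) < len(det):
                raise ValueError(
                    f"dataset invalid: {sample}.{run} has fewer peaks than detections"
                )
            summits: dict[str, list[int]] = {}
            for p in peaks:
                summits.setdefault(p.chrom, []).append(p.summit)
            for v in summits.values():
                v.sort()
            for site_id in det:
                s = site_by_id[site_id]
                arr = summits.get(s["chrom"], [])
                i = int(np.searchsorted(arr, s["center"]))
                near = [arr[j] for j in (i - 1, i) if 0 <= j < len(arr)]
                if not near or min(abs(x - s["center"]) for x in near) > 100:
                    raise ValueError(
                        f"dataset invalid: {sample}.{run} lacks a peak near {site_id}"
                    )
    for preset in ("lamprey", "gnathostome"):
        hdir = out / f"hox_{preset}"
        gb = read_gene_annotation(hdir / "genes.bed", format="bed")
        gg = read_gene_annotation(hdir / "genes.gff3", format="gff3")
        if [dataclasses.asdict(g) for g in gb] != [dataclasses.asdict(g) for g in gg]:
            raise ValueError(f"dataset invalid: hox_{preset} BED/GFF3 gene sets disagree")


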