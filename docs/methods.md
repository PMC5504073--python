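# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real data.

## Peak selection

Consensus peaks are anchored on the merged-replicates run: a merged-run
peak is consensus when it overlaps (≥ 1 bp, half-open coordinates) at least
one peak in each replicate. Coordinates, summit, and fold enrichment (FE)
always come from the merged run, because the significance cutoff is defined
on merged-run FE. We deliberately keep whole merged-run peaks rather than
truncating to the three-way coordinate intersection; provenance (which
replicate peaks support each consensus peak) is recorded instead.
`mean_fe_rule` reports the consensus mean FE and suggests the nearest of
{5, 10, 20} below it, but the cutoff applied is always an explicit value —
round cutoffs chosen by eye from the mean are a convention, not a formula.
Cross-sample sharing uses the same ≥ 1 bp overlap; because overlap is not
one-to-one, Venn-style counts are reported per set.

## Two-part motif model

Discovery is single-motif ZOOPS EM: each sequence contributes zero or one
motif occurrence, with a uniform prior over the valid scan positions on
both strands and an occurrence probability γ shared across sequences.
The background is a 1st-order Markov model trained on the top-2,000 peak
windows (summit ± 100 bp) with pseudocount 0.01 added to every count cell;
the same pseudocount (times the background frequency) regularises PWM
estimation, mirroring common `--motif-pseudo 0.01` behaviour. Restarts are
seeded from the most over-represented exact w-mers, scored by Poisson
surprise `count·log(count/expected)` — the count weighting matters, since
unweighted ratios are dominated by rare words and, on repeat-rich peak
sets, by repeat-consensus fragments. The EM log-likelihood (reported up to
the constant all-background term) is non-decreasing by construction and is
asserted per iteration in tests.

Model selection: a ZOOPS fit on pure background can sharpen onto a handful
of windows, yielding a spuriously informative PWM at tiny γ. A discovered
motif is therefore accepted only when twice its log-likelihood gain over
the no-occurrence model exceeds a BIC penalty of (3w + 1)·ln n; otherwise
the background-flat PWM is returned and flagged non-significant. Genuine
motifs sit orders of magnitude above this bar (gain ≈ 10⁴ versus a penalty
of ≈ 350 at the default scale).

Core width is fixed at 16; the upstream (M2) motif width defaults to 10 and
is searched within the 20-bp extension 5′ of each best core hit, restricted
to the core hit's strand (the two-part geometry implies same-strand
pairing). A de-novo core PWM is orientation-ambiguous; the pipeline fixes
the orientation by running the upstream stage under both orientations of
the core and keeping the one whose upstream motif attains the higher
likelihood — i.e. the orientation is defined by the two-part geometry, as
the canonical core orientation is in the field.

## Exact PWM p-values

Scanning p-values are exact under the order-0 background marginalised from
the order-1 model: discovery uses the full order-1 background in its
E-step, but p-values use order 0, matching the semantics of standard PWM
scanners (a DP over an order-1 chain is disproportionately complex and
changes p-values negligibly for near-equilibrium backgrounds). Column
log-odds (log₂) are discretised to 1000 bins per column, rounding down, and
the distribution of the integer total score is built by convolution;
flooring makes reported p-values conservative. Scanning computes integer
scores per window with the same matrix on both strands (the minus strand
via the reverse-complemented integer matrix), so hit sets are exactly
strand-symmetric and minus-strand hits report forward-strand footprints.
Positions whose window contains N are skipped. Per-peak selection takes
the lowest p-value, breaking ties by higher score, then leftmost start,
then + strand.

## Repeat-family association

For family *f*: `a` = copies overlapping any FE ≥ 5 consensus-peak summit
window (± 50 bp), counted once per copy; `c` = copies overlapping any
control region. The tested table is `[[a, n_peaks − a], [c, n_controls − c]]`
— this construction numerically reproduces published per-family odds
ratios from printed counts, which is why it is adopted despite the table's
mixed units (copies vs. regions). The two-sided p-value uses the
probability method (sum of hypergeometric probabilities ≤ that of the
observed table); the default odds-ratio estimator is the conditional MLE
under Fisher's noncentral hypergeometric distribution, with the sample
estimator `(ad)/(bc)` available for audit. Both are provided because
printed values in the motivating literature sit within 0.1% of either.
Multiple testing uses Storey q-values with the fixed-λ = 0.5 π₀ estimate
when ≥ 50 families are tested, and Benjamini–Hochberg (π₀ = 1) below that,
where the π₀ estimate is unstable. The significance call is q < 1e-10 and
OR > 10.

Control regions are non-overlapping, N-free, fixed-length segments. The
sampler is exactly uniform over valid placements: maximal N-free blocks
are enumerated, the allocation of counts across blocks is drawn
proportional to the number of placements per block (log-binomial dynamic
programme), and within a block the placement uses the bijection between
non-overlapping interval sets and combinations. This guarantees success
whenever a placement exists (a 200-bp chromosome asked for two 100-bp
regions is tiled deterministically) while keeping the marginal start
distribution uniform in the sparse regime; capped rejection sampling, the
obvious alternative, can fail on feasible tight inputs. Excluding
peak-overlapping controls is available as a flag but off by default (plain
"arbitrary non-overlapping, N-free" controls are the reference condition).

## Hox-cluster maps

Clusters are normalised so the coordinate runs 3′→5′, increasing with
paralog group; the axis is inferred from the gene order. Orientation
convention (fixed before implementation): *forward* means the core motif's
5′→3′ direction points toward higher paralog groups; *outward* means
pointing away from the segment between the first and last gene bodies, so
outward at the 3′ (group-1) end is *reverse* and at the 5′ end *forward*.
A peak's segment is decided by its summit alone (the summit is the
binding-point estimate used throughout). The Hox1–4 count covers calls in
intergenic segments whose bounding genes both lie in groups 1–4. Cluster
ends default to a 10-kb flank. Cross-cluster comparison reduces segments
to paralog-group pair labels, making occupancy matrices comparable across
clusters and species; "shared" segments are those occupied in ≥ k clusters
(default 2) — one defensible formalisation of visually shared positioning.

## Synthetic-data generator

The generator defines the study conditions; every knob is seeded and
recorded in the emitted truth file.

* **Genome**: 6 Mb in 3 chromosomes from a 1st-order Markov chain
  (mildly GC-biased transition matrix), one 1-kb N block per chromosome to
  exercise N-aware control sampling. The 6-Mb scale (rather than a smaller
  genome) is needed for a realistic contrast between repeat density among
  peak windows and among controls: on a much smaller genome the
  motif-carrying family's genomic density alone caps its attainable odds
  ratio below the significance rule's OR > 10, regardless of how strongly
  its copies coincide with peaks.
* **Repeat families**: five families of per-base mutated consensus clones
  (divergence 8–15%, lengths 180–400 bp, 120–250 copies). One family
  ("274", hAT-Tip100-like, 180 bp) carries the 16-bp core motif at a fixed
  consensus offset, so binding sites propagate with the repeat; its copy
  number is derived from the site budget (fraction_in_family = 0.4 of
  motif-bearing sites).
* **Sites**: 1,500 per sample; 70% carry the core motif (planted at 8%
  per-base mutation), 50% of motif sites carry the upstream motif 14 bp 5′
  of the core (10-bp motif + 4-bp gap); the rest are motif-less bound
  sites (CTCF tethered without its core sequence, as in real data).
  Two samples share 75% of sites; all repeat-borne sites are shared.
* **Peaks**: each site is detected per replicate with probability 0.99;
  the merged run detects the union and draws its own FE. FE is log-normal:
  ln FE ~ N(2.89, 0.5) for motif-bearing sites, N(1.79, 0.5) for
  motif-less sites, N(1.10, 0.3) for the 300 run-specific noise peaks —
  giving a consensus mean FE near 16 and the FE–motif coupling that makes
  the core-motif fraction rise across FE bins. The detection probability
  follows from the design: with consensus recovery scaling as p², observed
  sharing ≈ 0.75·p² must stay within a few points of the planted 0.75,
  which requires p ≈ 0.99 — consistent with the near-complete replicate
  reproducibility of strong CTCF peaks. Summits are jittered (σ = 5 bp).
* **Toy Hox clusters**: two clusters on opposite genomic axes, paralog
  groups 1–10 plus Evx (2-kb bodies, 8-kb spacing), with planted
  high-FE sites: outward sites at both ends and interior sites between
  groups 5–6 and 8–9 in both presets; the lamprey-like preset adds four
  repeat-borne sites between groups 1–4, the gnathostome-like preset none.

What the generator does **not** emulate: read-level noise (peaks are drawn
directly — the pipeline's computation starts at peak lists), GC or
chromatin bias in peak detection, fragmented repeat copies, overlapping or
nested sites, and background binding inside non-planted repeat families.
The last point means non-planted families appear mildly *depleted* (their
copies never overlap planted sites) rather than OR ≈ 1; the significance
rule (q < 1e-10 **and** OR > 10) is one-sided in effect, so this does not
affect which families are flagged, but enrichment p-values for null
families should not be read as calibrated. Passing tests therefore
demonstrate correct recovery of planted structure under idealised peak
lists, not robustness to the full noise spectrum of real ChIP-seq.

## Problem sizes and determinism

Default analyses run on the 6-Mb bundle with 5,000 controls of 100 bp
(paper-scale runs with 50,000 controls use the same code path). EM uses 3
seeded restarts and converges in well under 100 iterations; a full
pipeline run takes a few seconds on one CPU. All randomness flows from a
single seed through named spawned streams; the emitted bundle is
byte-identical across runs, and the enrichment report records its control
seed.

## Known limitations

* Single-motif ZOOPS does not replicate a multi-motif, E-value-ranked
  search; the two motifs of interest are discovered in two targeted runs.
* Storey's π₀ uses the fixed-λ estimator only (no spline refinement).
* The order-0 p-value background slightly mismatches the order-1
  discovery background by design (see above).
* Hox "shared positioning" across clusters is formalised as segment
  co-occupancy by paralog-group labels; other readings are possible.
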