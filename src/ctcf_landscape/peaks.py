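"""Consensus-peak construction, significance filtering, and cross-sample sharing.

A *consensus peak* is a peak from the merged-replicates run that overlaps
(>= 1 bp) at least one peak in each individual replicate; its coordinates,
summit, and fold enrichment are taken from the merged run.  A *significant
peak* is a consensus peak whose merged-run fold enrichment meets an explicit
cutoff; the cutoff is conventionally a round number chosen by referring to
the mean fold enrichment of the consensus set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from ctcf_landscape.formats import PeakRecord
from ctcf_landscape.intervals import IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class ConsensusPeakSet:
    peaks: list[PeakRecord]
    provenance: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    sample_label: str = ""

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SignificanceRule:
    """Fold-enrichment cutoff for significant peaks, with the mean-FE basis."""

    fe_cutoff: float
    basis: float | None = None

    def __post_init__(self) -> None:
        if self.fe_cutoff <= 0:
            raise ValueError("fe_cutoff must be positive")


def consensus_peaks(
    rep1: Sequence[PeakRecord],
    rep2: Sequence[PeakRecord],
    merged: Sequence[PeakRecord],
    sample_label: str = "",
) -> ConsensusPeakSet:
    """Merged-run peaks supported by >=1 bp overlap in both replicates."""
    t1 = IntervalSet.from_peaks(rep1)
    t2 = IntervalSet.from_peaks(rep2)
    keep: list[PeakRecord] = []
    provenance: dict[str, tuple[list[str], list[str]]] = {}
    for p in merged:
        s1 = t1.query(p.chrom, p.start, p.end)
        if not s1:
            continue
        s2 = t2.query(p.chrom, p.start, p.end)
        if not s2:
            continue
        keep.append(p)
        provenance[p.name] = (
            [h[2].name for h in s1],
            [h[2].name for h in s2],
        )
    return ConsensusPeakSet(peaks=keep, provenance=provenance, sample_label=sample_label)


def mean_fe_rule(consensus: ConsensusPeakSet) -> SignificanceRule:
    """Report mean consensus FE and suggest the nearest of {5, 10, 20} below it.

    The suggestion mirrors the convention of picking a round cutoff by
    referring to the consensus mean; the cutoff stays an explicit value.
    """
    if not consensus.peaks:
        raise ValueError("cannot derive a rule from an empty consensus set")
    mean = sum(p.fold_enrichment for p in consensus.peaks) / len(consensus.peaks)
    below = [c for c in (5.0, 10.0, 20.0) if c <= mean]
    return SignificanceRule(fe_cutoff=max(below) if below else 5.0, basis=mean)


def significant_peaks(
    consensus: ConsensusPeakSet, rule: SignificanceRule
) -> list[PeakRecord]:
    """Consensus peaks with merged-run FE >= cutoff (boundary inclusive)."""
    return [p for p in consensus.peaks if p.fold_enrichment >= rule.fe_cutoff]


def shared_fraction(
    a: ConsensusPeakSet, b: ConsensusPeakSet
) -> tuple[float, float, dict[str, int]]:
    """Fraction of peaks in each set overlapping >=1 peak of the other.

    Returns (frac_a_in_b, frac_b_in_a, venn) where venn counts each set's
    shared and exclusive peaks (overlap need not be one-to-one, so shared
    counts are reported per set).
    """
    ta = IntervalSet.from_peaks(a.peaks)
    tb = IntervalSet.from_peaks(b.peaks)
    a_shared = sum(1 for p in a.peaks if tb.overlaps_any(p.chrom, p.start, p.end))
    b_shared = sum(1 for p in b.peaks if ta.overlaps_any(p.chrom, p.start, p.end))
    if not a.peaks or not b.peaks:
        logger.warning("shared_fraction: empty peak set; fraction defined as 0")
    fa = a_shared / len(a.peaks) if a.peaks else 0.0
    fb = b_shared / len(b.peaks) if b.peaks else 0.0
    venn = {
        "a_shared": a_shared,
        "b_shared": b_shared,
        "a_only": len(a.peaks) - a_shared,
        "b_only": len(b.peaks) - b_shared,
    }
    return fa, fb, venn


def top_peaks_by_fe(peaks: Sequence[PeakRecord], n: int = 2000) -> list[PeakRecord]:
    """The n highest-FE peaks; ties broken by (chrom, start) for determinism."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(peaks, key=lambda p: (-p.fold_enrichment, p.chrom, p.start))
    return ranked[:n]
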