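"""Orientation-aware mapping of CTCF binding sites across Hox clusters.

Clusters are normalised to a common frame: the coordinate runs from the
3' end (paralog group 1) toward the 5' end (group 13 / Evx), increasing
with paralog number regardless of the cluster's genomic strand.

Orientation convention table (fixed before implementation):

  ============================  ======================================
  motif strand / cluster axis    orientation in the normalised frame
  ============================  ======================================
  + / +                          forward  (5'->3' toward higher groups)
  - / +                          reverse
  + / -                          reverse
  - / -                          forward
  ============================  ======================================

"Outward" means pointing away from the segment spanned by the first and
last gene bodies: at the 3' (group-1) end outward = reverse, at the 5'
end outward = forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from ctcf_landscape.formats import GeneRecord, GenomeSequence, PeakRecord, RepeatCopy
from ctcf_landscape.intervals import IntervalSet
from ctcf_landscape.motifs import (
    PWM,
    ScorePvalueTable,
    best_hit_per_peak,
    peak_scan_windows,
    scan,
)

logger = logging.getLogger(__name__)


@dataclass
class HoxCluster:
    """A Hox cluster: ordered genes, genomic span, and axis direction.

    ``axis`` is '+' when paralog numbers increase with genomic coordinate.
    """

    species: str
    cluster_name: str
    genes: list[GeneRecord]
    axis: str
    chrom: str
    span: tuple[int, int]

    @classmethod
    def from_genes(cls, genes: Sequence[GeneRecord], species: str = "",
                   cluster_name: str = "") -> "HoxCluster":
        if len(genes) < 2:
            raise ValueError("a Hox cluster needs at least 2 genes")
        chroms = {g.chrom for g in genes}
        if len(chroms) != 1:
            raise ValueError("cluster genes span multiple chromosomes")
        ordered = sorted(genes, key=lambda g: g.start)
        numeric = [g for g in ordered if isinstance(g.paralog_group, int)]
        if len(numeric) < 2:
            raise ValueError("need >= 2 genes with numeric paralog groups to orient the cluster")
        axis = "+" if numeric[-1].paralog_group >= numeric[0].paralog_group else "-"
        cluster = cls(
            species=species,
            cluster_name=cluster_name,
            genes=ordered,
            axis=axis,
            chrom=ordered[0].chrom,
            span=(ordered[0].start, max(g.end for g in ordered)),
        )
        groups = [g.paralog_group for g in cluster.genes_by_paralog()
                  if isinstance(g.paralog_group, int)]
        if any(b < a for a, b in zip(groups, groups[1:])):
            logger.warning(
                "cluster %s: paralog groups not monotone along the normalised axis", cluster_name
            )
        return cluster

    def normalized(self, pos: int) -> int:
        """Map a genomic coordinate into the 3'->5' cluster frame."""
        return pos - self.span[0] if self.axis == "+" else self.span[1] - pos

    def genes_by_paralog(self) -> list[GeneRecord]:
        """Genes ordered along the normalised axis (increasing paralog)."""
        return sorted(self.genes, key=lambda g: min(self.normalized(g.start),
                                                    self.normalized(g.end)))

    def gene_norm_interval(self, gene: GeneRecord) -> tuple[int, int]:
        a, b = self.normalized(gene.start), self.normalized(gene.end)
        return (min(a, b), max(a, b))


@dataclass
class BindingSiteCall:
    """A significant peak mapped into a cluster frame.

    ``orientation`` is 'none' exactly when no core motif was found (the
    green-bar vs arrowhead distinction)."""

    peak_id: str
    position: int  # normalised summit coordinate
    orientation: str  # forward / reverse / none
    has_core_motif: bool
    overlaps_repeat: bool
    segment: str
    segment_key: tuple

    def __post_init__(self) -> None:
        if (self.orientation == "none") == self.has_core_motif:
            raise ValueError("orientation must be 'none' iff the peak lacks a core motif")


@dataclass
class ClusterProfile:
    cluster_name: str
    species: str
    segment_counts: dict[tuple, int]
    total: int
    hox1_4_count: int
    outward_3prime: bool | None
    outward_5prime: bool | None

    def __post_init__(self) -> None:
        if sum(self.segment_counts.values()) != self.total:
            raise ValueError("segment counts must sum to the total")


def peaks_in_cluster(
    significant_peaks: Sequence[PeakRecord], cluster: HoxCluster, flank_bp: int = 10000
) -> list[PeakRecord]:
    """Peaks whose summit lies within the cluster span +/- flank, sorted
    along the normalised axis."""
    lo, hi = cluster.span[0] - flank_bp, cluster.span[1] + flank_bp
    sel = [
        p
        for p in significant_peaks
        if p.chrom == cluster.chrom and lo <= p.summit < hi
    ]
    sel.sort(key=lambda p: cluster.normalized(p.summit))
    return sel


def _orientation(hit_strand: str, axis: str) -> str:
    return "forward" if hit_strand == axis else "reverse"


def assign_segment(cluster: HoxCluster, norm_pos: int) -> tuple[str, tuple]:
    """Label the intergenic segment bracketing a normalised position.

    Keys are canonical across clusters: ('between', lo_group, hi_group),
    ('within', group), ('flank3',) or ('flank5',); gene names appear only
    in the human-readable label.
    """
    genes = cluster.genes_by_paralog()
    ivs = [cluster.gene_norm_interval(g) for g in genes]
    if norm_pos < ivs[0][0]:
        return "3'-flank", ("flank3",)
    if norm_pos >= ivs[-1][1]:
        return "5'-flank", ("flank5",)
    for g, (a, b) in zip(genes, ivs):
        if a <= norm_pos < b:
            return f"within {g.name}", ("within", g.paralog_group)
    for (g1, (a1, b1)), (g2, (a2, b2)) in zip(
        list(zip(genes, ivs))[:-1], list(zip(genes, ivs))[1:]
    ):
        if b1 <= norm_pos < a2:
            return (
                f"between {g1.name} and {g2.name}",
                ("between", g1.paralog_group, g2.paralog_group),
            )
    # overlapping gene bodies can leave gaps unmatched above; fall back
    return "3'-flank", ("flank3",)


def call_binding_sites(
    cluster_peaks: Sequence[PeakRecord],
    cluster: HoxCluster,
    core_pwm: PWM,
    background0,
    genome: GenomeSequence,
    thresh_p: float = 1e-3,
    repeats: Sequence[RepeatCopy] | None = None,
    flank: int = 100,
    repeat_flank: int = 50,
) -> list[BindingSiteCall]:
    """One call per peak: the lowest-p core hit in summit +/- flank gives the
    orientation (normalised to the cluster axis); peaks without a hit are
    motif-less bars.  The repeat flag marks summit +/- repeat_flank windows
    overlapping any annotated repeat copy."""
    windows = peak_scan_windows(cluster_peaks, genome, flank)
    table = ScorePvalueTable(core_pwm, background0)
    hits = scan(windows, core_pwm, background0, thresh_p, table=table)
    best = best_hit_per_peak(hits)
    repeat_set = IntervalSet() if repeats is None else IntervalSet.from_tuples(
        (r.chrom, r.start, r.end) for r in repeats
    )
    calls = []
    for p in cluster_peaks:
        pos = cluster.normalized(p.summit)
        hit = best.get(p.name)
        orientation = _orientation(hit.strand, cluster.axis) if hit else "none"
        seg_label, seg_key = assign_segment(cluster, pos)
        calls.append(
            BindingSiteCall(
                peak_id=p.name,
                position=pos,
                orientation=orientation,
                has_core_motif=hit is not None,
                overlaps_repeat=repeat_set.overlaps_any(
                    p.chrom, max(0, p.summit - repeat_flank), p.summit + repeat_flank
                ),
                segment=seg_label,
                segment_key=seg_key,
            )
        )
    calls.sort(key=lambda c: c.position)
    return calls


def cluster_profile(calls: Sequence[BindingSiteCall], cluster: HoxCluster) -> ClusterProfile:
    """Summarise calls per intergenic segment, with Hox1-4 counts and
    outward-orientation flags at both cluster ends."""
    counts: dict[tuple, int] = {}
    for c in calls:
        counts[c.segment_key] = counts.get(c.segment_key, 0) + 1
    hox1_4 = sum(
        1
        for c in calls
        if c.segment_key[0] == "between"
        and isinstance(c.segment_key[1], int)
        and isinstance(c.segment_key[2], int)
        and c.segment_key[1] >= 1
        and c.segment_key[2] <= 4
    )
    ordered = sorted(calls, key=lambda c: c.position)
    outward3 = outward5 = None
    if ordered:
        outward3 = ordered[0].orientation == "reverse"
        outward5 = ordered[-1].orientation == "forward"
    return ClusterProfile(
        cluster_name=cluster.cluster_name,
        species=cluster.species,
        segment_counts=counts,
        total=len(calls),
        hox1_4_count=hox1_4,
        outward_3prime=outward3,
        outward_5prime=outward5,
    )


def _key_label(key: tuple) -> str:
    if key[0] == "between":
        return f"between {key[1]}-{key[2]}"
    if key[0] == "within":
        return f"within {key[1]}"
    return {"flank3": "3'-flank", "flank5": "5'-flank"}[key[0]]


def compare_profiles(profiles: Sequence[ClusterProfile], min_clusters: int = 2):
    """Cross-cluster comparison: segment-occupancy matrix (clusters x
    paralog-labelled segments), per-cluster totals, per-species maxima, and
    the segments occupied in at least ``min_clusters`` clusters."""
    import pandas as pd

    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    keys = sorted({k for p in profiles for k in p.segment_counts}, key=str)
    occupancy = pd.DataFrame(
        [[p.segment_counts.get(k, 0) for k in keys] for p in profiles],
        index=[f"{p.species}:{p.cluster_name}" if p.species else p.cluster_name
               for p in profiles],
        columns=[_key_label(k) for k in keys],
    )
    totals = {idx: int(occupancy.loc[idx].sum()) for idx in occupancy.index}
    max_per_species: dict[str, int] = {}
    for p in profiles:
        max_per_species[p.species] = max(max_per_species.get(p.species, 0), p.total)
    shared = [
        col for col in occupancy.columns if int((occupancy[col] > 0).sum()) >= min_clusters
    ]
    return {
        "occupancy": occupancy,
        "totals": totals,
        "max_per_species": max_per_species,
        "shared_segments": shared,
    }


def render_text_track(
    calls: Sequence[BindingSiteCall], cluster: HoxCluster, width: int = 100
) -> str:
    """ASCII rendering of a cluster: gene boxes on one line, binding sites
    below ('>' forward, '<' reverse, '|' no motif, '*' marks repeat overlap)."""
    lo = min([0] + [c.position for c in calls])
    hi = max([cluster.normalized(cluster.span[1] if cluster.axis == "+" else cluster.span[0])]
             + [c.position for c in calls]) + 1
    scale = (width - 1) / max(hi - lo, 1)

    def col(pos: int) -> int:
        return min(width - 1, max(0, int((pos - lo) * scale)))

    gene_line = [" "] * width
    for g in cluster.genes_by_paralog():
        a, b = cluster.gene_norm_interval(g)
        for x in range(col(a), col(b) + 1):
            gene_line[x] = "="
        label = str(g.paralog_group) if g.paralog_group is not None else "?"
        gene_line[col((a + b) // 2)] = label[-1]
    site_line = [" "] * width
    star_line = [" "] * width
    sym = {"forward": ">", "reverse": "<", "none": "|"}
    for c in calls:
        site_line[col(c.position)] = sym[c.orientation]
        if c.overlaps_repeat:
            star_line[col(c.position)] = "*"
    header = f"{cluster.species} {cluster.cluster_name} (3' -> 5')"
    return "\n".join([header, "".join(gene_line), "".join(site_line), "".join(star_line)])
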