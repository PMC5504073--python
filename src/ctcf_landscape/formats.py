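"""Readers and writers for the genomic file formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  Converters at the IO
boundary handle the 1-based inclusive conventions of RepeatMasker ``.out``
and GFF3.  Readers canonicalise (uppercase sequence, ``N`` for ambiguity
codes) so that every reader/writer pair round-trips canonical files
byte-identically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A genome as a mapping from sequence id to an ACGTN string."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.records[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"window [{start},{end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


@dataclass
class PeakRecord:
    """One ChIP-seq peak call (narrowPeak row).

    ``fold_enrichment`` is the peak caller's signalValue;
    ``summit_offset`` is the summit position relative to ``start``.
    """

    chrom: str
    start: int
    end: int
    name: str
    score: int = 0
    strand: str = "."
    fold_enrichment: float = 1.0
    neglog10_p: float | None = None
    neglog10_q: float | None = None
    summit_offset: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"peak {self.name}: bad interval [{self.start},{self.end})")
        if not (0 <= self.summit_offset < self.end - self.start):
            raise FormatError(f"peak {self.name}: summit offset {self.summit_offset} outside peak")
        if self.fold_enrichment <= 0:
            raise FormatError(f"peak {self.name}: fold enrichment must be positive")

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass
class RepeatCopy:
    """A single genomic instance of a repeat-library entry."""

    family_id: str
    class_label: str
    chrom: str
    start: int
    end: int
    divergence_pct: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"repeat {self.family_id}: bad interval [{self.start},{self.end})")
        if not self.family_id:
            raise FormatError("repeat copy with empty family id")

    @property
    def length(self) -> int:
        return self.end - self.start


EVX = "Evx"


@dataclass
class GeneRecord:
    """A (Hox-cluster) gene with its paralog-group assignment."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    paralog_group: int | str | None = None  # 1..13, EVX, or None if unparseable

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"gene {self.name}: bad interval")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.name}: strand must be + or -")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file, uppercasing and mapping non-ACGTN letters to N.

    The number of substituted letters is logged as a warning.
    """
    records: dict[str, str] = {}
    n_substituted = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        cleaned = re.sub(r"[^ACGTN]", "N", seq)
        n_substituted += sum(a != b for a, b in zip(seq, cleaned)) if cleaned != seq else 0
        records[rec.id] = cleaned
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if n_substituted:
        logger.warning("read_fasta(%s): %d non-ACGTN letters mapped to N", path, n_substituted)
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)
# ---------------------------------------------------------------------------


def _opt_neglog10(txt: str, line_no: int) -> float | None:
    v = float(txt)
    return None if v == -1 else v


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Parse an ENCODE narrowPeak file (10 tab-separated columns).

    Column 7 (signalValue) is interpreted as fold enrichment, column 10 as
    the summit offset.  A summit of -1 is rejected: the pipeline requires
    summit positions.
    """
    out: list[PeakRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{line_no}: expected 10 columns, found {len(fields)}"
                )
            try:
                summit = int(fields[9])
                if summit == -1:
                    raise FormatError(
                        f"{path}:{line_no}: summit offset -1; summits are required"
                    )
                out.append(
                    PeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=int(fields[4]),
                        strand=fields[5],
                        fold_enrichment=float(fields[6]),
                        neglog10_p=_opt_neglog10(fields[7], line_no),
                        neglog10_q=_opt_neglog10(fields[8], line_no),
                        summit_offset=summit,
                    )
                )
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return out


def _fmt_opt(v: float | None) -> str:
    return "-1" if v is None else f"{v:g}"


def write_narrowpeak(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.strand,
                        f"{p.fold_enrichment:g}",
                        _fmt_opt(p.neglog10_p),
                        _fmt_opt(p.neglog10_q),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# repeat annotations: RepeatMasker .out and BED dialects
# ---------------------------------------------------------------------------

_RMOUT_HEADER = (
    "   SW   perc perc perc  query     position in query              matching"
    "          repeat            position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)     repeat"
    "            class/family      begin  end    (left)  ID\n"
    "\n"
)


def read_repeat_annotation(path: str | Path, dialect: str = "bed") -> list[RepeatCopy]:
    """Read repeat copies from a RepeatMasker ``.out`` file or a BED dialect.

    ``rmout`` coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention; the BED dialect carries ``family#class`` in
    column 4 and is already half-open.
    """
    if dialect == "rmout":
        return _read_rmout(path)
    if dialect == "bed":
        return _read_repeat_bed(path)
    raise ValueError(f"unknown repeat dialect {dialect!r}")


def _read_rmout(path: str | Path) -> list[RepeatCopy]:
    out: list[RepeatCopy] = []
    with open(path) as fh:
        lines = fh.readlines()
    for line_no, line in enumerate(lines[3:], 4):  # 3-line header
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 12:
            raise FormatError(f"{path}:{line_no}: unparsable RepeatMasker line")
        try:
            start1, end1 = int(f[5]), int(f[6])
            strand = "-" if f[8] in {"C", "-"} else "+"
            out.append(
                RepeatCopy(
                    family_id=f[9],
                    class_label=f[10],
                    chrom=f[4],
                    start=start1 - 1,
                    end=end1,
                    divergence_pct=float(f[1]),
                    strand=strand,
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return out


def _read_repeat_bed(path: str | Path) -> list[RepeatCopy]:
    out: list[RepeatCopy] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{line_no}: expected >=4 BED columns")
            name = f[3]
            family_id, _, class_label = name.partition("#")
            try:
                div = None
                if len(f) >= 5 and f[4] not in {".", ""}:
                    div = float(f[4])
                strand = f[5] if len(f) >= 6 else "."
                out.append(
                    RepeatCopy(
                        family_id=family_id,
                        class_label=class_label,
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        divergence_pct=div,
                        strand=strand,
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return out


def write_repeat_annotation(
    copies: Iterable[RepeatCopy], path: str | Path, dialect: str = "bed"
) -> None:
    copies = list(copies)
    if dialect == "bed":
        with open(path, "w") as fh:
            for c in copies:
                div = "." if c.divergence_pct is None else f"{c.divergence_pct:g}"
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.family_id}#{c.class_label}"
                    f"\t{div}\t{c.strand}\n"
                )
    elif dialect == "rmout":
        with open(path, "w") as fh:
            fh.write(_RMOUT_HEADER)
            for i, c in enumerate(copies, 1):
                div = 0.0 if c.divergence_pct is None else c.divergence_pct
                strand = "C" if c.strand == "-" else "+"
                fh.write(
                    f"{1000:5d} {div:6.1f}  0.0  0.0  {c.chrom}  {c.start + 1} "
                    f"{c.end} (0) {strand} {c.family_id} {c.class_label} "
                    f"1 {c.end - c.start} (0) {i}\n"
                )
    else:
        raise ValueError(f"unknown repeat dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene annotations (Hox clusters): BED6 and GFF3
# ---------------------------------------------------------------------------

# Parse rule table for Hox-style gene names (written before implementation):
#   Hox5, HoxA5, hoxb4, Hox-D10     -> numeric paralog group
#   Greek cluster letters (lamprey-style), e.g. "Hoxα4", "Hoxε2" -> group 4, 2
#   Evx, EvxA, Evx1                 -> EVX marker
#   anything else                   -> None (kept, with a warning)
_HOX_RE = re.compile(r"^hox[-_]?([a-dα-ω]?)[-_]?(\d+)$", re.IGNORECASE)
_EVX_RE = re.compile(r"^evx", re.IGNORECASE)


def parse_hox_name(name: str) -> int | str | None:
    """Extract the paralog group from a Hox/Evx gene name, or None."""
    if _EVX_RE.match(name):
        return EVX
    m = _HOX_RE.match(name)
    if m:
        group = int(m.group(2))
        if 1 <= group <= 13:
            return group
    return None


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneRecord]:
    """Read Hox-cluster gene annotations from BED6 or GFF3."""
    if format == "bed":
        rows = _read_gene_bed(path)
    elif format == "gff3":
        rows = _read_gene_gff3(path)
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
    out = []
    for name, chrom, start, end, strand in rows:
        group = parse_hox_name(name)
        if group is None:
            logger.warning("gene name %r: paralog group unparseable; kept with group=None", name)
        out.append(GeneRecord(name=name, chrom=chrom, start=start, end=end, strand=strand,
                              paralog_group=group))
    return out


def _read_gene_bed(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{line_no}: expected BED6")
            rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return rows


def _read_gene_gff3(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{line_no}: expected 9 GFF3 columns")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise FormatError(f"{path}:{line_no}: gene without Name/ID attribute")
            # GFF3 is 1-based inclusive
            rows.append((name, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return rows


def write_gene_annotation(
    genes: Iterable[GeneRecord], path: str | Path, format: str = "bed"
) -> None:
    genes = list(genes)
    if format == "bed":
        with open(path, "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tctcf_landscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.name};Name={g.name}\n"
                )
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
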