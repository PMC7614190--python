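"""Genomic interval arithmetic, gene/peak data model, and BED / gene-table IO.

All coordinates are 0-based half-open (BED convention) throughout. The TSS of
a minus-strand gene is ``end - 1`` (its last covered base); strand must be
explicit — genes with unknown strand are rejected at load time.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "PeakSet",
    "ValidationError",
    "ParseError",
    "read_gene_table",
    "read_gtf_genes",
    "read_bed",
    "write_bed",
    "tss",
    "tss_window",
    "scoring_region",
    "assign_peaks",
]


class ValidationError(ValueError):
    """Input violates a model invariant."""


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_VALID_STRANDS = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


@dataclass(frozen=True)
class GeneModel:
    """A gene body (TSS to TES) with strand; one TSS per gene."""

    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class Peak:
    """A named interval from a peak caller, tagged with its assay."""

    peak_id: str
    interval: GenomicInterval
    assay: str = ""


class PeakSet:
    """Non-overlapping peaks for one assay, sorted by (chrom, start, peak_id).

    Overlapping input peaks are merged on construction (interval union, ids
    joined with ``+``) so summed signals never double-count a region.
    """

    def __init__(self, peaks: Iterable[Peak], assay: str = "", merge: bool = True):
        self.assay = assay
        peaks = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.peak_id)
        )
        if merge:
            peaks = self._merge(peaks, assay)
        seen: set[str] = set()
        for p in peaks:
            if p.peak_id in seen:
                raise ValidationError(f"duplicate peak_id {p.peak_id!r}")
            seen.add(p.peak_id)
        self.peaks: list[Peak] = peaks
        self._by_id = {p.peak_id: p for p in peaks}
        # per-chrom start/end arrays for binary-search overlap queries
        self._index: dict[str, tuple[list[int], list[Peak]]] = {}
        for p in peaks:
            starts, plist = self._index.setdefault(p.interval.chrom, ([], []))
            starts.append(p.interval.start)
            plist.append(p)

    @staticmethod
    def _merge(peaks: Sequence[Peak], assay: str) -> list[Peak]:
        merged: list[Peak] = []
        for p in peaks:
            if (
                merged
                and merged[-1].interval.chrom == p.interval.chrom
                and p.interval.start < merged[-1].interval.end
            ):
                last = merged[-1]
                merged[-1] = Peak(
                    peak_id=f"{last.peak_id}+{p.peak_id}",
                    interval=GenomicInterval(
                        last.interval.chrom,
                        last.interval.start,
                        max(last.interval.end, p.interval.end),
                    ),
                    assay=assay,
                )
            else:
                merged.append(Peak(p.peak_id, p.interval, assay))
        return merged

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._by_id

    def get(self, peak_id: str) -> Peak:
        return self._by_id[peak_id]

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def overlapping(
        self, region: GenomicInterval, min_overlap: int = 1
    ) -> list[Peak]:
        """Peaks overlapping ``region`` by >= min_overlap bp, in (start, id) order."""
        entry = self._index.get(region.chrom)
        if entry is None:
            return []
        starts, plist = entry
        # peaks are non-overlapping, so a peak overlapping the region starts
        # after (region.start - max_peak_len); scan from the first candidate.
        i = bisect_left(starts, region.start)
        # step back while earlier peaks may still reach into the region
        j = i
        while j > 0 and plist[j - 1].interval.end > region.start:
            j -= 1
        hits = []
        for p in plist[j:]:
            if p.interval.start >= region.end:
                break
            if p.interval.overlap_bp(region) >= min_overlap:
                hits.append(p)
        return hits


# ---------------------------------------------------------------------------
# IO


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table with header gene_id, name, chrom, start, end, strand."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "name", "chrom", "start", "end", "strand"]
        if header[: len(required)] != required:
            raise ParseError(
                f"{path}: expected header {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            gene_id, name, chrom, start_s, end_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            strand = _VALID_STRANDS.get(strand, strand)
            try:
                genes.append(
                    GeneModel(gene_id, name, GenomicInterval(chrom, start, end), strand)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tname\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.name}\t{g.interval.chrom}\t"
                f"{g.interval.start}\t{g.interval.end}\t{g.strand}\n"
            )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read 'gene' features from a minimal GTF subset (gene_id / gene_name attrs).

    GTF is 1-based closed; converted to 0-based half-open on load.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = attr["gene_id"]
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            genes.append(
                GeneModel(
                    gene_id,
                    attr.get("gene_name", gene_id),
                    GenomicInterval(chrom, start, end),
                    _VALID_STRANDS.get(strand, strand),
                )
            )
    return genes


def read_bed(path: str | Path, assay: str = "", merge: bool = True) -> PeakSet:
    """Read a BED3+ file into a PeakSet.

    Column 4 supplies the peak id when present; otherwise ids are synthesized
    as ``chrom:start-end``. Columns beyond 4 are ignored.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            peak_id = fields[3] if len(fields) >= 4 and fields[3] else str(iv)
            peaks.append(Peak(peak_id, iv, assay))
    return PeakSet(peaks, assay=assay, merge=merge)


def write_bed(
    records: PeakSet | Iterable[Peak] | Iterable[GenomicInterval],
    path: str | Path,
) -> None:
    """Write peaks as BED4 (bare intervals as BED3)."""
    with Path(path).open("w") as fh:
        for rec in records:
            if isinstance(rec, Peak):
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.peak_id}\n")
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")


# ---------------------------------------------------------------------------
# Window logic


def tss(gene: GeneModel) -> int:
    """Transcription start site: interval start (+) or end - 1 (-)."""
    return gene.interval.start if gene.strand == "+" else gene.interval.end - 1


def tss_window(gene: GeneModel, half_width: int = 2000) -> GenomicInterval:
    """[TSS - half_width, TSS + half_width), left-clipped at 0."""
    if half_width <= 0:
        raise ValidationError(f"half_width must be > 0, got {half_width}")
    center = tss(gene)
    return GenomicInterval(
        gene.interval.chrom, max(0, center - half_width), center + half_width
    )


def scoring_region(gene: GeneModel, promoter_extension: int = 1000) -> GenomicInterval:
    """Gene body extended strand-aware upstream by ``promoter_extension`` bp."""
    if promoter_extension < 0:
        raise ValidationError("promoter_extension must be >= 0")
    iv = gene.interval
    if gene.strand == "+":
        return GenomicInterval(iv.chrom, max(0, iv.start - promoter_extension), iv.end)
    return GenomicInterval(iv.chrom, iv.start, iv.end + promoter_extension)


def assign_peaks(
    peaks: PeakSet, region: GenomicInterval, min_overlap: int = 1
) -> list[Peak]:
    """Peaks overlapping ``region`` by >= min_overlap bp (default any overlap)."""
    return peaks.overlapping(region, min_overlap=min_overlap)
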