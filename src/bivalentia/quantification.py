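"""Reads-in-peaks tabulation, RPM normalization, per-gene signal and log-fold-change.

The quantitative chain is: fragments -> per-peak counts (``SampleCounts``)
-> reads-per-million (``RpmTable``) -> summed per-gene signal over the gene
body + 1 kb promoter extension (``GeneSignal``) -> knockout-vs-control log2
fold change with a symmetric pseudocount (``GeneLfc``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    assign_peaks,
    read_bed,
    scoring_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SampleCounts",
    "RpmTable",
    "GeneSignal",
    "GeneLfc",
    "count_fragments_in_peaks",
    "rpm_normalize",
    "gene_signal",
    "gene_lfc",
    "read_fragments_bed",
    "write_counts_matrix",
    "read_counts_matrix",
]


@dataclass
class SampleCounts:
    """Per-peak read counts for one sample, with its total mapped-read depth."""

    sample_id: str
    assay: str
    condition: str
    library_size: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: library_size must be positive"
            )
        bad = [pid for pid, c in self.counts.items() if c < 0]
        if bad:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative counts for {bad[:3]}"
            )


class RpmTable:
    """Reads-per-million per (peak, sample), with sample -> condition labels."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]):
        self.values = values  # index: peak_id, columns: sample_id
        self.conditions = dict(conditions)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_mean(self, condition: str | None = None) -> pd.Series:
        """Mean RPM per peak over the samples of one condition (or all)."""
        cols = self.samples_for(condition) if condition is not None else self.sample_ids
        if not cols:
            raise ValidationError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)

    def max_over_samples(self) -> pd.Series:
        return self.values.max(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "peak_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


class GeneSignal:
    """Summed RPM per (gene, sample) over each gene's scoring region."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]):
        self.values = values  # index: gene_id, columns: sample_id
        self.conditions = dict(conditions)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def condition_mean(self, condition: str | None = None) -> pd.Series:
        cols = (
            [s for s, c in self.conditions.items() if c == condition]
            if condition is not None
            else list(self.values.columns)
        )
        if not cols:
            raise ValidationError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)

    def aggregate(self, how: str = "mean") -> pd.Series:
        """Collapse replicate samples to one value per gene (``mean`` or ``sum``)."""
        if how == "mean":
            return self.values.mean(axis=1)
        if how == "sum":
            return self.values.sum(axis=1)
        raise ValidationError(f"unknown replicate aggregation {how!r}")

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class GeneLfc:
    """log2 knockout/control per gene, computed with a symmetric pseudocount."""

    values: pd.Series
    pseudocount: float

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.rename("log2fc").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------


def read_fragments_bed(path: str | Path) -> list[GenomicInterval]:
    """Read fragment intervals from a BED3 file (no merging)."""
    ps = read_bed(path, merge=False)
    return [p.interval for p in ps]


def write_counts_matrix(
    samples: Sequence[SampleCounts], path: str | Path, sidecar: str | Path
) -> None:
    """Write peaks x samples counts plus a sidecar of per-sample metadata."""
    mat = pd.DataFrame({s.sample_id: pd.Series(s.counts, dtype=int) for s in samples})
    mat = mat.fillna(0).astype(int).sort_index()
    mat.index.name = "peak_id"
    mat.to_csv(path, sep="\t")
    with Path(sidecar).open("w") as fh:
        fh.write("sample_id\tassay\tcondition\tlibrary_size\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.assay}\t{s.condition}\t{s.library_size}\n")


def read_counts_matrix(path: str | Path, sidecar: str | Path) -> list[SampleCounts]:
    mat = pd.read_csv(path, sep="\t", index_col="peak_id")
    meta = pd.read_csv(sidecar, sep="\t", index_col="sample_id")
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"sidecar lacks samples {missing[:3]}")
    return [
        SampleCounts(
            sample_id=str(s),
            assay=str(meta.loc[s, "assay"]),
            condition=str(meta.loc[s, "condition"]),
            library_size=int(meta.loc[s, "library_size"]),
            counts={str(p): int(c) for p, c in mat[s].items()},
        )
        for s in mat.columns
    ]


def count_fragments_in_peaks(
    fragments: Iterable[GenomicInterval],
    peaks: PeakSet,
    library_size: int,
    sample_id: str = "sample",
    assay: str = "",
    condition: str = "",
) -> SampleCounts:
    """Tabulate reads in peaks: each fragment increments every peak it overlaps.

    ``library_size`` is the sample's total mapped reads and must be at least
    the number of fragments supplied (fragments outside all peaks count
    toward depth only).
    """
    fragments = list(fragments)
    if library_size < len(fragments):
        raise ValidationError(
            f"library_size {library_size} < fragment count {len(fragments)}"
        )
    counts = {pid: 0 for pid in peaks.peak_ids}
    for frag in fragments:
        for peak in peaks.overlapping(frag):
            counts[peak.peak_id] += 1
    return SampleCounts(
        sample_id=sample_id,
        assay=assay or peaks.assay,
        condition=condition,
        library_size=library_size,
        counts=counts,
    )


def rpm_normalize(samples: SampleCounts | Sequence[SampleCounts]) -> RpmTable:
    """count * 1e6 / library_size per peak; columns are samples."""
    if isinstance(samples, SampleCounts):
        samples = [samples]
    if not samples:
        raise ValidationError("no samples supplied")
    cols = {}
    conditions = {}
    for s in samples:
        if s.sample_id in cols:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        cols[s.sample_id] = pd.Series(s.counts, dtype=float) * 1e6 / s.library_size
        conditions[s.sample_id] = s.condition
    values = pd.DataFrame(cols).fillna(0.0)
    return RpmTable(values, conditions)


def gene_signal(
    rpm: RpmTable,
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_extension: int = 1000,
) -> GeneSignal:
    """Sum RPM over peaks assigned to each gene's scoring region, per sample.

    A peak overlapping two genes' regions contributes to both. Genes on
    chromosomes absent from the peak set get zero signal (logged, not an
    error).
    """
    missing = [pid for pid in peaks.peak_ids if pid not in rpm.values.index]
    if missing:
        raise ValidationError(f"RPM table lacks peaks {missing[:3]}")
    chroms = {p.interval.chrom for p in peaks}
    rows = np.zeros((len(genes), len(rpm.sample_ids)))
    mat = rpm.values
    for i, gene in enumerate(genes):
        if gene.interval.chrom not in chroms:
            logger.debug("gene %s: chromosome absent from peak set", gene.gene_id)
            continue
        region = scoring_region(gene, promoter_extension)
        hit_ids = [p.peak_id for p in assign_peaks(peaks, region)]
        if hit_ids:
            rows[i] = mat.loc[hit_ids].to_numpy().sum(axis=0)
    values = pd.DataFrame(
        rows, index=[g.gene_id for g in genes], columns=rpm.sample_ids
    )
    return GeneSignal(values, rpm.conditions)


def gene_lfc(
    ko: GeneSignal,
    ctrl: GeneSignal,
    pseudocount: float = 0.5,
    replicate_agg: str = "mean",
) -> GeneLfc:
    """log2((ko + pc) / (ctrl + pc)), replicates aggregated on the RPM scale."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if set(ko.gene_ids) != set(ctrl.gene_ids):
        raise ValidationError("knockout and control gene universes differ")
    a = ko.aggregate(replicate_agg)
    b = ctrl.aggregate(replicate_agg).reindex(a.index)
    values = np.log2((a + pseudocount) / (b + pseudocount))
    return GeneLfc(values=values, pseudocount=pseudocount)
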