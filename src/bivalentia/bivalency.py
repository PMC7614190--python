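"""Promoter chromatin-state classification from paired H3K4me3/H3K27me3 peaks.

A gene is bivalent when peaks of both marks fall within +/-2 kb of its TSS;
with only one mark it is k4_only / k27_only, with neither it is unmarked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .genome_model import (
    GeneModel,
    PeakSet,
    ValidationError,
    assign_peaks,
    tss_window,
)

__all__ = ["BivalencyCall", "classify_bivalency", "bivalent_gene_set", "write_calls"]

STATES = ("bivalent", "k4_only", "k27_only", "unmarked")


@dataclass(frozen=True)
class BivalencyCall:
    gene_id: str
    state: str
    k4_peaks: tuple[str, ...]
    k27_peaks: tuple[str, ...]


def _state(k4: Sequence[str], k27: Sequence[str]) -> str:
    if k4 and k27:
        return "bivalent"
    if k4:
        return "k4_only"
    if k27:
        return "k27_only"
    return "unmarked"


def classify_bivalency(
    genes: Sequence[GeneModel],
    k4: PeakSet,
    k27: PeakSet,
    half_width: int = 2000,
    expected_k4_assay: str | None = "H3K4me3",
    expected_k27_assay: str | None = "H3K27me3",
) -> list[BivalencyCall]:
    """Classify each gene by which marks have peaks in its TSS window.

    Peak membership is any-overlap (>= 1 bp) with [TSS - half_width,
    TSS + half_width). Assay labels are checked when the peak sets carry
    them, to catch swapped inputs; pass ``expected_*_assay=None`` to skip.
    """
    for ps, expected, role in ((k4, expected_k4_assay, "k4"), (k27, expected_k27_assay, "k27")):
        if expected is not None and ps.assay and ps.assay != expected:
            raise ValidationError(
                f"{role} peak set labelled {ps.assay!r}, expected {expected!r}"
            )
    calls = []
    for gene in genes:
        window = tss_window(gene, half_width)
        k4_hits = tuple(p.peak_id for p in assign_peaks(k4, window))
        k27_hits = tuple(p.peak_id for p in assign_peaks(k27, window))
        calls.append(
            BivalencyCall(gene.gene_id, _state(k4_hits, k27_hits), k4_hits, k27_hits)
        )
    return calls


def bivalent_gene_set(calls: Sequence[BivalencyCall]) -> list[str]:
    """Sorted gene_ids with state == bivalent."""
    return sorted(c.gene_id for c in calls if c.state == "bivalent")


def write_calls(calls: Sequence[BivalencyCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tstate\tn_k4_peaks\tn_k27_peaks\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.state}\t{len(c.k4_peaks)}\t{len(c.k27_peaks)}\n")
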