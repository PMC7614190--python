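"""Occupancy-redistribution analysis for a chromatin factor (KMT2A-style).

Pipeline: keep peaks with >= 1 RPM in both the factor and H3K4me3 samples,
classify each kept peak by the knockout-minus-control change in condition-mean
factor RPM (threshold 1 RPM in either direction), roll peak categories up to
genes via TSS windows, then summarize each gene group's bivalent composition
and mark-level log-fold-change distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .bivalency import BivalencyCall
from .genome_model import GeneModel, PeakSet, ValidationError, assign_peaks, tss_window
from .quantification import GeneLfc, RpmTable

__all__ = [
    "PeakChanges",
    "GroupComposition",
    "RedistributionResult",
    "filter_covered_peaks",
    "classify_peak_changes",
    "rollup_to_genes",
    "group_composition",
    "mark_shift_summary",
    "redistribution_analysis",
]

PEAK_CATEGORIES = ("reduced", "increased", "unchanged")
GENE_CATEGORIES = ("reduced", "increased", "unchanged", "not_covered")


@dataclass
class PeakChanges:
    """Per-peak change category plus the condition-mean delta that produced it."""

    categories: dict[str, str]  # peak_id -> reduced | increased | unchanged
    deltas: dict[str, float]  # peak_id -> mean(ko) - mean(ctrl), RPM
    delta_rpm: float

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("peak_id\tcategory\tdelta_rpm\n")
            for pid in sorted(self.categories):
                fh.write(f"{pid}\t{self.categories[pid]}\t{self.deltas[pid]:.6g}\n")


@dataclass(frozen=True)
class GroupComposition:
    group: str
    n_genes: int
    n_bivalent: int

    @property
    def fraction_bivalent(self) -> float:
        if self.n_genes == 0:
            raise ValidationError("fraction undefined for an empty group")
        return self.n_bivalent / self.n_genes


def filter_covered_peaks(
    factor_rpm: RpmTable, k4_rpm: RpmTable, min_rpm: float = 1.0
) -> set[str]:
    """Peaks with max-over-samples RPM >= min_rpm in BOTH tables (inclusive)."""
    if factor_rpm.values.empty or k4_rpm.values.empty:
        raise ValidationError("RPM tables must be non-empty")
    shared = factor_rpm.values.index.intersection(k4_rpm.values.index)
    f_ok = factor_rpm.max_over_samples().loc[shared] >= min_rpm
    k_ok = k4_rpm.max_over_samples().loc[shared] >= min_rpm
    return set(shared[f_ok & k_ok])


def classify_peak_changes(
    rpm_ctrl: RpmTable,
    rpm_ko: RpmTable,
    covered: set[str],
    delta_rpm: float = 1.0,
) -> PeakChanges:
    """Category per covered peak from the knockout-minus-control mean RPM delta.

    increased iff delta >= delta_rpm; reduced iff delta <= -delta_rpm (both
    inclusive); otherwise unchanged.
    """
    missing = [p for p in covered if p not in rpm_ctrl.values.index]
    missing += [p for p in covered if p not in rpm_ko.values.index]
    if missing:
        raise ValidationError(f"covered peaks missing from RPM tables: {sorted(set(missing))[:3]}")
    ctrl_mean = rpm_ctrl.condition_mean()
    ko_mean = rpm_ko.condition_mean()
    categories: dict[str, str] = {}
    deltas: dict[str, float] = {}
    for pid in sorted(covered):
        d = float(ko_mean[pid] - ctrl_mean[pid])
        deltas[pid] = d
        if d >= delta_rpm:
            categories[pid] = "increased"
        elif d <= -delta_rpm:
            categories[pid] = "reduced"
        else:
            categories[pid] = "unchanged"
    return PeakChanges(categories=categories, deltas=deltas, delta_rpm=delta_rpm)


def rollup_to_genes(
    changes: PeakChanges,
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    half_width: int = 2000,
) -> dict[str, str]:
    """Gene category from the covered peaks in its TSS window.

    increased if >= 1 increased peak and no reduced peak; reduced
    symmetrically; unchanged if covered peaks exist but neither direction
    dominates. A window containing both directions takes the direction with
    the larger summed |delta|; a tie is unchanged. Genes with no covered peak
    in the window are not_covered.
    """
    out: dict[str, str] = {}
    for gene in genes:
        window = tss_window(gene, half_width)
        in_window = [
            p.peak_id
            for p in assign_peaks(peaks, window)
            if p.peak_id in changes.categories
        ]
        if not in_window:
            out[gene.gene_id] = "not_covered"
            continue
        cats = {changes.categories[pid] for pid in in_window}
        if "increased" in cats and "reduced" in cats:
            up = sum(
                changes.deltas[pid]
                for pid in in_window
                if changes.categories[pid] == "increased"
            )
            down = -sum(
                changes.deltas[pid]
                for pid in in_window
                if changes.categories[pid] == "reduced"
            )
            if up > down:
                out[gene.gene_id] = "increased"
            elif down > up:
                out[gene.gene_id] = "reduced"
            else:
                out[gene.gene_id] = "unchanged"
        elif "increased" in cats:
            out[gene.gene_id] = "increased"
        elif "reduced" in cats:
            out[gene.gene_id] = "reduced"
        else:
            out[gene.gene_id] = "unchanged"
    return out


@dataclass
class RedistributionResult:
    """Full output of the redistribution pipeline."""

    peak_changes: PeakChanges
    gene_categories: dict[str, str]
    composition: dict[str, GroupComposition]
    params: dict = field(default_factory=dict)


def redistribution_analysis(
    sites: PeakSet,
    factor_rpm_ctrl: RpmTable,
    factor_rpm_ko: RpmTable,
    k4_rpm: RpmTable,
    genes: Sequence[GeneModel],
    bivalency: Sequence[BivalencyCall],
    min_rpm: float = 1.0,
    delta_rpm: float = 1.0,
    half_width: int = 2000,
) -> RedistributionResult:
    """Filter -> classify -> roll up -> composition, in one call.

    ``k4_rpm`` is the H3K4me3 signal tabulated over the same ``sites`` as the
    factor (the coverage co-requirement); the factor coverage filter pools
    control and knockout samples.
    """
    factor_all = RpmTable(
        pd.concat([factor_rpm_ctrl.values, factor_rpm_ko.values], axis=1).fillna(0.0),
        {**factor_rpm_ctrl.conditions, **factor_rpm_ko.conditions},
    )
    covered = filter_covered_peaks(factor_all, k4_rpm, min_rpm=min_rpm)
    changes = classify_peak_changes(factor_rpm_ctrl, factor_rpm_ko, covered, delta_rpm)
    gene_categories = rollup_to_genes(changes, genes, sites, half_width)
    composition = group_composition(gene_categories, bivalency)
    return RedistributionResult(
        peak_changes=changes,
        gene_categories=gene_categories,
        composition=composition,
        params={"min_rpm": min_rpm, "delta_rpm": delta_rpm, "tss_half_width": half_width},
    )


def group_composition(
    gene_categories: Mapping[str, str],
    bivalency: Sequence[BivalencyCall],
) -> dict[str, GroupComposition]:
    """Bivalent counts per gene category; empty categories are omitted."""
    bivalent = {c.gene_id for c in bivalency if c.state == "bivalent"}
    out: dict[str, GroupComposition] = {}
    for cat in GENE_CATEGORIES:
        members = [g for g, c in gene_categories.items() if c == cat]
        if not members:
            continue
        out[cat] = GroupComposition(
            group=cat,
            n_genes=len(members),
            n_bivalent=sum(g in bivalent for g in members),
        )
    return out


def mark_shift_summary(
    gene_categories: Mapping[str, str],
    mark_lfcs: Mapping[str, GeneLfc],
) -> pd.DataFrame:
    """Median and quartiles of per-gene LFC, per gene category and mark."""
    universes = [set(lfc.values.index) for lfc in mark_lfcs.values()]
    if universes and any(u != universes[0] for u in universes):
        raise ValidationError("mark LFC tables must share one gene universe")
    rows = []
    for cat in GENE_CATEGORIES:
        members = [g for g, c in gene_categories.items() if c == cat]
        if not members:
            continue
        for mark, lfc in mark_lfcs.items():
            vals = lfc.values.reindex(members).dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "category": cat,
                    "mark": mark,
                    "n_genes": len(vals),
                    "median_lfc": float(vals.median()),
                    "q1_lfc": float(vals.quantile(0.25)),
                    "q3_lfc": float(vals.quantile(0.75)),
                }
            )
    return pd.DataFrame(
        rows, columns=["category", "mark", "n_genes", "median_lfc", "q1_lfc", "q3_lfc"]
    )
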