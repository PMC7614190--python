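"""FACS-sorted CRISPR knockout screen analysis.

Reads are trimmed at the vector-derived constant prefix and the following
spacer window matched exactly against the guide library (multi-matching
spacers are discarded as ambiguous). Guides are scored by sorted-vs-unsorted
RPM log-ratio, genes ranked by the RSA statistic — the minimum hypergeometric
upper-tail probability over the ranks of a gene's guides among all ranked
guides — and tiered by p-value with a minimum of 4 enriched guides.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome_model import ValidationError

__all__ = [
    "Guide",
    "GuideLibrary",
    "ScreenCounts",
    "CONTROL_CLASSES",
    "TIERS",
    "read_guide_library",
    "count_guides",
    "guide_enrichment",
    "rsa_rank",
    "tier_hits",
    "intersect_screens",
]

CONTROL_CLASSES = ("non_targeting", "safe_targeting")
TIERS = ("high", "moderate", "low", "none")
_TIER_RANK = {t: i for i, t in enumerate(("none", "low", "moderate", "high"))}


@dataclass(frozen=True)
class Guide:
    guide_id: str
    spacer: str
    gene_id: str | None  # None for control-class guides
    control_class: str | None = None

    def __post_init__(self) -> None:
        if (self.gene_id is None) == (self.control_class is None):
            raise ValidationError(
                f"guide {self.guide_id!r}: exactly one of gene_id/control_class required"
            )
        if self.control_class is not None and self.control_class not in CONTROL_CLASSES:
            raise ValidationError(
                f"guide {self.guide_id!r}: unknown control class {self.control_class!r}"
            )
        if not self.spacer or set(self.spacer) - set("ACGT"):
            raise ValidationError(
                f"guide {self.guide_id!r}: spacer must be non-empty uppercase ACGT"
            )


class GuideLibrary:
    """Guide collection plus the constant read prefix preceding each spacer."""

    def __init__(self, guides: Iterable[Guide], constant_prefix: str):
        self.guides: dict[str, Guide] = {}
        for g in guides:
            if g.guide_id in self.guides:
                raise ValidationError(f"duplicate guide_id {g.guide_id!r}")
            self.guides[g.guide_id] = g
        if not self.guides:
            raise ValidationError("guide library is empty")
        self.constant_prefix = constant_prefix
        self._spacer_index: dict[str, list[str]] = {}
        for g in self.guides.values():
            self._spacer_index.setdefault(g.spacer, []).append(g.guide_id)
        for ids in self._spacer_index.values():
            ids.sort()
        self.spacer_lengths = sorted({len(g.spacer) for g in self.guides.values()})

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides.values())

    def gene_guides(self) -> dict[str, list[str]]:
        """gene_id -> sorted guide_ids, excluding control-class guides."""
        out: dict[str, list[str]] = {}
        for g in self.guides.values():
            if g.gene_id is not None:
                out.setdefault(g.gene_id, []).append(g.guide_id)
        for ids in out.values():
            ids.sort()
        return out

    def match_spacer(self, spacer: str) -> list[str]:
        return self._spacer_index.get(spacer, [])


def read_guide_library(path: str | Path, constant_prefix: str = "") -> GuideLibrary:
    """Read a TSV library: guide_id, gene_id-or-control-class, spacer."""
    guides = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["guide_id", "gene_id", "spacer"]:
            raise ValidationError(
                f"{path}: expected header guide_id/gene_id/spacer, got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            guide_id, target, spacer = line.rstrip("\n").split("\t")[:3]
            if target in CONTROL_CLASSES:
                guides.append(Guide(guide_id, spacer, None, target))
            else:
                guides.append(Guide(guide_id, spacer, target))
    return GuideLibrary(guides, constant_prefix)


def write_guide_library(library: GuideLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("guide_id\tgene_id\tspacer\n")
        for g in sorted(library, key=lambda g: g.guide_id):
            target = g.gene_id if g.gene_id is not None else g.control_class
            fh.write(f"{g.guide_id}\t{target}\t{g.spacer}\n")


class ScreenCounts:
    """Per-guide counts per sample plus assigned/ambiguous/unmatched tallies."""

    def __init__(
        self,
        counts: pd.DataFrame,
        totals: Mapping[str, Mapping[str, int]] | None = None,
    ):
        self.counts = counts  # index guide_id, columns sample labels
        if totals is None:
            totals = {
                s: {"assigned": int(counts[s].sum()), "ambiguous": 0, "unmatched": 0}
                for s in counts.columns
            }
        self.totals = {s: dict(t) for s, t in totals.items()}
        for s in counts.columns:
            t = self.totals[s]
            if int(counts[s].sum()) != t["assigned"]:
                raise ValidationError(
                    f"sample {s!r}: counts sum {int(counts[s].sum())} != assigned {t['assigned']}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def assigned(self, sample: str) -> int:
        return self.totals[sample]["assigned"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")


def _open_reads(source) -> Iterable[str]:
    """Yield read sequences from FASTQ path (plain or gzip) or string iterable."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        yield from source


def count_guides(
    reads: Mapping[str, object],
    library: GuideLibrary,
) -> ScreenCounts:
    """Count exact spacer matches per guide in each sample's reads.

    ``reads`` maps sample label -> FASTQ path or iterable of read sequences.
    Each read is cut at the first occurrence of the constant prefix; the
    window after it is compared against the library at every spacer length.
    A unique match assigns the read, multiple matches discard it as
    ambiguous, no match (or missing prefix) leaves it unmatched.
    """
    if len(library) == 0:
        raise ValidationError("guide library is empty")
    prefix = library.constant_prefix
    guide_ids = sorted(library.guides)
    cols: dict[str, pd.Series] = {}
    totals: dict[str, dict[str, int]] = {}
    for sample, source in reads.items():
        counts = dict.fromkeys(guide_ids, 0)
        assigned = ambiguous = unmatched = 0
        for seq in _open_reads(source):
            seq = seq.upper()
            pos = seq.find(prefix) if prefix else 0
            if pos < 0:
                unmatched += 1
                continue
            start = pos + len(prefix)
            hits: list[str] = []
            for length in library.spacer_lengths:
                window = seq[start : start + length]
                if len(window) == length:
                    hits.extend(library.match_spacer(window))
            if len(hits) == 1:
                counts[hits[0]] += 1
                assigned += 1
            elif len(hits) > 1:
                ambiguous += 1
            else:
                unmatched += 1
        cols[sample] = pd.Series(counts, dtype=int)
        totals[sample] = {
            "assigned": assigned,
            "ambiguous": ambiguous,
            "unmatched": unmatched,
        }
    return ScreenCounts(pd.DataFrame(cols).loc[guide_ids], totals)


def guide_enrichment(
    counts: ScreenCounts,
    pseudocount: float = 0.5,
    sorted_sample: str = "sorted",
    unsorted_sample: str = "unsorted",
) -> pd.Series:
    """Per-guide log2((RPM_sorted + pc) / (RPM_unsorted + pc))."""
    for sample in (sorted_sample, unsorted_sample):
        if sample not in counts.samples:
            raise ValidationError(f"sample {sample!r} missing from counts")
        if counts.assigned(sample) == 0:
            raise ValidationError(f"sample {sample!r} has zero assigned reads")
    rpm_s = counts.counts[sorted_sample] * 1e6 / counts.assigned(sorted_sample)
    rpm_u = counts.counts[unsorted_sample] * 1e6 / counts.assigned(unsorted_sample)
    return np.log2((rpm_s + pseudocount) / (rpm_u + pseudocount)).rename("score")


def rsa_rank(scores: pd.Series, library: GuideLibrary) -> pd.Series:
    """RSA gene ranking: minimum hypergeometric upper tail over guide ranks.

    Guides are sorted by descending score (ties broken by guide_id). For a
    gene with k guides at 1-based ranks r_1 < ... < r_k among N ranked
    guides, p_j = P[X >= j] for X ~ Hypergeom(N, k, r_j); the gene p-value is
    min_j p_j. Control-class guides occupy ranks but receive no gene p-value.
    Returns log10 p per gene.
    """
    unknown = [g for g in scores.index if g not in library.guides]
    if unknown:
        raise ValidationError(f"scored guides absent from library: {unknown[:3]}")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    rank_of = {g: i + 1 for i, g in enumerate(order)}
    n_total = len(order)
    logp: dict[str, float] = {}
    for gene, guide_ids in library.gene_guides().items():
        ranks = sorted(rank_of[g] for g in guide_ids if g in rank_of)
        if not ranks:
            continue
        k = len(ranks)
        p = min(
            hypergeom.sf(j - 1, n_total, k, r_j)
            for j, r_j in enumerate(ranks, start=1)
        )
        logp[gene] = math.log10(p) if p > 0 else -math.inf
    return pd.Series(logp, name="logp").sort_index()


def tier_hits(
    logp: pd.Series,
    scores: pd.Series,
    library: GuideLibrary,
    enriched_threshold: float = 1.0,
    min_enriched_guides: int = 4,
) -> pd.DataFrame:
    """Confidence tiers from RSA p and enriched-guide counts.

    A gene needs >= 4 guides with score >= enriched_threshold to tier at
    all; then high if p < 1e-5, moderate if 1e-5 <= p < 1e-4, low if
    1e-4 <= p < 1e-3, else none.
    """
    gene_guides = library.gene_guides()
    rows = []
    for gene in logp.index:
        guide_ids = gene_guides.get(gene, [])
        n_enriched = int(
            sum(scores.get(g, -math.inf) >= enriched_threshold for g in guide_ids)
        )
        p = 10.0 ** logp[gene]
        if n_enriched < min_enriched_guides:
            tier = "none"
        elif p < 1e-5:
            tier = "high"
        elif p < 1e-4:
            tier = "moderate"
        elif p < 1e-3:
            tier = "low"
        else:
            tier = "none"
        rows.append(
            {"gene_id": gene, "logp": float(logp[gene]), "n_enriched": n_enriched, "tier": tier}
        )
    return (
        pd.DataFrame(rows, columns=["gene_id", "logp", "n_enriched", "tier"])
        .set_index("gene_id")
        .sort_values(["logp", "gene_id"])
    )


def intersect_screens(
    a: pd.DataFrame, b: pd.DataFrame, min_tier: str = "low"
) -> pd.DataFrame:
    """Genes at or above ``min_tier`` in both screens, worst p-value first...

    Output columns: logp_a, logp_b, worst_logp; sorted by worst (largest)
    logp ascending so the most confident shared hits come first.
    """
    if min_tier not in _TIER_RANK or min_tier == "none":
        raise ValidationError(f"min_tier must be one of high/moderate/low, got {min_tier!r}")
    cutoff = _TIER_RANK[min_tier]
    shared = [
        g
        for g in a.index.intersection(b.index)
        if _TIER_RANK[a.loc[g, "tier"]] >= cutoff and _TIER_RANK[b.loc[g, "tier"]] >= cutoff
    ]
    out = pd.DataFrame(
        {
            "logp_a": a.loc[shared, "logp"],
            "logp_b": b.loc[shared, "logp"],
        }
    )
    out["worst_logp"] = out[["logp_a", "logp_b"]].max(axis=1)
    out = out.loc[sorted(out.index)]  # ties break by gene_id under stable sort
    return out.sort_values("worst_logp", kind="stable")
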