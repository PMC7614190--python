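"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates a toy genome with designed promoter classes (active / bivalent /
repressed / unmarked), negative-binomial multi-mark count data in control and
knockout conditions with a planted occupancy redistribution (factor lost from
active genes, gained at a designated subset of bivalent and repressed genes
with concomitant H3K4me3 gain and H3K27me3/SUZ12 loss), sorted-vs-unsorted
screen counts with planted repressors, and block-correlated gene-effect
matrices. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
    tss_window,
)
from .quantification import SampleCounts
from .screen_analysis import Guide, GuideLibrary, ScreenCounts

__all__ = [
    "GENE_CLASSES",
    "ASSAYS",
    "GroundTruth",
    "MarkSimConfig",
    "MarkSimulation",
    "make_genome",
    "simulate_mark_data",
    "simulate_screen",
    "emit_screen_fastq",
    "simulate_effect_matrix",
]

GENE_CLASSES = ("active", "bivalent", "repressed", "unmarked")
ASSAYS = ("H3K4me3", "H3K27me3", "SUZ12", "H2AK119Ub", "KMT2A", "Menin")
CONDITIONS = ("control", "knockout")


def _rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Independent, reproducible stream keyed by seed plus string/int tags."""
    entropy = [seed] + [
        zlib.crc32(t.encode()) if isinstance(t, str) else int(t) for t in tags
    ]
    return np.random.default_rng(entropy)


@dataclass
class GroundTruth:
    """Planted design: gene classes, redistribution sets, screen repressors."""

    gene_classes: dict[str, str]
    redistributed_gain: list[str]
    redistributed_loss: list[str]
    planted_repressors: list[str]
    params: dict

    def __post_init__(self) -> None:
        classes = self.gene_classes
        bad = {g: c for g, c in classes.items() if c not in GENE_CLASSES}
        if bad:
            raise ValidationError(f"unknown gene classes: {bad}")
        # gain genes come from the bivalent and repressed pools (so the
        # increased group can carry a designed bivalent fraction < 1);
        # loss genes are active by construction.
        for g in self.redistributed_gain:
            if classes[g] not in ("bivalent", "repressed"):
                raise ValidationError(f"gain gene {g} is {classes[g]}")
        for g in self.redistributed_loss:
            if classes[g] != "active":
                raise ValidationError(f"loss gene {g} is {classes[g]}")

    def genes_in_class(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.gene_classes.items() if c == cls)

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with Path(path).open() as fh:
            return cls(**json.load(fh))


def make_genome(
    n_genes: int,
    class_fractions: Mapping[str, float] | Sequence[float] | None = None,
    gene_length: tuple[int, int] = (2000, 8000),
    spacing: int = 20_000,
    seed: int = 0,
    tss_half_width: int = 2000,
    n_gain: int | None = None,
    gain_bivalent_fraction: float = 0.63,
    loss_fraction: float = 1.0,
    n_repressors: int = 20,
) -> tuple[list[GeneModel], GroundTruth]:
    """Lay out genes on a toy chromosome and draw the planted design.

    Genes are placed sequentially with ``spacing`` bp between bodies, which
    must be at least 2x the TSS half-width so TSS windows cannot overlap.
    Gain genes are an exact-count draw: round(gain_bivalent_fraction * n_gain)
    bivalent genes plus the remainder from the repressed class; loss genes
    are a fraction of the active class (all of it by default).
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if spacing < 2 * tss_half_width:
        raise ValidationError(
            f"spacing {spacing} < 2x tss_half_width {tss_half_width}: windows would overlap"
        )
    if class_fractions is None:
        class_fractions = {"active": 0.4, "bivalent": 0.3, "repressed": 0.2, "unmarked": 0.1}
    if not isinstance(class_fractions, Mapping):
        class_fractions = dict(zip(GENE_CLASSES, class_fractions))
    fracs = np.array([class_fractions.get(c, 0.0) for c in GENE_CLASSES], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9 or (fracs < 0).any():
        raise ValidationError(f"class fractions must be a simplex, got {fracs.tolist()}")

    rng = _rng(seed, "genome")
    classes = rng.choice(GENE_CLASSES, size=n_genes, p=fracs)
    lengths = rng.integers(gene_length[0], gene_length[1] + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)

    width = max(4, len(str(n_genes)))
    genes: list[GeneModel] = []
    cursor = spacing
    for i in range(n_genes):
        gid = f"g{i + 1:0{width}d}"
        start, end = cursor, cursor + int(lengths[i])
        genes.append(
            GeneModel(gid, gid.upper(), GenomicInterval("chrS1", start, end), strands[i])
        )
        cursor = end + spacing
    gene_classes = {g.gene_id: str(c) for g, c in zip(genes, classes)}

    bivalent = sorted(g for g, c in gene_classes.items() if c == "bivalent")
    repressed = sorted(g for g, c in gene_classes.items() if c == "repressed")
    active = sorted(g for g, c in gene_classes.items() if c == "active")

    if n_gain is None:
        n_gain = round(0.15 * n_genes)
    n_biv_gain = round(gain_bivalent_fraction * n_gain)
    n_rep_gain = n_gain - n_biv_gain
    if n_biv_gain > len(bivalent) or n_rep_gain > len(repressed):
        raise ValidationError(
            f"gain design infeasible: need {n_biv_gain} bivalent / {n_rep_gain} repressed, "
            f"have {len(bivalent)} / {len(repressed)}"
        )
    gain = sorted(rng.choice(bivalent, size=n_biv_gain, replace=False).tolist()) + sorted(
        rng.choice(repressed, size=n_rep_gain, replace=False).tolist()
    )
    n_loss = round(loss_fraction * len(active))
    loss = sorted(rng.choice(active, size=n_loss, replace=False).tolist())
    repressors = sorted(
        rng.choice(bivalent, size=min(n_repressors, len(bivalent)), replace=False).tolist()
    )

    truth = GroundTruth(
        gene_classes=gene_classes,
        redistributed_gain=gain,
        redistributed_loss=loss,
        planted_repressors=repressors,
        params={
            "seed": seed,
            "n_genes": n_genes,
            "class_fractions": {c: float(f) for c, f in zip(GENE_CLASSES, fracs)},
            "gene_length": list(gene_length),
            "spacing": spacing,
            "tss_half_width": tss_half_width,
            "n_gain": n_gain,
            "gain_bivalent_fraction": gain_bivalent_fraction,
            "loss_fraction": loss_fraction,
        },
    )
    return genes, truth


@dataclass
class MarkSimConfig:
    """Mean RPM per promoter class and the knockout fold-effects.

    The factor (KMT2A) carries a low baseline at bivalent promoters and none
    at repressed ones, except that gain-designated repressed genes get the
    same low baseline (their peak exists because of knockout signal). Gain-
    designated repressed genes also acquire de novo H3K4me3 in the knockout.
    """

    base_rpm: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "H3K4me3": {"active": 25.0, "bivalent": 15.0},
            "H3K27me3": {"bivalent": 12.0, "repressed": 18.0},
            "SUZ12": {"bivalent": 8.0},
            "H2AK119Ub": {"bivalent": 8.0, "repressed": 10.0},
            "KMT2A": {"active": 8.0, "bivalent": 1.0},
            "Menin": {"active": 15.0},
        }
    )
    factor_loss_fold: float = 0.25
    factor_gain_fold: float = 4.0
    k4_gain_fold: float = 2.0
    k27_gain_fold: float = 0.5
    suz12_gain_fold: float = 0.5
    de_novo_k4_rpm: float = 5.0
    dispersion: float = 0.05


class MarkSimulation:
    """Deterministic mean model plus NB count sampling for all mark assays."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        truth: GroundTruth,
        config: MarkSimConfig | None = None,
        tss_half_width: int = 2000,
    ):
        self.genes = list(genes)
        self.truth = truth
        self.config = config or MarkSimConfig()
        self.tss_half_width = tss_half_width
        self.windows: dict[str, GenomicInterval] = {
            g.gene_id: tss_window(g, tss_half_width) for g in self.genes
        }
        self.site_gene: dict[str, str] = {
            str(iv): gid for gid, iv in self.windows.items()
        }
        self.means = {c: self._mean_table(c) for c in CONDITIONS}

    def _mean_table(self, condition: str) -> pd.DataFrame:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        cfg = self.config
        gain = set(self.truth.redistributed_gain)
        loss = set(self.truth.redistributed_loss)
        rows = {}
        for g in self.genes:
            cls = self.truth.gene_classes[g.gene_id]
            mean = {a: cfg.base_rpm.get(a, {}).get(cls, 0.0) for a in ASSAYS}
            if g.gene_id in gain:
                mean["KMT2A"] = cfg.base_rpm["KMT2A"].get(cls, 0.0) or cfg.base_rpm[
                    "KMT2A"
                ].get("bivalent", 1.0)
            if condition == "knockout":
                if g.gene_id in loss:
                    mean["KMT2A"] *= cfg.factor_loss_fold
                if g.gene_id in gain:
                    mean["KMT2A"] *= cfg.factor_gain_fold
                    mean["H3K27me3"] *= cfg.k27_gain_fold
                    mean["SUZ12"] *= cfg.suz12_gain_fold
                    if mean["H3K4me3"] > 0:
                        mean["H3K4me3"] *= cfg.k4_gain_fold
                    else:
                        mean["H3K4me3"] = cfg.de_novo_k4_rpm
            rows[g.gene_id] = mean
        return pd.DataFrame.from_dict(rows, orient="index").loc[
            [g.gene_id for g in self.genes], list(ASSAYS)
        ]

    def peak_set(self, assay: str, condition: str = "control") -> PeakSet:
        """Peaks at TSS windows where the assay has signal in the condition.

        ``condition`` may be 'control', 'knockout', or 'union' (signal in
        either — the merged peak list a caller would produce from both).
        Peak ids are positional (chrom:start-end), shared across assays.
        """
        if condition == "union":
            mean = self.means["control"][assay].combine(
                self.means["knockout"][assay], max
            )
        elif condition in CONDITIONS:
            mean = self.means[condition][assay]
        else:
            raise ValidationError(f"unknown condition {condition!r}")
        peaks = [
            Peak(str(self.windows[gid]), self.windows[gid], assay)
            for gid in mean.index
            if mean[gid] > 0
        ]
        return PeakSet(peaks, assay=assay, merge=False)

    def sample_counts(
        self,
        assay: str,
        condition: str,
        n_replicates: int,
        depth: int,
        seed: int,
        sites: PeakSet | None = None,
    ) -> list[SampleCounts]:
        """NB-distributed per-peak counts for replicate samples.

        ``sites`` defaults to the assay's own peaks in the condition; pass a
        different PeakSet (e.g. the factor's union peaks) to tabulate this
        assay's signal over those regions instead.
        """
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        if sites is None:
            sites = self.peak_set(assay, condition)
        mean = self.means[condition][assay]
        mus = np.array(
            [
                mean[self.site_gene[p.peak_id]] * depth / 1e6
                for p in sites
            ]
        )
        out = []
        for rep in range(1, n_replicates + 1):
            rng = _rng(seed, "marks", assay, condition, rep)
            counts = _nb_draw(rng, mus, self.config.dispersion)
            out.append(
                SampleCounts(
                    sample_id=f"{assay}_{condition}_rep{rep}",
                    assay=assay,
                    condition=condition,
                    library_size=depth,
                    counts={p.peak_id: int(c) for p, c in zip(sites, counts)},
                )
            )
        return out

    def fragments(
        self,
        assay: str,
        condition: str,
        replicate: int,
        depth: int,
        seed: int,
        fragment_length: int = 200,
    ) -> list[GenomicInterval]:
        """Exactly ``depth`` fragments: NB in-peak counts placed uniformly
        inside each peak, the remainder scattered outside all peaks."""
        sites = self.peak_set(assay, condition)
        mean = self.means[condition][assay]
        rng = _rng(seed, "marks", assay, condition, replicate)
        mus = np.array([mean[self.site_gene[p.peak_id]] * depth / 1e6 for p in sites])
        counts = _nb_draw(rng, mus, self.config.dispersion)
        total_in_peaks = int(counts.sum())
        if total_in_peaks > depth:
            raise ValidationError("peak signal exceeds requested depth")
        frags: list[GenomicInterval] = []
        for p, c in zip(sites, counts):
            hi = max(p.interval.start + 1, p.interval.end - fragment_length)
            starts = rng.integers(p.interval.start, hi, size=int(c))
            frags.extend(
                GenomicInterval(p.interval.chrom, int(s), int(s) + fragment_length)
                for s in starts
            )
        # background outside every peak, rejection-sampled
        chrom_end = max(g.interval.end for g in self.genes) + 10_000
        peak_bounds = [(p.interval.start, p.interval.end) for p in sites]
        starts_arr = np.array([b[0] for b in peak_bounds])
        ends_arr = np.array([b[1] for b in peak_bounds])
        need = depth - total_in_peaks
        while need > 0:
            cand = rng.integers(0, chrom_end - fragment_length, size=int(need * 1.5) + 8)
            cend = cand + fragment_length
            if len(starts_arr):
                idx = np.searchsorted(starts_arr, cend, side="left")
                overlaps = (idx > 0) & (ends_arr[np.maximum(idx - 1, 0)] > cand)
                cand = cand[~overlaps]
            take = cand[:need]
            frags.extend(
                GenomicInterval("chrS1", int(s), int(s) + fragment_length) for s in take
            )
            need -= len(take)
        return frags


def _nb_draw(rng: np.random.Generator, mus: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mus = np.asarray(mus, dtype=float)
    out = np.zeros(mus.shape, dtype=np.int64)
    pos = mus > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mus[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mus[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_mark_data(
    truth: GroundTruth,
    genes: Sequence[GeneModel],
    condition: str,
    depth: int = 1_000_000,
    n_replicates: int = 3,
    seed: int = 0,
    config: MarkSimConfig | None = None,
    tss_half_width: int = 2000,
) -> tuple[dict[str, PeakSet], dict[str, list[SampleCounts]]]:
    """One condition's peak sets and replicate counts for every assay."""
    if depth < 10_000:
        raise ValidationError("depth must be >= 1e4 fragments per sample")
    sim = MarkSimulation(genes, truth, config, tss_half_width)
    peak_sets = {a: sim.peak_set(a, condition) for a in ASSAYS}
    counts = {
        a: sim.sample_counts(a, condition, n_replicates, depth, seed) for a in ASSAYS
    }
    return peak_sets, counts


# ---------------------------------------------------------------------------
# Screen simulation


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.array(list("ACGT"))
    spacers: set[str] = set()
    while len(spacers) < n:
        draw = rng.integers(0, 4, size=(n - len(spacers), length))
        for row in draw:
            spacers.add("".join(bases[row]))
    return sorted(spacers)[:n]


def simulate_screen(
    truth: GroundTruth,
    guides_per_gene: int = 10,
    active_guide_fraction: float = 0.7,
    enrichment_fold: float = 8.0,
    depth: int = 5_000_000,
    n_control_guides: int = 100,
    seed: int = 0,
    dispersion: float = 0.05,
    spacer_length: int = 20,
    constant_prefix: str = "ACCG",
    guide_activity: str = "bernoulli",
) -> tuple[GuideLibrary, ScreenCounts]:
    """Sorted/unsorted guide counts with planted repressor enrichment.

    Per-guide latent abundances are Gamma-distributed (shared between
    samples, giving NB marginals); the sorted sample multiplies the weights
    of each planted repressor's active guides by ``enrichment_fold``. Guide
    efficiency is Bernoulli(active_guide_fraction) per guide by default;
    ``guide_activity='exact'`` instead activates a random subset of exactly
    round(active_guide_fraction * guides_per_gene) guides per planted gene.
    With enrichment_fold = 1 the two samples are exchangeable.
    """
    if enrichment_fold < 1:
        raise ValidationError("enrichment_fold must be >= 1")
    if guide_activity not in ("bernoulli", "exact"):
        raise ValidationError(f"unknown guide_activity {guide_activity!r}")
    rng = _rng(seed, "screen")
    gene_ids = sorted(truth.gene_classes)
    planted = set(truth.planted_repressors)

    guide_rows: list[tuple[str, str | None, str | None]] = []
    for gid in gene_ids:
        for j in range(1, guides_per_gene + 1):
            guide_rows.append((f"{gid}_sg{j:02d}", gid, None))
    for j in range(1, n_control_guides // 2 + 1):
        guide_rows.append((f"ntc_sg{j:03d}", None, "non_targeting"))
    for j in range(1, n_control_guides - n_control_guides // 2 + 1):
        guide_rows.append((f"safe_sg{j:03d}", None, "safe_targeting"))

    spacers = _random_spacers(rng, len(guide_rows), spacer_length)
    perm = rng.permutation(len(guide_rows))
    guides = [
        Guide(guide_id, spacers[perm[i]], gene, control_class)
        for i, (guide_id, gene, control_class) in enumerate(guide_rows)
    ]
    library = GuideLibrary(guides, constant_prefix)

    guide_ids = [g[0] for g in guide_rows]
    n = len(guide_ids)
    if depth < 10 * n:
        import warnings

        warnings.warn(f"depth {depth} < 10x library size {n}: screen is underpowered")
    # latent abundance, shared between samples
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=n)
    else:
        lam = np.ones(n)
    fold = np.ones(n)
    if guide_activity == "bernoulli":
        for i, (guide_id, gene, _) in enumerate(guide_rows):
            if gene in planted and rng.random() < active_guide_fraction:
                fold[i] = enrichment_fold
    else:
        n_active = round(active_guide_fraction * guides_per_gene)
        by_gene: dict[str, list[int]] = {}
        for i, (_, gene, _) in enumerate(guide_rows):
            if gene in planted:
                by_gene.setdefault(gene, []).append(i)
        for gene in sorted(by_gene):
            chosen = rng.choice(by_gene[gene], size=n_active, replace=False)
            fold[chosen] = enrichment_fold
    unsorted = rng.multinomial(depth, lam / lam.sum())
    w = lam * fold
    sorted_counts = rng.multinomial(depth, w / w.sum())
    counts = pd.DataFrame(
        {"sorted": sorted_counts, "unsorted": unsorted}, index=guide_ids
    ).sort_index()
    return library, ScreenCounts(counts)


def emit_screen_fastq(
    library: GuideLibrary,
    counts: ScreenCounts,
    sample: str,
    path: str | Path,
) -> None:
    """Write each guide's reads as constant_prefix + spacer FASTQ records."""
    prefix = library.constant_prefix
    with Path(path).open("w") as fh:
        read_no = 0
        for guide_id in counts.counts.index:
            spacer = library.guides[guide_id].spacer
            seq = prefix + spacer
            qual = "I" * len(seq)
            for _ in range(int(counts.counts.loc[guide_id, sample])):
                read_no += 1
                fh.write(f"@{sample}_read{read_no}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Gene-effect matrix


def simulate_effect_matrix(
    n_genes: int,
    n_lines: int,
    block_spec: Sequence[tuple[int, float]] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x cell-lines effect matrix with block-correlated groups.

    Each block of size s with target correlation r draws its genes as
    sqrt(r) * shared_factor + sqrt(1 - r) * noise (unit variance), so
    within-block pairwise Pearson r converges to the target; ``noise_sd``
    adds independent noise on top, attenuating r toward 0. Remaining genes
    are independent standard normals.
    """
    for _, r in block_spec:
        if not 0 <= r < 1:
            raise ValidationError(f"target correlation must be in [0, 1), got {r}")
    rng = _rng(seed, "effects")
    total_block = sum(s for s, _ in block_spec)
    if total_block > n_genes:
        raise ValidationError("block sizes exceed n_genes")
    rows = []
    names = []
    for b, (size, r) in enumerate(block_spec):
        factor = rng.standard_normal(n_lines)
        for j in range(size):
            eps = rng.standard_normal(n_lines)
            rows.append(np.sqrt(r) * factor + np.sqrt(1 - r) * eps)
            names.append(f"blk{b + 1}_g{j + 1:03d}")
    for j in range(n_genes - total_block):
        rows.append(rng.standard_normal(n_lines))
        names.append(f"bg_g{j + 1:04d}")
    mat = np.vstack(rows) if rows else np.empty((0, n_lines))
    if noise_sd > 0:
        mat = mat + noise_sd * rng.standard_normal(mat.shape)
    return pd.DataFrame(
        mat, index=names, columns=[f"line{i + 1:04d}" for i in range(n_lines)]
    )
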