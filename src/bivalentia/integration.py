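"""Set-level downstream statistics.

Benjamini-Hochberg adjustment, differential-expression thresholding
(q < 0.05, |log2FC| > 1, strict), exclusive-region overlap summaries,
bivalent-fraction of gene sets, and gene-effect co-dependency correlation.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bivalency import BivalencyCall
from .genome_model import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "read_de_table",
    "de_gene_sets",
    "overlap_summary",
    "bivalent_fraction",
    "codependency",
]


def bh_adjust(pvalues: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving.

    q_i = min over j with p_j >= p_i of p_j * m / rank_j, clipped at 1.
    """
    index = pvalues.index if isinstance(pvalues, pd.Series) else None
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.Series(dtype=float) if index is not None else p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if index is not None:
        return pd.Series(q, index=index)
    return q


def read_de_table(path: str | Path, adjust: bool = True) -> pd.DataFrame:
    """Read a TSV of gene_id, log2fc, pvalue; BH-adjust unless a qvalue column exists."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id rows")
    df = df.set_index("gene_id")
    if "qvalue" not in df.columns and adjust:
        df["qvalue"] = bh_adjust(df["pvalue"])
    return df


def de_gene_sets(
    table: pd.DataFrame, lfc_min: float = 1.0, q_max: float = 0.05
) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at q < q_max and |log2fc| > lfc_min — strict inequalities."""
    if "qvalue" not in table.columns:
        raise ValidationError("DE table lacks a qvalue column; run bh_adjust first")
    sig = table["qvalue"] < q_max
    up = set(table.index[sig & (table["log2fc"] > lfc_min)])
    down = set(table.index[sig & (table["log2fc"] < -lfc_min)])
    return up, down


def overlap_summary(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive-region counts for 2 or 3 named sets (a venn decomposition).

    Keys are sorted tuples of the set names whose exclusive region the count
    describes; counts over all regions sum to the union size.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 3:
        raise ValidationError(f"expected 2 or 3 sets, got {len(names)}")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in members))
            outside = set.union(set(), *(sets[n] for n in names if n not in members))
            out[members] = len(inside - outside)
    return out


def bivalent_fraction(
    gene_set: set[str], bivalency: Sequence[BivalencyCall]
) -> tuple[float, int, int] | None:
    """(fraction, n_bivalent, n_total) of the set; None for an empty set.

    Genes outside the bivalency universe are dropped with a log message.
    """
    universe = {c.gene_id for c in bivalency}
    known = gene_set & universe
    dropped = gene_set - universe
    if dropped:
        logger.warning("dropping %d genes outside the bivalency universe", len(dropped))
    if not known:
        return None
    bivalent = {c.gene_id for c in bivalency if c.state == "bivalent"}
    n_biv = len(known & bivalent)
    return n_biv / len(known), n_biv, len(known)


def codependency(
    matrix: pd.DataFrame,
    query: str,
    k: int = 20,
    min_shared: int = 10,
) -> list[tuple[str, float]]:
    """Top-k genes by Pearson correlation of effect profiles with ``query``.

    ``matrix`` is genes x cell lines; missing values are excluded pairwise
    with at least ``min_shared`` shared lines (else the pair is skipped).
    Ties in r break by gene_id; the query is excluded from its own list.
    """
    if query not in matrix.index:
        raise ValidationError(f"query gene {query!r} not in matrix")
    if k < 1:
        raise ValidationError("k must be >= 1")
    qvec = matrix.loc[query]
    results: list[tuple[str, float]] = []
    for gene in matrix.index:
        if gene == query:
            continue
        other = matrix.loc[gene]
        mask = qvec.notna() & other.notna()
        if int(mask.sum()) < min_shared:
            logger.warning("skipping %s: only %d shared lines", gene, int(mask.sum()))
            continue
        x = qvec[mask].to_numpy(dtype=float)
        y = other[mask].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("skipping %s: zero-variance vector", gene)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        results.append((gene, r))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results[:k]
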