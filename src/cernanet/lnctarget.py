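"""lncRNA target-gene inference.

cis: genes whose genomic span lies within +/-100 kb of the lncRNA span
(strand ignored, distance between nearest span ends, overlap => 0).

trans: gene expression whose Spearman correlation with the lncRNA across
all samples satisfies |rho| > 0.8 (strict) and p < 0.05, with the p-value
from the Student-t approximation on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import sqrt
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .formats_io import ExpressionMatrix, TranscriptModel

__all__ = [
    "CisPair",
    "TransPair",
    "cis_targets",
    "spearman_rho",
    "spearman_pvalue",
    "spearman_pvalue_exact",
    "trans_targets",
    "merge_lnc_targets",
]


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    distance_bp: int
    coincide: bool

    def __post_init__(self) -> None:
        if self.coincide and self.distance_bp != 0:
            raise ValueError("coinciding spans must have distance 0")
        if self.distance_bp < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class TransPair:
    lncrna_id: str
    gene_id: str
    rho: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# cis
# ---------------------------------------------------------------------------

def span_distance(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Gap between two 1-based inclusive spans; 0 when they overlap."""
    return max(0, b[0] - a[1], a[0] - b[1])


def cis_targets(
    lnc_models: Sequence[TranscriptModel],
    gene_models: Sequence[TranscriptModel],
    config: PipelineConfig,
) -> List[CisPair]:
    """All (lncRNA, gene) pairs on a shared chromosome whose genomic spans
    are within the cis window (inclusive). Strand is ignored."""
    genes_by_chrom: Dict[str, List[TranscriptModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    pairs: List[CisPair] = []
    for lnc in lnc_models:
        lspan = lnc.span
        for g in genes_by_chrom.get(lnc.chrom, ()):
            d = span_distance(lspan, g.span)
            if d <= config.cis_window_bp:
                pairs.append(CisPair(lnc.transcript_id, g.gene_id, d, coincide=(d == 0)))
    return pairs


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of mid-ranks (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant vector has undefined rank correlation")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via t = rho*sqrt((n-2)/(1-rho^2))
    against Student-t with n-2 df. |rho| = 1 returns exactly 0."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho out of range: {rho}")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_pvalue_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact permutation p-value (all n! permutations); only for n <= 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation only supported for n <= 10")
    observed = abs(spearman_rho(x, y))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(spearman_rho(x, y[list(perm)]))
        if r >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------

def trans_targets(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    config: PipelineConfig,
    keep_all: bool = False,
) -> List[TransPair]:
    """Score every lncRNA x gene pair across the shared samples; retain
    pairs with |rho| > threshold (strict) and p < threshold."""
    if lnc_expr.sample_ids != gene_expr.sample_ids:
        raise ValueError("lncRNA and gene matrices must share sample order")
    n = len(lnc_expr.sample_ids)
    out: List[TransPair] = []
    for lnc in lnc_expr.feature_ids:
        x = lnc_expr.row(lnc)
        if np.all(x == x[0]):
            continue
        for gene in gene_expr.feature_ids:
            y = gene_expr.row(gene)
            if np.all(y == y[0]):
                continue
            rho = spearman_rho(x, y)
            p = spearman_pvalue(rho, n)
            pair = TransPair(lnc, gene, rho, p, n)
            if keep_all or (abs(rho) > config.trans_abs_rho_min and p < config.trans_p_max):
                out.append(pair)
    return out


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge_lnc_targets(
    cis_pairs: Iterable[CisPair],
    trans_pairs: Iterable[TransPair],
    degs: Set[str],
) -> Dict[str, Dict[str, str]]:
    """Union of cis and trans targets per lncRNA, restricted to DEGs.

    Returns lncRNA -> {gene -> "cis" | "trans" | "both"}.
    """
    out: Dict[str, Dict[str, str]] = {}
    for p in cis_pairs:
        if p.gene_id in degs:
            out.setdefault(p.lncrna_id, {})[p.gene_id] = "cis"
    for p in trans_pairs:
        if p.gene_id in degs:
            genes = out.setdefault(p.lncrna_id, {})
            genes[p.gene_id] = "both" if genes.get(p.gene_id) == "cis" else "trans"
    return out
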