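"""Gene-set over-representation by the upper-tail hypergeometric test.

Significance is raw p < 0.05 (no multiple-testing correction) to match the
screening criterion this pipeline implements; a BH option is provided for
users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .formats_io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_enrich", "format_enrichment"]


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    k: int  # hits in query
    K: int  # set size within background
    n: int  # query size
    N: int  # background size
    p_value: float
    member_hits: List[str]


def hypergeom_enrich(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    background: Iterable[str],
    apply_bh: bool = False,
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of the query in each
    gene set, both intersected with the background universe.

    p = P(X >= k) for X ~ Hypergeom(N, K, n). Results sorted by (p, set_id).
    With ``apply_bh`` the p_value field is left raw and a ``fdr`` attribute
    is attached to each result.
    """
    query = set(query_genes)
    bg = set(background)
    if not query or not bg:
        raise ValueError("query and background must be non-empty")
    if not query <= bg:
        extra = sorted(query - bg)
        raise ValueError(f"query genes not in background: {extra[:5]}")
    N = len(bg)
    n = len(query)
    results: List[EnrichmentResult] = []
    for set_id, (name, members) in gene_sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        if K == 0:
            continue
        hits = sorted(query & in_bg)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(p, 0.0))
        results.append(EnrichmentResult(set_id, name, k, K, n, N, p, hits))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    if apply_bh:
        from .de import bh_fdr

        fdrs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, fdrs):
            r.fdr = float(q)  # type: ignore[attr-defined]
    return results


def format_enrichment(
    results: Sequence[EnrichmentResult],
    config: Optional[PipelineConfig] = None,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Tabulate results as term / id / p / comma-joined hit genes, stable
    sorted by (p, set_id); optionally keep only significant sets."""
    p_max = config.enrich_p_max if config is not None else 0.05
    rows = []
    for r in sorted(results, key=lambda r: (r.p_value, r.set_id)):
        if significant_only and not r.p_value < p_max:
            continue
        rows.append(
            {
                "term": r.name,
                "id": r.set_id,
                "p_value": r.p_value,
                "genes": ",".join(r.member_hits),
            }
        )
    return pd.DataFrame(rows, columns=["term", "id", "p_value", "genes"])
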