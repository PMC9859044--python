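"""miRNA target prediction by canonical seed matching, plus multi-source
intersection with differentially expressed genes.

The scanner reports every occurrence of the reverse complement of miRNA
positions 2-7 on the target (DNA sense strand), classified at its maximal
canonical type:

========  =============================================================
8mer      seed match + position-8 pair + 'A' opposite miRNA position 1
7mer-m8   seed match + position-8 pair
7mer-A1   seed match + 'A' opposite position 1
6mer      seed match only
========  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .formats_io import SequenceRecord

__all__ = [
    "SeedSite",
    "TargetPair",
    "revcomp",
    "site_string",
    "seed_sites",
    "intersect_sources",
    "lnc_mirna_targets",
    "SITE_TYPE_ORDER",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
SITE_TYPE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # strongest first


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    target_kind: str  # "utr3" | "lncrna"
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1" | "6mer"
    position: int  # 1-based start of the full matched site string

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPE_ORDER:
            raise ValueError(f"bad site_type {self.site_type!r}")


@dataclass
class TargetPair:
    mirna_id: str
    target_id: str
    evidence: Set[str]
    best_site: Optional[SeedSite] = None

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("TargetPair evidence must be non-empty")


def site_string(mirna_seq: str, site_type: str) -> str:
    """The exact target-strand (5'->3' DNA) string a site of the given type
    must contain: the seed core (revcomp of miRNA 2-7) with the m8 pair
    and/or the A1 adenine appended on the proper sides."""
    m = mirna_seq.upper().replace("U", "T")
    if len(m) < 8:
        raise ValueError("mature miRNA must be >= 8 nt")
    core = revcomp(m[1:7])
    m8 = m[7].translate(_COMPLEMENT)
    if site_type == "8mer":
        return m8 + core + "A"
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "6mer":
        return core
    raise ValueError(f"bad site_type {site_type!r}")


def seed_sites(
    mirna: SequenceRecord, target: SequenceRecord, target_kind: Optional[str] = None
) -> List[SeedSite]:
    """Scan one target for canonical seed sites of one miRNA.

    All (possibly overlapping) core occurrences are reported, each at its
    maximal type. Sites whose flanking window contains an ambiguous N are
    skipped.
    """
    m = mirna.seq
    if len(m) < 8:
        raise ValueError(f"{mirna.id}: mature miRNA must be >= 8 nt")
    if target_kind is None:
        target_kind = "lncrna" if target.moltype == "transcript" else "utr3"
    t = target.seq
    core = revcomp(m[1:7])
    m8_pair = m[7].translate(_COMPLEMENT)
    sites: List[SeedSite] = []
    start = t.find(core)
    while start != -1:
        five = t[start - 1] if start >= 1 else None
        three = t[start + 6] if start + 6 < len(t) else None
        if five == "N" or three == "N":
            start = t.find(core, start + 1)
            continue
        has_m8 = five == m8_pair
        has_a1 = three == "A"
        if has_m8 and has_a1:
            stype, pos0 = "8mer", start - 1
        elif has_m8:
            stype, pos0 = "7mer-m8", start - 1
        elif has_a1:
            stype, pos0 = "7mer-A1", start
        else:
            stype, pos0 = "6mer", start
        sites.append(SeedSite(mirna.id, target.id, target_kind, stype, pos0 + 1))
        start = t.find(core, start + 1)
    return sites


def _best_site(sites: Sequence[SeedSite]) -> SeedSite:
    rank = {t: i for i, t in enumerate(SITE_TYPE_ORDER)}
    return min(sites, key=lambda s: (rank[s.site_type], s.position))


def scan_all(
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    target_kind: Optional[str] = None,
) -> Dict[Tuple[str, str], List[SeedSite]]:
    """All seed sites for every (miRNA, target) combination with >=1 site."""
    out: Dict[Tuple[str, str], List[SeedSite]] = {}
    for m in mirnas:
        for t in targets:
            sites = seed_sites(m, t, target_kind=target_kind)
            if sites:
                out[(m.id, t.id)] = sites
    return out


def intersect_sources(
    source_lists: Mapping[str, Iterable[Tuple[str, str]]],
    degs: Set[str],
    sites_by_pair: Optional[Mapping[Tuple[str, str], Sequence[SeedSite]]] = None,
) -> List[TargetPair]:
    """Pairs present in ALL sources, restricted to targets that are DEGs.

    ``source_lists`` maps source name -> iterable of (mirna_id, target_id).
    ``sites_by_pair`` optionally attaches the best in-repo seed site.
    """
    if not source_lists:
        raise ValueError("need at least one target-prediction source")
    sets = {name: set(pairs) for name, pairs in source_lists.items()}
    common = set.intersection(*sets.values())
    out = []
    for mirna_id, target_id in sorted(common):
        if target_id not in degs:
            continue
        best = None
        if sites_by_pair and (mirna_id, target_id) in sites_by_pair:
            best = _best_site(sites_by_pair[(mirna_id, target_id)])
        out.append(TargetPair(mirna_id, target_id, set(sets), best_site=best))
    return out


def lnc_mirna_targets(
    del_seqs: Sequence[SequenceRecord],
    mirnas: Sequence[SequenceRecord],
    dems: Set[str],
) -> List[TargetPair]:
    """Seed-scan DE lncRNA sequences as targets; keep pairs whose miRNA is
    itself differentially expressed."""
    out = []
    for m in mirnas:
        if m.id not in dems:
            continue
        for lnc in del_seqs:
            sites = seed_sites(m, lnc, target_kind="lncrna")
            if sites:
                out.append(
                    TargetPair(m.id, lnc.id, {"seed_scan"}, best_site=_best_site(sites))
                )
    return out
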