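"""ceRNA network assembly.

A ceRNA unit is a triangle (lncRNA, miRNA, mRNA) in which the lncRNA and
miRNA are paired, and the mRNA is a target of both; mRNAs targeted by only
one of the two are dropped from that pair's context. The tripartite
network carries DE directions on nodes and merged evidence on edges, and
a PPI edge list yields a degree-based hub ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .config import PipelineConfig

__all__ = [
    "CeRNANetwork",
    "HubRanking",
    "extract_triangles",
    "assemble_network",
    "ppi_hubs",
    "direction_consistency",
]

EDGE_RELATIONS = ("lnc-mir", "mir-mrna", "lnc-mrna")
_RELATION_KINDS = {
    "lnc-mir": ("lncrna", "mirna"),
    "mir-mrna": ("mirna", "mrna"),
    "lnc-mrna": ("lncrna", "mrna"),
}


@dataclass
class CeRNANetwork:
    # node id -> (kind, de_direction)
    nodes: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    # (a, b, relation) -> evidence set
    edges: Dict[Tuple[str, str, str], Set[str]] = field(default_factory=dict)
    triangles: List[Tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        for (a, b, rel), evidence in self.edges.items():
            if rel not in EDGE_RELATIONS:
                raise ValueError(f"bad relation {rel!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            kinds = (self.nodes[a][0], self.nodes[b][0])
            if kinds != _RELATION_KINDS[rel]:
                raise ValueError(f"edge ({a}, {b}) kinds {kinds} do not match relation {rel}")
            if not evidence:
                raise ValueError(f"edge ({a}, {b}) has empty evidence")
        for lnc, mir, mrna in self.triangles:
            for key in ((lnc, mir, "lnc-mir"), (mir, mrna, "mir-mrna"), (lnc, mrna, "lnc-mrna")):
                if key not in self.edges:
                    raise ValueError(f"triangle ({lnc}, {mir}, {mrna}) missing edge {key}")

    # -- serialization (plain TSV, round-trips exactly) --------------------
    def write(self, out_dir: str | Path, prefix: str = "network") -> Dict[str, Path]:
        out_dir = Path(out_dir)
        paths = {
            "nodes": out_dir / f"{prefix}_nodes.tsv",
            "edges": out_dir / f"{prefix}_edges.tsv",
            "triangles": out_dir / f"{prefix}_triangles.tsv",
        }
        with open(paths["nodes"], "w") as fh:
            fh.write("id\tkind\tde_direction\n")
            for nid in sorted(self.nodes):
                kind, direction = self.nodes[nid]
                fh.write(f"{nid}\t{kind}\t{direction}\n")
        with open(paths["edges"], "w") as fh:  # SIF-compatible column order
            fh.write("source\trelation\ttarget\tevidence\n")
            for a, b, rel in sorted(self.edges):
                fh.write(f"{a}\t{rel}\t{b}\t{','.join(sorted(self.edges[(a, b, rel)]))}\n")
        with open(paths["triangles"], "w") as fh:
            fh.write("lncrna\tmirna\tmrna\n")
            for lnc, mir, mrna in sorted(self.triangles):
                fh.write(f"{lnc}\t{mir}\t{mrna}\n")
        return paths

    @classmethod
    def read(cls, out_dir: str | Path, prefix: str = "network") -> "CeRNANetwork":
        out_dir = Path(out_dir)
        net = cls()
        with open(out_dir / f"{prefix}_nodes.tsv") as fh:
            next(fh)
            for line in fh:
                nid, kind, direction = line.rstrip("\n").split("\t")
                net.nodes[nid] = (kind, direction)
        with open(out_dir / f"{prefix}_edges.tsv") as fh:
            next(fh)
            for line in fh:
                a, rel, b, evidence = line.rstrip("\n").split("\t")
                net.edges[(a, b, rel)] = set(evidence.split(","))
        with open(out_dir / f"{prefix}_triangles.tsv") as fh:
            next(fh)
            for line in fh:
                lnc, mir, mrna = line.rstrip("\n").split("\t")
                net.triangles.append((lnc, mir, mrna))
        net.triangles.sort()
        return net


@dataclass
class HubRanking:
    """(gene, degree) ordered by non-increasing degree; ties at the cut are
    all reported and flagged."""

    entries: List[Tuple[str, int]]
    tie_at_cut: bool = False


# ---------------------------------------------------------------------------
# triangles
# ---------------------------------------------------------------------------

def extract_triangles(
    lnc_mir_pairs: Iterable[Tuple[str, str]],
    mir_targets: Mapping[str, Set[str]],
    lnc_targets: Mapping[str, Set[str]],
) -> List[Tuple[str, str, str]]:
    """For every paired (lncRNA, miRNA), emit one triangle per mRNA in the
    intersection of their target sets; mRNAs targeted by only one of the
    two are removed from that pair's context."""
    triangles = set()
    for lnc, mir in lnc_mir_pairs:
        shared = lnc_targets.get(lnc, set()) & mir_targets.get(mir, set())
        for gene in shared:
            triangles.add((lnc, mir, gene))
    return sorted(triangles)


def assemble_network(
    triangles: Sequence[Tuple[str, str, str]],
    lnc_mir_pairs: Iterable[Tuple[str, str]],
    mir_target_evidence: Mapping[Tuple[str, str], Set[str]],
    lnc_target_evidence: Mapping[Tuple[str, str], Set[str]],
    de_directions: Mapping[str, str],
    pairs_only: bool = False,
) -> CeRNANetwork:
    """Build the tripartite network from retained triangles.

    Nodes are every feature appearing in a retained relationship, annotated
    with its DE direction; duplicate edges merge their evidence. With
    ``pairs_only`` and no triangles, the lnc-mir pairs alone are emitted.
    """
    net = CeRNANetwork()

    def add_node(nid: str, kind: str) -> None:
        direction = de_directions.get(nid, "ns")
        net.nodes.setdefault(nid, (kind, direction))

    def add_edge(a: str, b: str, rel: str, evidence: Set[str]) -> None:
        net.edges.setdefault((a, b, rel), set()).update(evidence or {"inferred"})

    if triangles:
        pair_set = set(lnc_mir_pairs)
        for lnc, mir, mrna in triangles:
            add_node(lnc, "lncrna")
            add_node(mir, "mirna")
            add_node(mrna, "mrna")
            add_edge(lnc, mir, "lnc-mir",
                     {"seed_scan"} if (lnc, mir) in pair_set else {"paired"})
            add_edge(mir, mrna, "mir-mrna", set(mir_target_evidence.get((mir, mrna), set())))
            add_edge(lnc, mrna, "lnc-mrna", set(lnc_target_evidence.get((lnc, mrna), set())))
        net.triangles = sorted(set(triangles))
    elif pairs_only:
        for lnc, mir in lnc_mir_pairs:
            add_node(lnc, "lncrna")
            add_node(mir, "mirna")
            add_edge(lnc, mir, "lnc-mir", {"seed_scan"})
    net.validate()
    return net


# ---------------------------------------------------------------------------
# PPI hubs
# ---------------------------------------------------------------------------

def ppi_hubs(
    edge_list: Iterable[Tuple[str, str]],
    gene_universe: Set[str],
    config: PipelineConfig,
) -> HubRanking:
    """Degree ranking of an undirected PPI edge list restricted to the gene
    universe, after dropping self-loops and duplicate edges. Truncated at
    ``hub_top_n`` with ties at the cut all included."""
    unique_edges = set()
    for a, b in edge_list:
        if a == b or a not in gene_universe or b not in gene_universe:
            continue
        unique_edges.add(frozenset((a, b)))
    degree: Dict[str, int] = {}
    for edge in unique_edges:
        for node in edge:
            degree[node] = degree.get(node, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    top_n = config.hub_top_n
    if len(ranked) <= top_n:
        return HubRanking(ranked, tie_at_cut=False)
    cut_degree = ranked[top_n - 1][1]
    kept = [(g, d) for g, d in ranked if d >= cut_degree]
    return HubRanking(kept, tie_at_cut=len(kept) > top_n)


# ---------------------------------------------------------------------------
# direction diagnostic
# ---------------------------------------------------------------------------

def direction_consistency(network: CeRNANetwork) -> Dict[str, object]:
    """Per-triangle flag of the canonical ceRNA expectation: lncRNA and
    mRNA share DE direction while the miRNA is opposite. Diagnostic only;
    nothing is filtered."""
    flags: Dict[Tuple[str, str, str], bool] = {}
    for lnc, mir, mrna in network.triangles:
        d_lnc = network.nodes[lnc][1]
        d_mir = network.nodes[mir][1]
        d_mrna = network.nodes[mrna][1]
        consistent = (
            d_lnc in ("up", "down")
            and d_lnc == d_mrna
            and d_mir in ("up", "down")
            and d_mir != d_lnc
        )
        flags[(lnc, mir, mrna)] = consistent
    n_consistent = sum(flags.values())
    return {
        "per_triangle": flags,
        "n_consistent": n_consistent,
        "n_inconsistent": len(flags) - n_consistent,
    }
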