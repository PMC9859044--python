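"""End-to-end orchestration: identification -> DE (x3) -> targets ->
network -> enrichment, with a manifest recording config, input hashes and
per-stage counts. A single flag swaps real inputs for the simulator."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from . import cenet, de, enrich, lncfilter, lnctarget, mirtarget
from . import formats_io as fio
from .config import PipelineConfig
from .simulate import SimulationParams, simulate_dataset

__all__ = ["RunManifest", "run_all", "report"]


@dataclass
class RunManifest:
    config: dict
    input_hashes: Dict[str, str]
    stage_counts: Dict[str, int]
    outputs: Dict[str, str]
    seed: int
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls.from_json(Path(path).read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    inputs: Optional[Mapping[str, str | Path]] = None,
    simulate_inputs: bool = False,
    params: Optional[SimulationParams] = None,
    numerator_group: Optional[str] = None,
) -> RunManifest:
    """Execute the full pipeline and write every stage output under
    ``out_dir``. With ``simulate_inputs`` the input bundle is generated
    (seeded from the config) into ``out_dir/inputs`` and read back, so the
    run is identical to one starting from files on disk.

    ``inputs`` must otherwise provide paths keyed as the simulator writes
    them: gene_gtf, lnc_gtf, utr_fasta, lnc_fasta, mirna_fasta,
    gene_counts, mirna_counts, lnc_counts, design, gmt, ppi.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if simulate_inputs:
        params = params or SimulationParams(seed=config.rng_seed)
        dataset = simulate_dataset(params)
        inputs = dataset.write(out / "inputs")
    if inputs is None:
        raise ValueError("provide inputs or set simulate_inputs=True")
    inputs = {k: Path(v) for k, v in inputs.items()}

    counts: Dict[str, int] = {}
    outputs: Dict[str, str] = {}

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = name  # recorded relative to the run directory

    try:
        stage = "read_inputs"
        gene_models = fio.read_gtf(inputs["gene_gtf"])
        lnc_models = fio.read_gtf(inputs["lnc_gtf"])
        utr_seqs = fio.read_fasta(inputs["utr_fasta"], moltype="utr3")
        lnc_seqs = fio.read_fasta(inputs["lnc_fasta"], moltype="transcript")
        mirna_seqs = fio.read_fasta(inputs["mirna_fasta"], moltype="mirna_mature")
        gene_counts = fio.read_counts(inputs["gene_counts"], inputs["design"])
        mirna_counts = fio.read_counts(inputs["mirna_counts"], inputs["design"])
        lnc_counts = fio.read_counts(inputs["lnc_counts"], inputs["design"])
        gene_sets = fio.read_gmt(inputs["gmt"])
        ppi_edges = fio.read_edge_list(inputs["ppi"])
        verdicts = None
        domain_hits: Dict[str, float] = {}
        if "verdicts" in inputs:
            rows = fio.read_table(inputs["verdicts"], [("transcript_id", str), ("source", str), ("score", float), ("call", str)])
            verdicts = {}
            for tx, source, score, call in rows:
                verdicts.setdefault(tx, []).append(
                    lncfilter.CodingPotentialVerdict(tx, source, score, call)
                )
        if "domains" in inputs:
            for tx, evalue in fio.read_table(inputs["domains"], [("transcript_id", str), ("evalue", float)]):
                domain_hits[tx] = min(evalue, domain_hits.get(tx, float("inf")))
        counts["transcript_candidates"] = len(lnc_models)
        counts["genes"] = len(gene_models)
        counts["mirnas"] = len(mirna_seqs)

        stage = "lncfilter"
        candidates = lncfilter.run_lnc_pipeline(
            lnc_models, lnc_seqs, lnc_counts, verdicts, domain_hits, config
        )
        lnc_final = {c.transcript_id for c in candidates if c.final}
        counts["lnc_identified"] = len(lnc_final)
        _write_df(
            pd.DataFrame(
                [
                    {"transcript_id": c.transcript_id, "final": c.final,
                     **{f"stage_{s}": c.passed_stages[s] for s in lncfilter.LncCandidate.STAGES}}
                    for c in candidates
                ]
            ),
            "lnc_candidates.tsv",
        )

        stage = "de"
        de_tables = {}
        deg_results = de.screen_de(gene_counts, config, numerator_group)
        dem_results = de.screen_de(mirna_counts, config, numerator_group)
        lnc_counts_final = lnc_counts.subset([f for f in lnc_counts.feature_ids if f in lnc_final])
        del_results = de.screen_de(lnc_counts_final, config, numerator_group) if lnc_final else []
        for name, results in (("genes", deg_results), ("mirnas", dem_results), ("lncs", del_results)):
            df = pd.DataFrame(
                [{"feature_id": r.feature_id, "log2fc": r.log2fc, "p": r.p_value,
                  "fdr": r.fdr, "call": r.call} for r in results]
            )
            _write_df(df, f"de_{name}.tsv")
            de_tables[name] = results
        degs, deg_dirs = de.de_sets(deg_results)
        dems, dem_dirs = de.de_sets(dem_results)
        dels, del_dirs = de.de_sets(del_results)
        counts["deg_up"] = sum(1 for r in deg_results if r.call == "up")
        counts["deg_down"] = sum(1 for r in deg_results if r.call == "down")
        counts["deg"] = len(degs)
        counts["dem"] = len(dems)
        counts["del"] = len(dels)

        stage = "mirtarget"
        dem_seqs = [m for m in mirna_seqs if m.id in dems]
        sites_by_pair = mirtarget.scan_all(dem_seqs, utr_seqs, target_kind="utr3")
        mir_gene_pairs = mirtarget.intersect_sources(
            {"seed_scan": set(sites_by_pair)}, degs, sites_by_pair
        )
        del_seqs = [s for s in lnc_seqs if s.id in dels]
        lnc_mir_pairs = mirtarget.lnc_mirna_targets(del_seqs, mirna_seqs, dems)
        counts["mir_gene_pairs"] = len(mir_gene_pairs)
        counts["lnc_mir_pairs"] = len(lnc_mir_pairs)
        _write_df(
            pd.DataFrame(
                [{"mirna": p.mirna_id, "target": p.target_id,
                  "site_type": p.best_site.site_type if p.best_site else "",
                  "position": p.best_site.position if p.best_site else ""}
                 for p in mir_gene_pairs]
            ),
            "mir_gene_pairs.tsv",
        )
        _write_df(
            pd.DataFrame(
                [{"mirna": p.mirna_id, "lncrna": p.target_id,
                  "site_type": p.best_site.site_type if p.best_site else ""}
                 for p in lnc_mir_pairs]
            ),
            "lnc_mir_pairs.tsv",
        )

        stage = "lnctarget"
        del_models = [m for m in lnc_models if m.transcript_id in dels]
        cis_pairs = lnctarget.cis_targets(del_models, gene_models, config)
        gene_lengths = {m.gene_id: m.spliced_length for m in gene_models}
        lnc_lengths = {m.transcript_id: m.spliced_length for m in lnc_models}
        gene_fpkm = lncfilter.fpkm(gene_counts, gene_lengths)
        lnc_fpkm = lncfilter.fpkm(lnc_counts, lnc_lengths) if lnc_counts.feature_ids else None
        del_fpkm = lnc_fpkm.subset(sorted(dels)) if lnc_fpkm else None
        deg_fpkm = gene_fpkm.subset(sorted(degs))
        trans_pairs = (
            lnctarget.trans_targets(del_fpkm, deg_fpkm, config)
            if del_fpkm and del_fpkm.feature_ids
            else []
        )
        lnc_targets = lnctarget.merge_lnc_targets(cis_pairs, trans_pairs, degs)
        counts["cis_pairs"] = len(cis_pairs)
        counts["trans_pairs"] = len(trans_pairs)
        _write_df(
            pd.DataFrame(
                [{"lncrna": p.lncrna_id, "gene": p.gene_id,
                  "distance_bp": p.distance_bp, "coincide": p.coincide}
                 for p in cis_pairs]
            ),
            "cis_pairs.tsv",
        )
        _write_df(
            pd.DataFrame(
                [{"lncrna": p.lncrna_id, "gene": p.gene_id, "rho": p.rho,
                  "p": p.p_value, "n": p.n} for p in trans_pairs]
            ),
            "trans_pairs.tsv",
        )

        stage = "network"
        mir_targets = {}
        mir_evidence: Dict[Tuple[str, str], set] = {}
        for p in mir_gene_pairs:
            mir_targets.setdefault(p.mirna_id, set()).add(p.target_id)
            mir_evidence[(p.mirna_id, p.target_id)] = set(p.evidence)
        lnc_target_sets = {l: set(gs) for l, gs in lnc_targets.items()}
        lnc_evidence = {
            (l, g): {ann} for l, gs in lnc_targets.items() for g, ann in gs.items()
        }
        pair_tuples = [(p.target_id, p.mirna_id) for p in lnc_mir_pairs]
        triangles = cenet.extract_triangles(pair_tuples, mir_targets, lnc_target_sets)
        directions = {**deg_dirs, **dem_dirs, **del_dirs}
        network = cenet.assemble_network(
            triangles, pair_tuples, mir_evidence, lnc_evidence, directions
        )
        net_paths = network.write(out)
        outputs.update({p.name: p.name for p in net_paths.values()})
        deptgs = set()
        for gs in lnc_target_sets.values():
            deptgs |= gs
        for gs in mir_targets.values():
            deptgs |= gs
        hubs = cenet.ppi_hubs(ppi_edges, deptgs, config)
        consistency = cenet.direction_consistency(network)
        counts["triangles"] = len(triangles)
        counts["deptg"] = len(deptgs)
        counts["hubs"] = len(hubs.entries)
        counts["triangles_direction_consistent"] = int(consistency["n_consistent"])
        _write_df(
            pd.DataFrame(hubs.entries, columns=["gene", "degree"]), "ppi_hubs.tsv"
        )

        stage = "enrich"
        background = list(gene_counts.feature_ids)
        query = sorted(deptgs & set(background))
        if query:
            results = enrich.hypergeom_enrich(query, gene_sets, background)
            table = enrich.format_enrichment(results, config)
        else:
            results, table = [], pd.DataFrame(columns=["term", "id", "p_value", "genes"])
        counts["enriched_sets"] = len(table)
        _write_df(table, "enrichment.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=config.to_dict(),
        input_hashes={k: _sha256(v) for k, v in sorted(inputs.items())},
        stage_counts=counts,
        outputs=outputs,
        seed=config.rng_seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    manifest.save(out / "manifest.json")
    report_text = report(manifest)
    (out / "report.txt").write_text(report_text)
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable per-stage summary regenerated purely from the
    manifest (so a saved manifest reproduces the same text)."""
    c = manifest.stage_counts
    lines = [
        "cernanet run summary",
        "====================",
        f"seed: {manifest.seed}",
        "",
        f"candidate transcripts:    {c.get('transcript_candidates', 0)}",
        f"identified lncRNAs:       {c.get('lnc_identified', 0)}",
        f"DE genes (up/down/total): {c.get('deg_up', 0)}/{c.get('deg_down', 0)}/{c.get('deg', 0)}",
        f"DE miRNAs:                {c.get('dem', 0)}",
        f"DE lncRNAs:               {c.get('del', 0)}",
        f"miRNA-gene target pairs:  {c.get('mir_gene_pairs', 0)}",
        f"lncRNA-miRNA pairs:       {c.get('lnc_mir_pairs', 0)}",
        f"cis pairs:                {c.get('cis_pairs', 0)}",
        f"trans pairs:              {c.get('trans_pairs', 0)}",
        f"DEPTGs:                   {c.get('deptg', 0)}",
        f"ceRNA triangles:          {c.get('triangles', 0)}"
        + ("  (none found)" if c.get("triangles", 0) == 0 else ""),
        f"PPI hub genes:            {c.get('hubs', 0)}",
        f"enriched gene sets:       {c.get('enriched_sets', 0)}",
        "",
    ]
    return "\n".join(lines)
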