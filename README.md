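# cernanet

Integrative lncRNA–miRNA–mRNA (ceRNA) network analysis for two-group
RNA-seq designs, as a reusable, tested Python package:

- **lncRNA identification** — class-code filter, structural filter
  (≥ 2 exons, > 200 nt), coding-potential consensus (Fickett TESTCODE,
  hexamer usage log-likelihood, logistic ORF model, plus pluggable
  external verdict tables), protein-domain-hit exclusion
  (E-value < 1e-5) and an FPKM ≥ 0.1 expression floor.
- **Differential expression** — TMM normalization, pooled common
  dispersion, conditional two-sided exact negative-binomial test,
  Benjamini–Hochberg FDR; calls require FDR < 0.05 and |FC| ≥ 2.
- **miRNA target prediction** — canonical seed matching (8mer, 7mer-m8,
  7mer-A1, 6mer) with multi-source intersection restricted to DE genes,
  and lncRNA-borne site scanning for lncRNA–miRNA pairs.
- **lncRNA target genes** — cis by ±100 kb genomic windows, trans by
  Spearman |ρ| > 0.8 with p < 0.05 (Student-t approximation, n − 2 df).
- **Network assembly** — ceRNA triangle extraction (shared targets of
  paired lncRNA/miRNA), tripartite graph with DE directions, PPI degree
  hub ranking (top 10, ties kept), direction-consistency diagnostic.
- **Enrichment** — hypergeometric over-representation against GMT gene
  sets at raw p < 0.05 (optional BH).
- **Simulation** — a first-class generator that plants every structure
  the analysis assumes (NB counts with known fold changes, coding vs
  noncoding sequence composition, seed sites, cis/trans pairs, full
  ceRNA triangles) with a recorded truth table, so the entire pipeline
  runs and is scored end-to-end with no external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-value
reconstructions, brute-force oracle equivalences, statistical calibration
(type-I error, FDR control, power), planted-structure recovery and
byte-level determinism.

## Command line

```sh
# one-command synthetic end-to-end run (deterministic per seed)
cernanet run --simulate --seed 7 --out run7/

# write just the synthetic input bundle + truth JSON
cernanet simulate --out sim/ --seed 7

# individual stages on files
cernanet io validate sim/genes.gtf --format gtf
cernanet lncid --gtf sim/lnc_candidates.gtf --fasta sim/lnc_candidates.fa \
    --counts sim/lnc_counts.tsv --design sim/design.tsv --out lnc.tsv
cernanet de --counts sim/gene_counts.tsv --design sim/design.tsv \
    --numerator-group SL --out de.tsv
cernanet mirtarget --mirnas sim/mirna_mature.fa --targets sim/utr3.fa \
    --degs degs.txt --out pairs.tsv
cernanet lnctarget --lnc-gtf sim/lnc_candidates.gtf --gene-gtf sim/genes.gtf \
    --lnc-expr sim/lnc_counts.tsv --gene-expr sim/gene_counts.tsv \
    --design sim/design.tsv --degs degs.txt --out-cis cis.tsv --out-trans trans.tsv
cernanet enrich --query deptgs.txt --gmt sim/gene_sets.gmt \
    --background all_genes.txt --out enrich.tsv
```

`cernanet run` writes per-stage TSVs, network node/edge/triangle tables
(SIF-compatible edges), a `manifest.json` (config snapshot, input hashes,
per-stage counts, seed) and a plain-text report.

## Package layout

```
src/cernanet/
  config.py      # every threshold in one frozen dataclass
  formats_io.py  # GTF / FASTA / counts+design / GMT / edge lists / tables
  simulate.py    # planted-truth synthetic data generator
  lncfilter.py   # identification cascade + coding-potential scorers
  de.py          # TMM, dispersion, exact NB test, BH, full screen
  mirtarget.py   # seed-site scanner + source intersection
  lnctarget.py   # cis windows, Spearman trans targets, merging
  cenet.py       # triangles, tripartite network, PPI hubs
  enrich.py      # hypergeometric over-representation
  pipeline.py    # orchestration, manifest, report
  cli.py         # click entry points
```
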