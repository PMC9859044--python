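"""Synthetic data with planted, recorded ground truth.

Generates every input the pipeline consumes — transcript models, coding
and noncoding sequences, NB count matrices for genes/miRNAs/lncRNA
candidates, mature miRNA sequences, 3'UTRs with planted seed sites,
cis-proximal and trans-correlated lncRNA/gene pairs, gene sets and a PPI
edge list — so the full analysis can be exercised and scored against truth
without any external download. Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import formats_io as fio
from .formats_io import ExpressionMatrix, SequenceRecord, TranscriptModel

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_transcripts",
    "plant_seed_sites",
    "plant_trans_correlation",
    "simulate_dataset",
    "random_coding_sequence",
    "random_noncoding_sequence",
]

BASES = np.array(list("ACGT"))

# Biased per-codon-position base preferences for "coding" sequence: strong
# third-position G/C bias and first-position purine bias give both a
# periodicity (Fickett) and a hexamer-usage signal against uniform
# background. Stop codons are excluded when drawing ORF codons.
_CODON_POS_PROBS = (
    np.array([0.35, 0.15, 0.35, 0.15]),  # position 1: A C G T
    np.array([0.35, 0.20, 0.15, 0.30]),  # position 2
    np.array([0.10, 0.40, 0.40, 0.10]),  # position 3
)
STOP_CODONS = ("TAA", "TAG", "TGA")
MAX_NONCODING_ORF = 150  # nt, exclusive upper bound for generated noncoding
MIN_CODING_ORF = 300  # nt, inclusive lower bound for generated coding
REJECTION_CAP = 1000


@dataclass
class SimulationParams:
    n_per_group: int = 6
    n_genes: int = 300
    n_mirnas: int = 30
    n_lnc_candidates: int = 80
    n_triangles: int = 10
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.0
    seed: int = 0
    group_labels: Tuple[str, str] = ("SL", "L")

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not 0 <= self.frac_de < 1:
            raise ValueError("frac_de must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class SimulationTruth:
    """Planted ground truth; every id refers to a generated feature."""

    de_features: Dict[str, Tuple[float, str]] = field(default_factory=dict)
    noncoding_tx: Set[str] = field(default_factory=set)
    coding_tx: Set[str] = field(default_factory=set)
    planted_seed_sites: List[Tuple[str, str, str, int]] = field(default_factory=list)
    planted_cis_pairs: List[Tuple[str, str, int]] = field(default_factory=list)
    planted_trans_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    planted_triangles: List[Tuple[str, str, str]] = field(default_factory=list)

    def merge(self, other: "SimulationTruth") -> None:
        self.de_features.update(other.de_features)
        self.noncoding_tx |= other.noncoding_tx
        self.coding_tx |= other.coding_tx
        self.planted_seed_sites += other.planted_seed_sites
        self.planted_cis_pairs += other.planted_cis_pairs
        self.planted_trans_pairs += other.planted_trans_pairs
        self.planted_triangles += other.planted_triangles

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["noncoding_tx"] = sorted(self.noncoding_tx)
        d["coding_tx"] = sorted(self.coding_tx)

        def _tolerant(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON serializable: {type(obj)}")

        return json.dumps(d, indent=1, sort_keys=True, default=_tolerant)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            de_features={k: (v[0], v[1]) for k, v in d["de_features"].items()},
            noncoding_tx=set(d["noncoding_tx"]),
            coding_tx=set(d["coding_tx"]),
            planted_seed_sites=[tuple(x) for x in d["planted_seed_sites"]],
            planted_cis_pairs=[tuple(x) for x in d["planted_cis_pairs"]],
            planted_trans_pairs=[tuple(x) for x in d["planted_trans_pairs"]],
            planted_triangles=[tuple(x) for x in d["planted_triangles"]],
        )


# ---------------------------------------------------------------------------
# sequence generators
# ---------------------------------------------------------------------------

def _uniform_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _biased_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(
            rng.choice(BASES, p=_CODON_POS_PROBS[i]) for i in range(3)
        )
        if codon not in STOP_CODONS:
            return codon


def random_coding_sequence(
    rng: np.random.Generator,
    n_codons_range: Tuple[int, int] = (100, 250),
    utr5_range: Tuple[int, int] = (0, 60),
    utr3_range: Tuple[int, int] = (10, 120),
) -> str:
    """Transcript with an ATG..stop ORF of >= 300 nt drawn from the biased
    codon table, flanked by uniform-composition UTRs."""
    n_codons = int(rng.integers(*n_codons_range, endpoint=True))
    utr5 = _uniform_seq(rng, int(rng.integers(*utr5_range, endpoint=True)))
    utr3 = _uniform_seq(rng, int(rng.integers(*utr3_range, endpoint=True)))
    body = "".join(_biased_codon(rng) for _ in range(n_codons))
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return utr5 + "ATG" + body + stop + utr3


def random_noncoding_sequence(
    rng: np.random.Generator,
    length_range: Tuple[int, int] = (250, 700),
    max_orf: int = MAX_NONCODING_ORF,
) -> str:
    """Uniform-composition sequence whose longest ORF is < max_orf nt
    (rejection-sampled)."""
    from .lncfilter import longest_orf

    length = int(rng.integers(*length_range, endpoint=True))
    for _ in range(REJECTION_CAP):
        seq = _uniform_seq(rng, length)
        if longest_orf(seq)[2] < max_orf:
            return seq
    raise RuntimeError(f"could not generate a noncoding sequence of length {length}")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (numpy n/p parameterization)."""
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    feature_prefix: str = "G",
    n_features: Optional[int] = None,
    planted: Optional[Mapping[str, Tuple[float, str]]] = None,
    baseline_means: Optional[Mapping[str, float]] = None,
) -> Tuple[ExpressionMatrix, SimulationTruth]:
    """Two-group NB count matrix with planted fold changes.

    Baseline per-feature means are exp(N(baseline_log_mean, baseline_log_sd));
    planted features ("up"/"down", |log2fc| = planted_log2fc) have the fold
    applied multiplicatively in the first group. With ``planted`` given it
    overrides the random frac_de selection; ``baseline_means`` pins chosen
    features' baselines.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = n_features if n_features is not None else params.n_genes
    width = max(4, len(str(n)))
    features = [f"{feature_prefix}{i + 1:0{width}d}" for i in range(n)]
    ga, gb = params.group_labels
    samples = [f"{ga}{i + 1}" for i in range(params.n_per_group)] + [
        f"{gb}{i + 1}" for i in range(params.n_per_group)
    ]
    design = {s: (ga if s.startswith(ga) else gb) for s in samples}

    base = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=n))
    if baseline_means:
        for i, f in enumerate(features):
            if f in baseline_means:
                base[i] = baseline_means[f]

    if planted is None:
        n_de = int(round(params.frac_de * n))
        de_idx = rng.choice(n, size=n_de, replace=False)
        planted = {}
        for j, i in enumerate(sorted(de_idx)):
            direction = "up" if j % 2 == 0 else "down"
            lfc = params.planted_log2fc if direction == "up" else -params.planted_log2fc
            planted = {**planted, features[i]: (lfc, direction)}
    truth = SimulationTruth(de_features=dict(planted))

    fold = np.ones(n)
    for i, f in enumerate(features):
        if f in planted:
            fold[i] = 2.0 ** planted[f][0]

    n_per = params.n_per_group
    mean_a = base * fold
    mean_b = base
    values = np.empty((n, 2 * n_per))
    for j in range(n_per):
        values[:, j] = _nb_draw(rng, mean_a, params.nb_dispersion)
    for j in range(n_per):
        values[:, n_per + j] = _nb_draw(rng, mean_b, params.nb_dispersion)
    matrix = ExpressionMatrix(features, samples, values, unit="count", design=design)
    return matrix, truth


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def _exonize(
    rng: np.random.Generator, chrom: str, start: int, total_len: int, n_exons: int
) -> List[Tuple[int, int]]:
    """Split total_len nt into n_exons exons with random intron gaps."""
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    pieces = np.diff(np.r_[0, cuts, total_len])
    exons = []
    pos = start
    for k, piece in enumerate(pieces):
        exons.append((pos, pos + int(piece) - 1))
        pos += int(piece) + int(rng.integers(100, 2000))  # intron
    return exons


def simulate_transcripts(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    prefix: str = "LNC",
) -> Tuple[List[TranscriptModel], List[SequenceRecord], SimulationTruth]:
    """Candidate transcript pool spanning both sides of every
    identification filter.

    ~60% true noncoding passing class/structure filters, ~15% coding
    contaminants with kept class codes, ~15% structure failures (single
    exon or length <= 200) and ~10% class-code failures ("=", "c").
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n = params.n_lnc_candidates
    truth = SimulationTruth()
    models: List[TranscriptModel] = []
    seqs: List[SequenceRecord] = []
    kept_codes = ["u", "i", "x"]
    for i in range(n):
        tx_id = f"{prefix}{i + 1:04d}"
        r = i % 20
        if r < 12:  # clean lncRNA
            seq = random_noncoding_sequence(rng)
            code = kept_codes[i % 3]
            n_exons = int(rng.integers(2, 5))
            truth.noncoding_tx.add(tx_id)
        elif r < 15:  # coding contaminant with a kept class code
            seq = random_coding_sequence(rng)
            code = kept_codes[i % 3]
            n_exons = int(rng.integers(2, 5))
            truth.coding_tx.add(tx_id)
        elif r < 18:  # structure failure
            if r % 2 == 0:
                seq = random_noncoding_sequence(rng, length_range=(250, 700))
                n_exons = 1
            else:
                seq = random_noncoding_sequence(rng, length_range=(60, 200), max_orf=60)
                n_exons = 2
            code = kept_codes[i % 3]
            truth.noncoding_tx.add(tx_id)
        else:  # class-code failure
            seq = random_noncoding_sequence(rng)
            code = "=" if r == 18 else "c"
            n_exons = int(rng.integers(2, 5))
            truth.noncoding_tx.add(tx_id)
        n_exons = min(n_exons, len(seq) - 1) if len(seq) > 1 else 1
        chrom = f"chrL{(i % 4) + 1}"
        start = 10_000 + (i // 4) * 500_000
        exons = _exonize(rng, chrom, start, len(seq), n_exons)
        models.append(
            TranscriptModel(tx_id, f"{tx_id}.g", chrom, "+", exons, class_code=code)
        )
        seqs.append(SequenceRecord(tx_id, seq, moltype="transcript"))
    return models, seqs, truth


# ---------------------------------------------------------------------------
# seed-site planting
# ---------------------------------------------------------------------------

def _all_cores(mirnas: Sequence[SequenceRecord]) -> Dict[str, str]:
    from .mirtarget import revcomp

    return {m.id: revcomp(m.seq[1:7]) for m in mirnas}


def _contains_any_core(seq: str, cores: Mapping[str, str]) -> bool:
    return any(core in seq for core in cores.values())


def plant_seed_sites(
    targets: Sequence[SequenceRecord],
    mirnas: Sequence[SequenceRecord],
    site_plan: Sequence[Tuple[str, str, str]],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    hygiene_ids: Optional[Set[str]] = None,
    constraints: Optional[Mapping[str, Callable[[str], bool]]] = None,
) -> Tuple[List[SequenceRecord], SimulationTruth]:
    """Write canonical seed sites into target sequences at recorded
    positions and scrub everything else.

    ``site_plan`` is a list of (mirna_id, target_id, site_type). Planned
    targets are rebuilt (uniform background, rejection-sampled) so they
    contain exactly the planned sites and no other canonical core of any
    simulated miRNA; sequences in ``hygiene_ids`` (default: all non-target
    sequences) are rejection-sampled to contain no core at all.
    ``constraints`` maps target_id -> predicate the resampled background
    must also satisfy (e.g. a maximum-ORF rule for noncoding sequences).
    """
    from .mirtarget import revcomp, seed_sites, site_string

    if rng is None:
        rng = np.random.default_rng(seed)
    mirna_by_id = {m.id: m for m in mirnas}
    cores = _all_cores(mirnas)
    plans_by_target: Dict[str, List[Tuple[str, str]]] = {}
    for mirna_id, target_id, stype in site_plan:
        if mirna_id not in mirna_by_id:
            raise ValueError(f"unknown miRNA {mirna_id!r} in site plan")
        plans_by_target.setdefault(target_id, []).append((mirna_id, stype))

    truth = SimulationTruth()
    out: List[SequenceRecord] = []
    constraints = constraints or {}
    for rec in targets:
        plans = plans_by_target.get(rec.id)
        constraint = constraints.get(rec.id)
        if plans:
            new_seq, sites = _plant_into(rec, plans, mirna_by_id, cores, rng, constraint)
            truth.planted_seed_sites.extend(sites)
            out.append(SequenceRecord(rec.id, new_seq, moltype=rec.moltype))
        elif hygiene_ids is None or rec.id in hygiene_ids:
            seq = _scrub_cores(rec.seq, cores, rng, constraint, rec.id)
            out.append(SequenceRecord(rec.id, seq, moltype=rec.moltype))
        else:
            out.append(rec)
    unplanned = set(plans_by_target) - {r.id for r in targets}
    if unplanned:
        raise ValueError(f"site plan references unknown targets: {sorted(unplanned)}")
    return out, truth


def _scrub_cores(
    seq: str,
    cores: Mapping[str, str],
    rng: np.random.Generator,
    constraint: Optional[Callable[[str], bool]],
    seq_id: str,
) -> str:
    """Point-mutate away every canonical core occurrence (local repair
    converges where whole-sequence rejection sampling would not)."""
    chars = list(seq)
    for _ in range(REJECTION_CAP * 4):
        text = "".join(chars)
        hit = -1
        for core in cores.values():
            pos = text.find(core)
            if pos != -1:
                hit = pos
                break
        if hit == -1:
            if constraint is None or constraint(text):
                return text
            # constraint broken (e.g. a long ORF emerged): rewrite a window
            w = int(rng.integers(0, max(1, len(chars) - 30)))
            chars[w : w + 30] = list(_uniform_seq(rng, min(30, len(chars) - w)))
            continue
        i = hit + int(rng.integers(0, 6))
        chars[i] = _other_base(rng, chars[i])
    raise RuntimeError(f"could not scrub cores from {seq_id}")


def _plant_into(
    rec: SequenceRecord,
    plans: List[Tuple[str, str]],
    mirna_by_id: Mapping[str, SequenceRecord],
    cores: Mapping[str, str],
    rng: np.random.Generator,
    constraint: Optional[Callable[[str], bool]],
) -> Tuple[str, List[Tuple[str, str, str, int]]]:
    """Rebuild one target so it contains exactly the planned sites."""
    from .mirtarget import seed_sites

    length = len(rec.seq)
    need = sum(10 for _ in plans)
    if length < need + 2:
        raise ValueError(f"target {rec.id} (len {length}) too short for {len(plans)} sites")
    comp = str.maketrans("ACGT", "TGCA")
    for _ in range(REJECTION_CAP):
        background = _scrub_cores(_uniform_seq(rng, length), cores, rng, constraint, rec.id)
        # non-overlapping 8 nt windows, core at window+1
        starts = sorted(
            rng.choice(np.arange(1, length - 9), size=len(plans), replace=False)
        )
        if any(b - a < 10 for a, b in zip(starts, starts[1:])):
            continue
        seq = list(background)
        expected: List[Tuple[str, str, str, int]] = []
        for w, (mirna_id, stype) in zip(starts, plans):
            m = mirna_by_id[mirna_id].seq
            core = cores[mirna_id]
            m8c = m[7].translate(comp)
            left = m8c if stype in ("8mer", "7mer-m8") else _other_base(rng, m8c)
            right = "A" if stype in ("8mer", "7mer-A1") else _other_base(rng, "A")
            window = left + core + right
            seq[w - 1 : w + 7] = window
            pos = w if stype in ("8mer", "7mer-m8") else w + 1  # 1-based site start
            expected.append((mirna_id, rec.id, stype, pos))
        candidate = "".join(seq)
        if constraint is not None and not constraint(candidate):
            continue
        if _sites_match(candidate, rec, mirna_by_id, expected):
            return candidate, expected
    raise RuntimeError(f"could not plant sites into {rec.id} within {REJECTION_CAP} attempts")


def _other_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _sites_match(
    seq: str,
    rec: SequenceRecord,
    mirna_by_id: Mapping[str, SequenceRecord],
    expected: List[Tuple[str, str, str, int]],
) -> bool:
    """Exactly the expected sites, nothing else, across all miRNAs."""
    from .mirtarget import seed_sites

    probe = SequenceRecord(rec.id, seq, moltype=rec.moltype)
    found = []
    for m in mirna_by_id.values():
        for s in seed_sites(m, probe):
            found.append((s.mirna_id, s.target_id, s.site_type, s.position))
    return sorted(found) == sorted(expected)


# ---------------------------------------------------------------------------
# trans-correlation planting
# ---------------------------------------------------------------------------

def plant_trans_correlation(
    expr: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str, float]],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    lnc_expr: Optional[ExpressionMatrix] = None,
    preserve_groups: bool = False,
) -> Tuple[ExpressionMatrix, SimulationTruth]:
    """Rewrite gene rows so each (lncrna, gene, target_rho) pair has sample
    Spearman correlation centered on target_rho.

    A Gaussian copula on ranks is used: the bivariate-normal latent
    correlation a = 2*sin(pi*rho/6) yields population Spearman rho. The
    gene's own values are kept as the marginal (sorted, tie-broken to be
    strictly increasing) and reassigned by latent rank, which preserves an
    aligned group effect. target_rho >= 1 is an exact monotone transform.

    With ``preserve_groups`` each design group keeps its own block of the
    sorted marginal (ordered within the group by the latent variable), so
    a planted group fold change survives the rewrite exactly; the realized
    correlation then sits at or above the target when the lncRNA itself
    separates the groups.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lnc_source = lnc_expr if lnc_expr is not None else expr
    values = expr.values.copy()
    findex = expr._findex
    n = len(expr.sample_ids)
    truth = SimulationTruth()
    for lnc_id, gene_id, target_rho in pairs:
        if gene_id not in findex:
            raise ValueError(f"unknown gene {gene_id!r} in trans plan")
        if lnc_id not in lnc_source._findex:
            raise ValueError(f"unknown lncRNA {lnc_id!r} in trans plan")
        if not 0 < target_rho <= 1:
            raise ValueError(f"target_rho must be in (0, 1], got {target_rho}")
        x = lnc_source.row(lnc_id)
        # latent z for the lncRNA from (tie-broken) ranks
        order = np.lexsort((rng.random(n), x))
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        from scipy.stats import norm

        zx = norm.ppf((ranks - 0.375) / (n + 0.25))
        if target_rho >= 1.0:
            zg = zx
        else:
            a = 2.0 * math.sin(math.pi * target_rho / 6.0)
            zg = a * zx + math.sqrt(1.0 - a * a) * rng.standard_normal(n)
        orig = values[findex[gene_id]]
        gene_sorted = np.sort(orig) + np.arange(n)  # strictly increasing marginal
        if preserve_groups and expr.design:
            cols_by_group: Dict[str, List[int]] = {}
            for idx, s in enumerate(expr.sample_ids):
                cols_by_group.setdefault(expr.design[s], []).append(idx)
            new_row = np.empty(n)
            offset = 0
            # ascending group mean gets the low block of the marginal
            for _label, cols in sorted(
                cols_by_group.items(), key=lambda kv: orig[kv[1]].mean()
            ):
                block = gene_sorted[offset : offset + len(cols)]
                order_in_group = np.argsort(zg[cols], kind="stable")
                for rank_i, ci in enumerate(order_in_group):
                    new_row[cols[ci]] = block[rank_i]
                offset += len(cols)
            values[findex[gene_id]] = new_row
        else:
            gene_ranks = np.empty(n, dtype=int)
            gene_ranks[np.argsort(zg, kind="stable")] = np.arange(n)
            values[findex[gene_id]] = gene_sorted[gene_ranks]
        truth.planted_trans_pairs.append((lnc_id, gene_id, float(target_rho)))
    out = ExpressionMatrix(expr.feature_ids, expr.sample_ids, values,
                           unit=expr.unit, design=expr.design)
    return out, truth


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    params: SimulationParams
    truth: SimulationTruth
    gene_models: List[TranscriptModel]
    lnc_models: List[TranscriptModel]
    gene_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    lnc_counts: ExpressionMatrix
    utr_seqs: List[SequenceRecord]
    lnc_seqs: List[SequenceRecord]
    mirna_seqs: List[SequenceRecord]
    gene_sets: fio.GeneSetCollection
    ppi_edges: List[Tuple[str, str]]

    def write(self, out_dir: str | Path) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_gtf": out / "genes.gtf",
            "lnc_gtf": out / "lnc_candidates.gtf",
            "utr_fasta": out / "utr3.fa",
            "lnc_fasta": out / "lnc_candidates.fa",
            "mirna_fasta": out / "mirna_mature.fa",
            "gene_counts": out / "gene_counts.tsv",
            "mirna_counts": out / "mirna_counts.tsv",
            "lnc_counts": out / "lnc_counts.tsv",
            "design": out / "design.tsv",
            "gmt": out / "gene_sets.gmt",
            "ppi": out / "ppi_edges.tsv",
            "truth": out / "truth.json",
        }
        fio.write_gtf(self.gene_models, paths["gene_gtf"])
        fio.write_gtf(self.lnc_models, paths["lnc_gtf"])
        fio.write_fasta(self.utr_seqs, paths["utr_fasta"])
        fio.write_fasta(self.lnc_seqs, paths["lnc_fasta"])
        fio.write_fasta(self.mirna_seqs, paths["mirna_fasta"])
        fio.write_counts(self.gene_counts, paths["gene_counts"])
        fio.write_counts(self.mirna_counts, paths["mirna_counts"])
        fio.write_counts(self.lnc_counts, paths["lnc_counts"])
        fio.write_design(self.gene_counts.design, paths["design"])
        fio.write_gmt(self.gene_sets, paths["gmt"])
        fio.write_edge_list(self.ppi_edges, paths["ppi"])
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _random_mirnas(rng: np.random.Generator, n: int) -> List[SequenceRecord]:
    """Random 22-mers whose maximal 8 nt site windows are mutually core-free,
    so planting any site type for one miRNA can never create a site for
    another."""
    from .mirtarget import site_string

    out: List[SequenceRecord] = []
    cores: List[str] = []
    windows: List[str] = []
    while len(out) < n:
        seq = _uniform_seq(rng, 22)
        if "AAAAA" in seq:
            continue
        window = site_string(seq, "8mer")
        core = window[1:7]
        if any(c in window for c in cores) or any(core in w for w in windows):
            continue
        cores.append(core)
        windows.append(window)
        out.append(SequenceRecord(f"mir-{len(out) + 1:04d}", seq, moltype="mirna_mature"))
    return out


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate the full input bundle with planted ceRNA triangles.

    Triangle i couples lncRNA TLNC_i (DE up, passes every identification
    filter), miRNA M_i (DE down) and gene TG_i (DE up): the miRNA has a
    planted site in both the gene's 3'UTR and the lncRNA, the lncRNA lies
    within the cis window of the gene, and the pair is also planted with
    trans correlation 0.9.
    """
    rng = np.random.default_rng(params.seed)
    truth = SimulationTruth()
    k = params.n_triangles
    if k > params.n_mirnas or 3 * k > params.n_genes:
        raise ValueError("too many triangles for the feature space")

    # -- feature ids --------------------------------------------------------
    width = max(4, len(str(params.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(params.n_genes)]
    mirnas = _random_mirnas(rng, params.n_mirnas)
    tri_genes = gene_ids[:k]
    tri_mirs = [m.id for m in mirnas[:k]]

    # -- lncRNA candidate pool + extra triangle lncRNAs --------------------
    lnc_models, lnc_seqs, lnc_truth = simulate_transcripts(params, rng=rng)
    truth.merge(lnc_truth)
    tri_lncs = []
    for i in range(k):
        tx_id = f"TLNC{i + 1:04d}"
        seq = random_noncoding_sequence(rng, length_range=(500, 800))
        lnc_seqs.append(SequenceRecord(tx_id, seq, moltype="transcript"))
        truth.noncoding_tx.add(tx_id)
        tri_lncs.append(tx_id)

    # -- gene models on a deterministic grid; triangle lncRNAs placed cis --
    gene_models: List[TranscriptModel] = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{(i % 4) + 1}"
        start = 1_000_000 + (i // 4) * 400_000
        glen = int(rng.integers(2_000, 10_000))
        exons = _exonize(rng, chrom, start, glen, int(rng.integers(2, 6)))
        gene_models.append(
            TranscriptModel(f"{gid}.t1", gid, chrom, "+" if i % 2 else "-",
                            exons, class_code="=", biotype_hint="coding")
        )
    for i, (lnc_id, gid) in enumerate(zip(tri_lncs, tri_genes)):
        gm = gene_models[gene_ids.index(gid)]
        seq_len = len(next(s for s in lnc_seqs if s.id == lnc_id).seq)
        if i % 3 == 0:  # overlapping span ("coincide")
            start = gm.span[0] + 100
            distance = 0
        else:
            distance = int(rng.integers(1_000, 80_000))
            start = gm.span[1] + distance
        exons = _exonize(rng, gm.chrom, start, seq_len, 2)
        # keep the gap to the gene equal to the recorded distance
        lnc_models.append(
            TranscriptModel(lnc_id, f"{lnc_id}.g", gm.chrom, "+", exons, class_code="u")
        )
        from .lnctarget import span_distance

        actual = span_distance(lnc_models[-1].span, gm.span)
        truth.planted_cis_pairs.append((lnc_id, gid, actual))

    # -- counts with forced DE on triangle members -------------------------
    high = 300.0
    planted_genes: Dict[str, Tuple[float, str]] = {
        g: (params.planted_log2fc, "up") for g in tri_genes
    }
    n_extra = max(0, int(round(params.frac_de * params.n_genes)) - k)
    extra_idx = rng.choice(np.arange(k, params.n_genes), size=n_extra, replace=False)
    for j, i in enumerate(sorted(extra_idx)):
        direction = "up" if j % 2 == 0 else "down"
        lfc = params.planted_log2fc if direction == "up" else -params.planted_log2fc
        planted_genes[gene_ids[i]] = (lfc, direction)
    gene_counts, gtruth = simulate_counts(
        params, rng=rng, feature_prefix="G", n_features=params.n_genes,
        planted=planted_genes, baseline_means={g: high for g in tri_genes},
    )
    truth.de_features.update(gtruth.de_features)

    # alternate directions so one-sided planting does not bias normalization
    planted_mirs: Dict[str, Tuple[float, str]] = {
        m: ((-params.planted_log2fc, "down") if i % 2 == 0 else (params.planted_log2fc, "up"))
        for i, m in enumerate(tri_mirs)
    }
    mirna_counts, mtruth = simulate_counts(
        params, rng=rng, feature_prefix="mir-", n_features=params.n_mirnas,
        planted=planted_mirs, baseline_means={m: high for m in tri_mirs},
    )
    assert mirna_counts.feature_ids == [m.id for m in mirnas]
    truth.de_features.update(mtruth.de_features)

    lnc_ids = [s.id for s in lnc_seqs]
    planted_lncs: Dict[str, Tuple[float, str]] = {
        l: (params.planted_log2fc, "up") for l in tri_lncs
    }
    n_extra_l = max(0, int(round(params.frac_de * len(lnc_ids))) - k)
    other_lnc = [l for l in lnc_ids if l not in planted_lncs]
    extra_l = rng.choice(len(other_lnc), size=min(n_extra_l, len(other_lnc)), replace=False)
    for j, i in enumerate(sorted(extra_l)):
        direction = "up" if j % 2 == 0 else "down"
        lfc = params.planted_log2fc if direction == "up" else -params.planted_log2fc
        planted_lncs[other_lnc[i]] = (lfc, direction)
    lnc_counts, _ = simulate_counts(
        params, rng=rng, feature_prefix="LNCTMP", n_features=len(lnc_ids),
        planted={}, baseline_means=None,
    )
    # rebuild with real ids and planted folds (keeps one rng stream)
    base = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=len(lnc_ids)))
    fold = np.ones(len(lnc_ids))
    for i, l in enumerate(lnc_ids):
        if l in planted_lncs:
            base[i] = high
            fold[i] = 2.0 ** planted_lncs[l][0]
    n_per = params.n_per_group
    vals = np.empty((len(lnc_ids), 2 * n_per))
    for j in range(n_per):
        vals[:, j] = _nb_draw(rng, base * fold, params.nb_dispersion)
    for j in range(n_per):
        vals[:, n_per + j] = _nb_draw(rng, base, params.nb_dispersion)
    lnc_counts = ExpressionMatrix(lnc_ids, lnc_counts.sample_ids, vals,
                                  unit="count", design=lnc_counts.design)
    truth.de_features.update(planted_lncs)

    # -- trans correlation for triangle pairs ------------------------------
    trans_plan = [(l, g, 0.9) for l, g in zip(tri_lncs, tri_genes)]
    gene_counts, ttruth = plant_trans_correlation(
        gene_counts, trans_plan, rng=rng, lnc_expr=lnc_counts, preserve_groups=True
    )
    truth.planted_trans_pairs += ttruth.planted_trans_pairs

    # -- 3'UTRs and seed sites ---------------------------------------------
    utr_seqs = [
        SequenceRecord(gid, _uniform_seq(rng, int(rng.integers(250, 400))), moltype="utr3")
        for gid in gene_ids
    ]
    site_types = ["8mer", "7mer-m8", "7mer-A1"]
    utr_plan = [(m, g, site_types[i % 3]) for i, (m, g) in enumerate(zip(tri_mirs, tri_genes))]
    utr_seqs, utr_truth = plant_seed_sites(utr_seqs, mirnas, utr_plan, rng=rng)
    truth.planted_seed_sites += utr_truth.planted_seed_sites

    from .lncfilter import longest_orf

    lnc_plan = [(m, l, site_types[(i + 1) % 3]) for i, (m, l) in enumerate(zip(tri_mirs, tri_lncs))]
    noncoding_ok = lambda s: longest_orf(s)[2] < MAX_NONCODING_ORF  # noqa: E731
    constraints = {tx: noncoding_ok for tx in truth.noncoding_tx}
    hygiene = {s.id for s in lnc_seqs if s.id in truth.noncoding_tx}
    lnc_seqs, lnc_site_truth = plant_seed_sites(
        lnc_seqs, mirnas, lnc_plan, rng=rng, hygiene_ids=hygiene, constraints=constraints
    )
    truth.planted_seed_sites += lnc_site_truth.planted_seed_sites

    truth.planted_triangles = [
        (l, m, g) for l, m, g in zip(tri_lncs, tri_mirs, tri_genes)
    ]

    # -- gene sets: one stacked with planted DE genes, rest random ---------
    de_genes = [g for g in gene_ids if g in planted_genes]
    sets: Dict[str, Tuple[str, List[str]]] = {}
    stacked = de_genes[: min(12, len(de_genes))]
    filler = [g for g in gene_ids if g not in stacked]
    sets["SET0001"] = ("planted_de_pathway", stacked + filler[:3])
    for s in range(4):
        members = list(rng.choice(gene_ids, size=15, replace=False))
        sets[f"SET{s + 2:04d}"] = (f"random_pathway_{s + 1}", sorted(set(members)))
    gene_sets = fio.GeneSetCollection(sets)

    # -- PPI: a planted hub over the triangle genes plus random edges ------
    hub = tri_genes[0] if tri_genes else gene_ids[0]
    ppi: List[Tuple[str, str]] = [(hub, g) for g in de_genes if g != hub][:15]
    pool = de_genes if len(de_genes) >= 2 else gene_ids
    for _ in range(60):
        a, b = rng.choice(pool, size=2, replace=False)
        if a != b:
            ppi.append((str(a), str(b)))

    return SimulatedDataset(
        params=params,
        truth=truth,
        gene_models=gene_models,
        lnc_models=lnc_models,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        lnc_counts=lnc_counts,
        utr_seqs=utr_seqs,
        lnc_seqs=lnc_seqs,
        mirna_seqs=mirnas,
        gene_sets=gene_sets,
        ppi_edges=ppi,
    )
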