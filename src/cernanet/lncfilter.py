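"""lncRNA identification cascade.

Stages, applied in order per candidate transcript:

1. assembly class code in the kept set (default {i, u, x});
2. structure: exon count >= 2 and spliced length > 200 nt;
3. coding-potential consensus: every enabled scorer must call noncoding;
4. no significant protein-domain hit (E-value < 1e-5);
5. expression floor: FPKM >= 0.1 in at least one sample.

Three coding-potential scorers ship in-repo (Fickett TESTCODE, hexamer
usage log-likelihood, a logistic combination of ORF features) and external
verdict tables can be intersected alongside or instead of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .formats_io import ExpressionMatrix, SequenceRecord, TranscriptModel

__all__ = [
    "CodingPotentialVerdict",
    "LncCandidate",
    "filter_class_code",
    "filter_structure",
    "longest_orf",
    "fickett_score",
    "train_hexamer_table",
    "hexamer_score",
    "OrfLogitModel",
    "consensus_call",
    "fpkm",
    "filter_expression",
    "run_lnc_pipeline",
    "FICKETT_CODING_CUTOFF",
    "HEXAMER_CODING_CUTOFF",
    "ORF_LOGIT_CODING_CUTOFF",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# Bundled decision thresholds (overridable by callers); scores at or above
# the cutoff are called coding.
FICKETT_CODING_CUTOFF = 0.95
HEXAMER_CODING_CUTOFF = 0.0
ORF_LOGIT_CODING_CUTOFF = 0.5


@dataclass
class CodingPotentialVerdict:
    transcript_id: str
    source: str
    score: float
    call: str  # "coding" | "noncoding"

    def __post_init__(self) -> None:
        if self.call not in ("coding", "noncoding"):
            raise ValueError(f"bad call {self.call!r}")


@dataclass
class LncCandidate:
    """Audit record of one transcript through the cascade.

    ``passed_stages`` maps stage name -> True/False, or None when a stage
    was never evaluated because an earlier one failed (short-circuit).
    """

    transcript_id: str
    passed_stages: Dict[str, Optional[bool]] = field(default_factory=dict)
    final: bool = False

    STAGES = ("class_code", "structure", "consensus", "domain", "expression")


# ---------------------------------------------------------------------------
# structural filters
# ---------------------------------------------------------------------------

def filter_class_code(
    txs: Iterable[TranscriptModel], config: PipelineConfig
) -> List[TranscriptModel]:
    """Keep transcripts whose class code is in the configured kept set;
    transcripts with no class code are dropped."""
    kept = config.class_codes_kept
    return [t for t in txs if t.class_code is not None and t.class_code in kept]


def filter_structure(
    txs: Iterable[TranscriptModel], config: PipelineConfig
) -> List[TranscriptModel]:
    """Keep transcripts with >= min_exons exons and spliced length
    >= min_tx_length (strictly more than 200 nt at defaults)."""
    return [
        t
        for t in txs
        if t.n_exons >= config.min_exons and t.spliced_length >= config.min_tx_length
    ]


# ---------------------------------------------------------------------------
# ORF search
# ---------------------------------------------------------------------------

def longest_orf(seq: str) -> Tuple[int, int, int]:
    """Longest ATG..stop open reading frame on the sense strand.

    Searches all 3 frames; returns ``(start, end, length_nt)`` with 1-based
    inclusive coordinates (length includes the stop codon), or ``(0, 0, 0)``
    when no complete ORF exists.
    """
    seq = seq.upper().replace("U", "T")
    best = (0, 0, 0)
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = i + 3 - start
                if length > best[2]:
                    best = (start + 1, i + 3, length)
                start = None
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------
# Published TESTCODE probability and weight tables (position asymmetry and
# base content). Position parameter thresholds descend from 1.9; content
# thresholds from 0.33.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for idx, cut in enumerate(thresholds):
        if value >= cut:
            return probs[idx]
    return probs[len(thresholds) - 1]


def fickett_score(seq: str) -> float:
    """Classic TESTCODE statistic; higher is more coding-like.

    Computed from the per-base position asymmetry across the three frame
    positions and the per-base content fraction, each mapped through the
    published lookup tables and weighted. Sequences shorter than 200 nt are
    scored anyway but are low-confidence.
    """
    seq = seq.upper().replace("U", "T")
    usable = [b for b in seq if b in "ACGT"]
    n = len(usable)
    if n == 0:
        return 0.0
    frame_counts = {b: [0, 0, 0] for b in "ACGT"}
    pos = 0
    for b in seq:
        if b in "ACGT":
            frame_counts[b][pos % 3] += 1
        pos += 1
    score = 0.0
    for b in "ACGT":
        counts = frame_counts[b]
        position_param = max(counts) / (min(counts) + 1.0)
        content_param = sum(counts) / n
        score += _POSITION_WEIGHT[b] * _lookup(position_param, _POSITION_PARA, _POSITION_PROB[b])
        score += _CONTENT_WEIGHT[b] * _lookup(content_param, _CONTENT_PARA, _CONTENT_PROB[b])
    return score


# ---------------------------------------------------------------------------
# hexamer usage score
# ---------------------------------------------------------------------------

def _hexamers(seq: str, step: int = 3):
    for i in range(0, len(seq) - 5, step):
        h = seq[i : i + 6]
        if set(h) <= set("ACGT"):
            yield h


def train_hexamer_table(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str], pseudocount: float = 1.0
) -> Dict[str, Tuple[float, float]]:
    """Estimate in-frame hexamer frequencies from labelled sequence sets.

    Returns hexamer -> (f_coding, f_noncoding), pseudocount-smoothed over
    the full 4^6 alphabet so every ratio is finite.
    """
    from itertools import product

    alphabet = ["".join(p) for p in product("ACGT", repeat=6)]
    counts = {h: [pseudocount, pseudocount] for h in alphabet}
    totals = [pseudocount * len(alphabet), pseudocount * len(alphabet)]
    for label, seqs in ((0, coding_seqs), (1, noncoding_seqs)):
        for seq in seqs:
            seq = seq.upper().replace("U", "T")
            for h in _hexamers(seq):
                counts[h][label] += 1
                totals[label] += 1
    return {h: (c[0] / totals[0], c[1] / totals[1]) for h, c in counts.items()}


def hexamer_score(seq: str, hexamer_table: Mapping[str, Tuple[float, float]]) -> float:
    """Mean log(f_coding/f_noncoding) over in-frame hexamers (step 3);
    0.0 for sequences shorter than 6 nt."""
    seq = seq.upper().replace("U", "T")
    ratios = [
        math.log(hexamer_table[h][0] / hexamer_table[h][1])
        for h in _hexamers(seq)
        if h in hexamer_table
    ]
    if not ratios:
        return 0.0
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# logistic ORF model
# ---------------------------------------------------------------------------

class OrfLogitModel:
    """Logistic combination of ORF length, ORF coverage, Fickett and
    hexamer scores, trained on labelled sequences.

    Stands in for an externally trained coding-potential predictor; the
    probability of *coding* is thresholded at 0.5 by default.
    """

    def __init__(self, hexamer_table: Mapping[str, Tuple[float, float]]) -> None:
        self.hexamer_table = hexamer_table
        self._model = None

    def _features(self, seqs: Sequence[str]) -> np.ndarray:
        rows = []
        for seq in seqs:
            _s, _e, orf_len = longest_orf(seq)
            rows.append(
                [
                    math.log1p(orf_len),
                    orf_len / max(len(seq), 1),
                    fickett_score(seq),
                    hexamer_score(seq, self.hexamer_table),
                ]
            )
        return np.asarray(rows)

    def fit(self, coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]) -> "OrfLogitModel":
        from sklearn.linear_model import LogisticRegression

        X = self._features(list(coding_seqs) + list(noncoding_seqs))
        y = np.r_[np.ones(len(coding_seqs)), np.zeros(len(noncoding_seqs))]
        self._model = LogisticRegression(max_iter=1000).fit(X, y)
        return self

    def score(self, seq: str) -> float:
        """Probability the sequence is coding."""
        if self._model is None:
            raise RuntimeError("OrfLogitModel used before fit()")
        return float(self._model.predict_proba(self._features([seq]))[0, 1])


# ---------------------------------------------------------------------------
# consensus + expression
# ---------------------------------------------------------------------------

def consensus_call(
    verdicts_by_tx: Mapping[str, Sequence[CodingPotentialVerdict]],
    domain_hits: Mapping[str, float],
    config: PipelineConfig,
    sources: Optional[Set[str]] = None,
) -> Set[str]:
    """Transcripts called noncoding by ALL enabled sources and carrying no
    protein-domain hit below the E-value cutoff.

    ``domain_hits`` maps transcript -> best (minimum) E-value. When
    ``sources`` is None the enabled set is the union of sources seen.
    """
    if sources is None:
        sources = {v.source for vs in verdicts_by_tx.values() for v in vs}
    noncoding: Set[str] = set()
    for tx_id, verdicts in verdicts_by_tx.items():
        by_source = {v.source: v for v in verdicts}
        for source in sources:
            if source not in by_source:
                raise ValueError(f"transcript {tx_id} missing a verdict from source {source!r}")
        if all(by_source[s].call == "noncoding" for s in sources):
            evalue = domain_hits.get(tx_id)
            if evalue is None or not evalue < config.domain_evalue_max:
                noncoding.add(tx_id)
    return noncoding


def fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """FPKM(f, s) = count * 1e9 / (library_size(s) * length(f)), with
    library size taken as the column sum of the count matrix."""
    if counts.unit != "count":
        raise ValueError("fpkm() expects a count matrix")
    lib = counts.values.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    length_vec = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    if np.any(length_vec <= 0):
        raise ValueError("non-positive feature length")
    values = counts.values * 1e9 / (lib[None, :] * length_vec[:, None])
    return ExpressionMatrix(
        counts.feature_ids, counts.sample_ids, values, unit="fpkm", design=counts.design
    )


def filter_expression(fpkm_matrix: ExpressionMatrix, config: PipelineConfig) -> List[str]:
    """Feature ids with FPKM >= floor in at least one sample (inclusive)."""
    if fpkm_matrix.unit != "fpkm":
        raise ValueError("filter_expression() expects an FPKM matrix")
    keep_mask = (fpkm_matrix.values >= config.fpkm_floor).any(axis=1)
    return [f for f, keep in zip(fpkm_matrix.feature_ids, keep_mask) if keep]


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_lnc_pipeline(
    txs: Sequence[TranscriptModel],
    seqs: Sequence[SequenceRecord],
    counts: ExpressionMatrix,
    verdicts: Optional[Mapping[str, Sequence[CodingPotentialVerdict]]],
    domain_hits: Mapping[str, float],
    config: PipelineConfig,
    orf_logit: Optional[OrfLogitModel] = None,
    hexamer_table: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> List[LncCandidate]:
    """Run the five-stage cascade, returning one audit record per input
    transcript. Stages after the first failure are left unevaluated.

    When ``verdicts`` is empty/None the in-repo scorers (fickett, hexamer,
    orf_logit) are computed; this requires ``orf_logit`` and
    ``hexamer_table`` (or they are trained on internally simulated labelled
    sequences seeded from the config).
    """
    seq_by_id = {s.id: s.seq for s in seqs}
    tx_by_id = {t.transcript_id: t for t in txs}

    if not verdicts:
        if orf_logit is None or hexamer_table is None:
            orf_logit, hexamer_table = _default_scorers(config)
        verdicts = {}
        for tx_id, seq in seq_by_id.items():
            if tx_id not in tx_by_id:
                continue
            fick = fickett_score(seq)
            hexa = hexamer_score(seq, hexamer_table)
            logit = orf_logit.score(seq)
            verdicts[tx_id] = [
                CodingPotentialVerdict(
                    tx_id, "fickett", fick,
                    "coding" if fick >= FICKETT_CODING_CUTOFF else "noncoding"),
                CodingPotentialVerdict(
                    tx_id, "hexamer", hexa,
                    "coding" if hexa >= HEXAMER_CODING_CUTOFF else "noncoding"),
                CodingPotentialVerdict(
                    tx_id, "orf_logit", logit,
                    "coding" if logit >= ORF_LOGIT_CODING_CUTOFF else "noncoding"),
            ]

    # stage 3+4 evaluated jointly for the transcripts that get there
    survivors_12 = {
        t.transcript_id
        for t in filter_structure(filter_class_code(txs, config), config)
    }
    stage3_verdicts = {
        tx: vs for tx, vs in verdicts.items() if tx in survivors_12
    }
    sources = {v.source for vs in verdicts.values() for v in vs} or None
    noncoding_no_domain = consensus_call(stage3_verdicts, domain_hits, config, sources=sources)
    # split consensus vs domain for the audit trail
    consensus_only = consensus_call(stage3_verdicts, {}, config, sources=sources)

    fpkm_mat = fpkm(counts, {t.transcript_id: t.spliced_length for t in txs
                             if t.transcript_id in counts._findex})
    expressed = set(filter_expression(fpkm_mat, config))

    out: List[LncCandidate] = []
    for t in txs:
        tx_id = t.transcript_id
        stages: Dict[str, Optional[bool]] = {s: None for s in LncCandidate.STAGES}
        stages["class_code"] = t.class_code is not None and t.class_code in config.class_codes_kept
        if stages["class_code"]:
            stages["structure"] = (
                t.n_exons >= config.min_exons and t.spliced_length >= config.min_tx_length
            )
            if stages["structure"]:
                stages["consensus"] = tx_id in consensus_only
                if stages["consensus"]:
                    evalue = domain_hits.get(tx_id)
                    stages["domain"] = evalue is None or not evalue < config.domain_evalue_max
                    if stages["domain"]:
                        stages["expression"] = tx_id in expressed
        final = all(stages[s] is True for s in LncCandidate.STAGES)
        if final:
            assert tx_id in noncoding_no_domain
        out.append(LncCandidate(tx_id, stages, final))
    return out


def _default_scorers(config: PipelineConfig):
    """Train the in-repo scorers on internally simulated labelled sequences."""
    from . import simulate

    rng = np.random.default_rng(config.rng_seed + 987654321)
    coding = [simulate.random_coding_sequence(rng) for _ in range(300)]
    noncoding = [simulate.random_noncoding_sequence(rng) for _ in range(300)]
    table = train_hexamer_table(coding[:150], noncoding[:150])
    model = OrfLogitModel(table).fit(coding[150:], noncoding[150:])
    return model, table
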