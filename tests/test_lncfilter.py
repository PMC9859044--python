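import itertools
import math
import re

import numpy as np
import pytest

from cernanet import lncfilter
from cernanet.config import PipelineConfig
from cernanet.formats_io import ExpressionMatrix, SequenceRecord, TranscriptModel
from cernanet.lncfilter import (
    CodingPotentialVerdict,
    consensus_call,
    fickett_score,
    filter_class_code,
    filter_expression,
    filter_structure,
    fpkm,
    hexamer_score,
    longest_orf,
    train_hexamer_table,
)


def _tx(tx_id, n_exons=2, length=300, class_code="u"):
    per = length // n_exons
    exons, pos = [], 1
    for i in range(n_exons):
        size = per if i < n_exons - 1 else length - per * (n_exons - 1)
        exons.append((pos, pos + size - 1))
        pos += size + 50
    return TranscriptModel(tx_id, tx_id + ".g", "chr1", "+", exons, class_code=class_code)


# ---------------------------------------------------------------------------
# class-code / structure filters
# ---------------------------------------------------------------------------

def test_filter_class_code_keeps_iux(config):
    txs = [_tx(f"t{i}", class_code=c) for i, c in enumerate(["u", "i", "x", "=", "c"])]
    kept = filter_class_code(txs, config)
    assert {t.class_code for t in kept} == {"u", "i", "x"}
    assert len(kept) == 3


def test_filter_class_code_drops_absent(config):
    txs = [_tx("t0", class_code="u")]
    txs[0].class_code = None
    assert filter_class_code(txs, config) == []


def test_filter_class_code_empty(config):
    assert filter_class_code([], config) == []
    assert filter_class_code([_tx("t", class_code="=")], config) == []


@pytest.mark.parametrize(
    "n_exons,length,kept",
    [(2, 201, True), (2, 200, False), (1, 5000, False), (3, 600, True)],
)
def test_filter_structure_boundaries(config, n_exons, length, kept):
    txs = [_tx("t", n_exons=n_exons, length=length)]
    assert bool(filter_structure(txs, config)) is kept


# ---------------------------------------------------------------------------
# longest ORF
# ---------------------------------------------------------------------------

def test_longest_orf_single_codon():
    assert longest_orf("ATGAAATAA") == (1, 9, 9)


def test_longest_orf_no_atg():
    assert longest_orf("CCCCCCCCCCCC") == (0, 0, 0)


def test_longest_orf_picks_longer():
    short = "ATG" + "AAA" * 8 + "TAA"  # 30 nt
    long = "ATG" + "GGG" * 18 + "TGA"  # 60 nt
    seq = short + "C" + long  # frame shift separates them
    assert longest_orf(seq)[2] == 60


def _orf_oracle(seq):
    """Brute force: regex over each frame."""
    best = 0
    for frame in range(3):
        framed = seq[frame:]
        codons = [framed[i : i + 3] for i in range(0, len(framed) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                for j in range(i + 1, len(codons)):
                    if codons[j] in ("TAA", "TAG", "TGA"):
                        best = max(best, (j - i + 1) * 3)
                        i = j
                        break
                else:
                    break
            i += 1
    return best


def test_longest_orf_matches_bruteforce(rng):
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 400))))
        assert longest_orf(seq)[2] == _orf_oracle(seq), seq


# ---------------------------------------------------------------------------
# Fickett
# ---------------------------------------------------------------------------

def _fickett_oracle(seq):
    """Independent table evaluation (direct transliteration of TESTCODE)."""
    pos_prob = lncfilter._POSITION_PROB
    pos_w = lncfilter._POSITION_WEIGHT
    pos_para = lncfilter._POSITION_PARA
    con_prob = lncfilter._CONTENT_PROB
    con_w = lncfilter._CONTENT_WEIGHT
    con_para = lncfilter._CONTENT_PARA
    total = 0.0
    for b in "ACGT":
        c = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == b:
                c[i % 3] += 1
        position = max(c) / (min(c) + 1)
        content = sum(c) / len(seq)
        pi = next(i for i, cut in enumerate(pos_para) if position >= cut)
        ci = next((i for i, cut in enumerate(con_para) if content >= cut), len(con_para) - 1)
        total += pos_prob[b][pi] * pos_w[b] + con_prob[b][ci] * con_w[b]
    return total


def test_fickett_degenerate_periodic_input():
    seq = "ACGT" * 100
    assert fickett_score(seq) == pytest.approx(_fickett_oracle(seq), abs=1e-12)


def test_fickett_random_sequences_match_oracle(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert fickett_score(seq) == pytest.approx(_fickett_oracle(seq), abs=1e-12)


def test_fickett_scale_invariance(rng):
    seq = "".join(rng.choice(list("ACGT"), size=120))
    tripled = seq * 3  # length multiple of 3 keeps frame composition identical
    assert fickett_score(tripled) == pytest.approx(fickett_score(tripled * 2), abs=1e-12)


def test_fickett_separates_coding_from_random(labelled_sequences):
    coding, noncoding = labelled_sequences
    mean_c = np.mean([fickett_score(s) for s in coding])
    mean_n = np.mean([fickett_score(s) for s in noncoding])
    assert mean_c > mean_n


# ---------------------------------------------------------------------------
# hexamer
# ---------------------------------------------------------------------------

def test_hexamer_identical_frequencies_scores_zero(rng):
    table = {h: (1e-4, 1e-4) for h in ("".join(p) for p in itertools.product("ACGT", repeat=6))}
    seq = "".join(rng.choice(list("ACGT"), size=200))
    assert hexamer_score(seq, table) == 0.0


def test_hexamer_single_enriched_hexamer():
    h = "ATGATG"  # invariant under the in-frame step
    table = {k: (1e-4, 1e-4) for k in ("".join(p) for p in itertools.product("ACGT", repeat=6))}
    table[h] = (8e-4, 1e-4)
    assert hexamer_score(h * 10, table) == pytest.approx(math.log(8.0))


def test_hexamer_short_sequence_scores_zero():
    assert hexamer_score("ACGTA", {}) == 0.0


def test_hexamer_auroc_above_090(labelled_sequences):
    from sklearn.metrics import roc_auc_score

    coding, noncoding = labelled_sequences
    table = train_hexamer_table(coding[:100], noncoding[:100])
    scores = [hexamer_score(s, table) for s in coding[100:]] + [
        hexamer_score(s, table) for s in noncoding[100:]
    ]
    labels = [1] * len(coding[100:]) + [0] * len(noncoding[100:])
    assert roc_auc_score(labels, scores) > 0.9


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _verdicts(tx, calls):
    return [
        CodingPotentialVerdict(tx, f"src{i}", 0.0, call) for i, call in enumerate(calls)
    ]


def test_consensus_all_noncoding_no_domain(config):
    v = {"t1": _verdicts("t1", ["noncoding"] * 4)}
    assert consensus_call(v, {}, config) == {"t1"}


def test_consensus_domain_hit_discards(config):
    v = {"t1": _verdicts("t1", ["noncoding"] * 4)}
    assert consensus_call(v, {"t1": 1e-6}, config) == set()
    # at exactly the cutoff the hit does NOT discard (strict <)
    assert consensus_call(v, {"t1": 1e-5}, config) == {"t1"}


def test_consensus_requires_unanimity(config):
    v = {"t1": _verdicts("t1", ["noncoding"] * 3 + ["coding"])}
    assert consensus_call(v, {}, config) == set()


def test_consensus_missing_verdict_names_source(config):
    v = {
        "t1": _verdicts("t1", ["noncoding"] * 4),
        "t2": _verdicts("t2", ["noncoding"] * 3),
    }
    with pytest.raises(ValueError, match="src3"):
        consensus_call(v, {}, config)


def test_consensus_equals_bruteforce_intersection(config, rng):
    """Random verdicts: consensus == intersection of per-source noncoding
    sets minus the domain-hit set."""
    sources = ["a", "b", "c"]
    txs = [f"t{i}" for i in range(30)]
    verdicts = {
        tx: [
            CodingPotentialVerdict(
                tx, s, 0.0, "noncoding" if rng.random() < 0.7 else "coding"
            )
            for s in sources
        ]
        for tx in txs
    }
    domain_hits = {tx: 10.0 ** -rng.integers(3, 8) for tx in txs if rng.random() < 0.3}

    per_source = {
        s: {tx for tx in txs if next(v for v in verdicts[tx] if v.source == s).call == "noncoding"}
        for s in sources
    }
    oracle = set.intersection(*per_source.values()) - {
        tx for tx, e in domain_hits.items() if e < config.domain_evalue_max
    }
    assert consensus_call(verdicts, domain_hits, config) == oracle


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def test_fpkm_formula():
    # library = 1e6 reads, feature of 1000 nt with 10 counts -> FPKM 10
    m = ExpressionMatrix(
        ["f1", "filler"], ["s1"], np.array([[10.0], [999_990.0]]),
        unit="count", design={"s1": "A"},
    )
    out = fpkm(m, {"f1": 1000, "filler": 500})
    assert out.row("f1")[0] == pytest.approx(10.0)
    assert out.unit == "fpkm"


def test_fpkm_zero_library_errors():
    m = ExpressionMatrix(["f"], ["s"], np.array([[0.0]]), unit="count", design={"s": "A"})
    with pytest.raises(ValueError, match="library"):
        fpkm(m, {"f": 100})


def test_filter_expression_inclusive_boundary(config):
    values = np.array([[0.1, 0.0], [0.0999, 0.0999], [0.0, 0.0]])
    m = ExpressionMatrix(["at", "below", "zero"], ["s1", "s2"], values, unit="fpkm",
                         design={"s1": "A", "s2": "A"})
    assert filter_expression(m, config) == ["at"]


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_scorers(labelled_sequences):
    coding, noncoding = labelled_sequences
    table = train_hexamer_table(coding[:100], noncoding[:100])
    model = lncfilter.OrfLogitModel(table).fit(coding[100:], noncoding[100:])
    return model, table


def _cascade_inputs(rng, n=6):
    txs = [
        _tx("pass", n_exons=2, length=300, class_code="u"),
        _tx("badcode", n_exons=2, length=300, class_code="="),
        _tx("badstruct", n_exons=1, length=300, class_code="u"),
    ]
    seqs = [
        SequenceRecord("pass", "".join(rng.choice(list("ACGT"), size=300))),
        SequenceRecord("badcode", "".join(rng.choice(list("ACGT"), size=300))),
        SequenceRecord("badstruct", "".join(rng.choice(list("ACGT"), size=300))),
    ]
    counts = ExpressionMatrix(
        ["pass", "badcode", "badstruct"],
        ["s1", "s2"],
        np.array([[50.0, 60.0], [50.0, 60.0], [50.0, 60.0]]),
        unit="count",
        design={"s1": "A", "s2": "B"},
    )
    return txs, seqs, counts


def test_cascade_short_circuit(config, rng, trained_scorers):
    model, table = trained_scorers
    txs, seqs, counts = _cascade_inputs(rng)
    verdicts = {
        t.transcript_id: _verdicts(t.transcript_id, ["noncoding"] * 2) for t in txs
    }
    out = {c.transcript_id: c for c in lncfilter.run_lnc_pipeline(
        txs, seqs, counts, verdicts, {}, config, orf_logit=model, hexamer_table=table)}
    assert out["badcode"].passed_stages["class_code"] is False
    assert out["badcode"].passed_stages["structure"] is None  # not assessed
    assert out["badstruct"].passed_stages["structure"] is False
    assert out["badstruct"].passed_stages["consensus"] is None
    assert out["pass"].final is True


def test_cascade_stage12_order_insensitive(config):
    """Stages 1-2 are pure predicates: applying them in either order gives
    the same surviving set."""
    txs = [
        _tx(f"t{i}", n_exons=ne, length=ln, class_code=cc)
        for i, (ne, ln, cc) in enumerate(
            itertools.product([1, 2], [150, 400], ["u", "=", "i"])
        )
    ]
    a = {t.transcript_id for t in filter_structure(filter_class_code(txs, config), config)}
    b = {t.transcript_id for t in filter_class_code(filter_structure(txs, config), config)}
    assert a == b


def test_cascade_self_computes_scores_when_no_verdicts(config, rng, trained_scorers):
    model, table = trained_scorers
    txs, seqs, counts = _cascade_inputs(rng)
    out = lncfilter.run_lnc_pipeline(
        txs, seqs, counts, None, {}, config, orf_logit=model, hexamer_table=table
    )
    assert len(out) == 3
    stages = {c.transcript_id: c.passed_stages for c in out}
    assert stages["pass"]["consensus"] in (True, False)  # in-repo scorers ran
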