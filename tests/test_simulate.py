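import numpy as np
import pytest

from cernanet import simulate
from cernanet.formats_io import ExpressionMatrix, SequenceRecord
from cernanet.lncfilter import longest_orf
from cernanet.mirtarget import revcomp, seed_sites
from cernanet.simulate import (
    SimulationParams,
    plant_seed_sites,
    plant_trans_correlation,
    simulate_counts,
    simulate_transcripts,
)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_simulate_counts_deterministic():
    p = SimulationParams(seed=11, n_genes=50)
    m1, t1 = simulate_counts(p)
    m2, t2 = simulate_counts(p)
    assert m1 == m2
    assert t1.de_features == t2.de_features


def test_simulate_counts_null_configuration():
    p = SimulationParams(seed=3, n_genes=100, frac_de=0.0)
    matrix, truth = simulate_counts(p)
    assert truth.de_features == {}
    a = matrix.values[:, matrix.group_columns("SL")].mean()
    b = matrix.values[:, matrix.group_columns("L")].mean()
    assert abs(a - b) / b < 0.15  # equal in expectation


def test_planted_fold_monte_carlo():
    """A feature planted up with log2fc=2 shows mean(A)/mean(B) ~ 4.

    10k NB draws per group at a large baseline; 3-SE tolerance via the
    delta method for the ratio of means.
    """
    p = SimulationParams(seed=5, n_per_group=10_000, n_genes=1, nb_dispersion=0.1)
    matrix, truth = simulate_counts(
        p, planted={"G0001": (2.0, "up")}, baseline_means={"G0001": 500.0}
    )
    a = matrix.values[0, matrix.group_columns("SL")]
    b = matrix.values[0, matrix.group_columns("L")]
    ratio = a.mean() / b.mean()
    se = ratio * np.sqrt(
        a.var() / (len(a) * a.mean() ** 2) + b.var() / (len(b) * b.mean() ** 2)
    )
    assert abs(ratio - 4.0) <= 3 * se


def test_nb_variance_matches_parameterization():
    """var = mu + phi * mu^2 at large sample size."""
    gen = np.random.default_rng(0)
    mu, phi = 200.0, 0.1
    draws = simulate._nb_draw(gen, np.full(200_000, mu), phi)
    expected = mu + phi * mu * mu
    assert abs(draws.var() - expected) / expected < 0.05
    assert abs(draws.mean() - mu) / mu < 0.02


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def test_simulate_transcripts_deterministic_bytes(tmp_path):
    from cernanet.formats_io import write_fasta

    p = SimulationParams(seed=9, n_lnc_candidates=20)
    for run in ("x", "y"):
        _, seqs, _ = simulate_transcripts(p)
        write_fasta(seqs, tmp_path / f"{run}.fa")
    assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()


def test_coding_transcripts_have_long_orf():
    p = SimulationParams(seed=2, n_lnc_candidates=40)
    _, seqs, truth = simulate_transcripts(p)
    by_id = {s.id: s.seq for s in seqs}
    assert truth.coding_tx
    for tx in truth.coding_tx:
        assert longest_orf(by_id[tx])[2] >= simulate.MIN_CODING_ORF


def test_noncoding_transcripts_have_short_orf():
    p = SimulationParams(seed=2, n_lnc_candidates=40)
    _, seqs, truth = simulate_transcripts(p)
    by_id = {s.id: s.seq for s in seqs}
    for tx in truth.noncoding_tx:
        assert longest_orf(by_id[tx])[2] < simulate.MAX_NONCODING_ORF


def test_transcript_pool_spans_filters():
    """Single-exon and short transcripts are generated and recorded as
    noncoding truth, i.e. known structure-filter failures."""
    p = SimulationParams(seed=4, n_lnc_candidates=60)
    models, _, truth = simulate_transcripts(p)
    single_exon = [m for m in models if m.n_exons == 1]
    short = [m for m in models if m.spliced_length <= 200]
    assert single_exon and short
    for m in single_exon + short:
        assert m.transcript_id in truth.noncoding_tx
    codes = {m.class_code for m in models}
    assert {"u", "i", "x"} <= codes
    assert codes & {"=", "c"}


# ---------------------------------------------------------------------------
# seed-site planting
# ---------------------------------------------------------------------------

def _mk_mirnas(gen, n):
    return simulate._random_mirnas(gen, n)


def _naive_site_scan(mirna, target):
    """Independent brute-force scan: try every offset, classify by string
    comparison against explicitly constructed site strings."""
    from cernanet.mirtarget import site_string

    found = []
    for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        s = site_string(mirna.seq, stype)
        for i in range(len(target.seq) - len(s) + 1):
            if target.seq[i : i + len(s)] == s:
                found.append((stype, i + 1))
    return found


def test_plant_single_8mer_found_exactly_once(rng):
    mirnas = _mk_mirnas(rng, 3)
    targets = [SequenceRecord(f"U{i}", simulate._uniform_seq(rng, 300), "utr3") for i in range(4)]
    planted, truth = plant_seed_sites(targets, mirnas, [(mirnas[0].id, "U0", "8mer")], rng=rng)
    assert len(truth.planted_seed_sites) == 1
    mir_id, target_id, stype, pos = truth.planted_seed_sites[0]
    t0 = next(t for t in planted if t.id == "U0")
    sites = seed_sites(mirnas[0], t0)
    assert len(sites) == 1
    assert sites[0].site_type == "8mer"
    assert sites[0].position == pos


def test_empty_plan_scrubs_background(rng):
    mirnas = _mk_mirnas(rng, 5)
    targets = [SequenceRecord(f"U{i}", simulate._uniform_seq(rng, 400), "utr3") for i in range(10)]
    planted, _ = plant_seed_sites(targets, mirnas, [], rng=rng)
    for t in planted:
        for m in mirnas:
            assert seed_sites(m, t) == []


def test_planted_6mer_is_exactly_6mer(rng):
    """Type fidelity cross-checked with an independent brute-force scan."""
    mirnas = _mk_mirnas(rng, 2)
    targets = [SequenceRecord("U0", simulate._uniform_seq(rng, 300), "utr3")]
    planted, truth = plant_seed_sites(targets, mirnas, [(mirnas[0].id, "U0", "6mer")], rng=rng)
    _, _, stype, pos = truth.planted_seed_sites[0]
    assert stype == "6mer"
    sites = seed_sites(mirnas[0], planted[0])
    assert [(s.site_type, s.position) for s in sites] == [("6mer", pos)]
    assert _naive_site_scan(mirnas[0], planted[0]) == [("6mer", pos)]


def test_plant_target_too_short_errors(rng):
    mirnas = _mk_mirnas(rng, 1)
    targets = [SequenceRecord("U0", "ACGTACG", "utr3")]
    with pytest.raises(ValueError, match="too short"):
        plant_seed_sites(targets, mirnas, [(mirnas[0].id, "U0", "8mer")], rng=rng)


def test_plant_unknown_target_errors(rng):
    mirnas = _mk_mirnas(rng, 1)
    with pytest.raises(ValueError, match="unknown targets"):
        plant_seed_sites([], mirnas, [(mirnas[0].id, "NOPE", "8mer")], rng=rng)


# ---------------------------------------------------------------------------
# trans-correlation planting
# ---------------------------------------------------------------------------

def _expr_with(rows, design=None):
    features = sorted(rows)
    values = np.array([rows[f] for f in features], dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(features, samples, values, design=design or {s: "g" for s in samples})


def test_trans_rho_one_exact():
    from cernanet.lnctarget import spearman_rho

    x = np.array([3, 9, 1, 14, 6, 11, 2, 8, 13, 5, 10, 4], dtype=float)
    expr = _expr_with({"lnc": x, "gene": np.arange(12.0) + 1})
    out, _ = plant_trans_correlation(expr, [("lnc", "gene", 1.0)], seed=0)
    assert spearman_rho(out.row("lnc"), out.row("gene")) == pytest.approx(1.0)


def test_trans_rho_calibration_monte_carlo():
    """target_rho=0.9, n=12: mean sample rho within [0.85, 0.95] over 1000
    replicates of the copula planting."""
    from cernanet.lnctarget import spearman_rho

    gen = np.random.default_rng(42)
    rhos = []
    for _ in range(1000):
        x = gen.poisson(200, size=12).astype(float)
        g = gen.poisson(200, size=12).astype(float)
        expr = _expr_with({"lnc": x, "gene": g})
        out, _ = plant_trans_correlation(
            expr, [("lnc", "gene", 0.9)], rng=gen
        )
        rhos.append(spearman_rho(out.row("lnc"), out.row("gene")))
    assert 0.85 <= np.mean(rhos) <= 0.95


def test_unplanted_pairs_are_null():
    """Independent rows: mean rho ~ 0 and |rho| > 0.8 essentially never."""
    from cernanet.lnctarget import spearman_rho

    gen = np.random.default_rng(7)
    rhos = []
    for _ in range(1000):
        x = gen.poisson(200, size=12).astype(float)
        y = gen.poisson(200, size=12).astype(float)
        rhos.append(spearman_rho(x, y))
    rhos = np.array(rhos)
    assert abs(rhos.mean()) < 0.05
    rate = np.mean(np.abs(rhos) > 0.8)
    se = np.sqrt(0.05 * 0.95 / len(rhos))
    assert rate <= 0.05 + 3 * se


def test_trans_unknown_feature_errors():
    expr = _expr_with({"a": np.arange(12.0)})
    with pytest.raises(ValueError, match="unknown"):
        plant_trans_correlation(expr, [("a", "missing", 0.9)], seed=0)


def test_preserve_groups_keeps_fold_change():
    gen = np.random.default_rng(1)
    design = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
    gene = np.r_[gen.poisson(800, 6), gen.poisson(200, 6)].astype(float)
    lnc = np.r_[gen.poisson(800, 6), gen.poisson(200, 6)].astype(float)
    expr = _expr_with({"gene": gene, "lnc": lnc}, design=design)
    out, _ = plant_trans_correlation(
        expr, [("lnc", "gene", 0.9)], rng=gen, preserve_groups=True
    )
    new = out.row("gene")
    assert new[:6].mean() / new[6:].mean() == pytest.approx(
        np.sort(gene + np.arange(12))[6:].mean() / np.sort(gene + np.arange(12))[:6].mean(),
        rel=0.2,
    )
    assert new[:6].mean() > 2.5 * new[6:].mean()


# ---------------------------------------------------------------------------
# dataset-level invariants
# ---------------------------------------------------------------------------

def test_dataset_reproducible(tmp_path, small_dataset):
    ds2 = simulate.simulate_dataset(SimulationParams(seed=7))
    p1 = small_dataset.write(tmp_path / "a")
    p2 = ds2.write(tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_truth_triangles_consistent(small_dataset):
    """Each planted triangle's three pairwise relations appear in the
    respective planted lists."""
    truth = small_dataset.truth
    site_pairs = {(m, t) for m, t, _, _ in truth.planted_seed_sites}
    cis_pairs = {(l, g) for l, g, _ in truth.planted_cis_pairs}
    trans_pairs = {(l, g) for l, g, _ in truth.planted_trans_pairs}
    assert truth.planted_triangles
    for lnc, mir, gene in truth.planted_triangles:
        assert (mir, gene) in site_pairs
        assert (mir, lnc) in site_pairs
        assert (lnc, gene) in cis_pairs
        assert (lnc, gene) in trans_pairs


def test_truth_references_generated_features(small_dataset):
    ds = small_dataset
    lnc_ids = {s.id for s in ds.lnc_seqs}
    gene_ids = set(ds.gene_counts.feature_ids)
    mir_ids = {m.id for m in ds.mirna_seqs}
    for lnc, mir, gene in ds.truth.planted_triangles:
        assert lnc in lnc_ids and mir in mir_ids and gene in gene_ids
    for lnc, gene, d in ds.truth.planted_cis_pairs:
        assert d <= 100_000
    for _, _, rho in ds.truth.planted_trans_pairs:
        assert 0.8 < rho <= 1


def test_truth_json_round_trip(small_dataset):
    text = small_dataset.truth.to_json()
    back = simulate.SimulationTruth.from_json(text)
    assert back.to_json() == text
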