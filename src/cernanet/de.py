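"""Two-group differential-expression screen for count matrices.

Normalization is trimmed-mean-of-M-values (TMM); testing is a conditional
two-sided exact negative-binomial test with a pooled common dispersion,
applied identically to mRNA, miRNA and lncRNA matrices; significance is
Benjamini-Hochberg FDR < 0.05 combined with |fold change| >= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import PipelineConfig
from .formats_io import ExpressionMatrix

__all__ = [
    "DEResult",
    "tmm_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "screen_de",
]

DISPERSION_FLOOR = 1e-6
_BINOMIAL_PHI = 1e-8  # below this the conditional NB test degenerates to binomial


@dataclass
class DEResult:
    feature_id: str
    log2fc: float
    p_value: float
    fdr: float
    call: str  # "up" | "down" | "ns"


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: np.ndarray,
    ref_sample: Optional[int] = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values scaling factors, one per sample (column).

    M-values are trimmed 30% on each side, A-values 5%, remaining M-values
    averaged with inverse asymptotic-variance weights. Factors multiply
    library sizes and are rescaled to geometric mean 1. The reference
    sample defaults to the one whose 0.75 count quantile (library-scaled)
    is closest to the mean across samples.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("tmm_factors needs a features x samples matrix with >=2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("all-zero sample column")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
        ref_sample = int(np.argmin(np.abs(f75 - f75.mean())))

    n_samples = counts.shape[1]
    factors = np.ones(n_samples)
    yr = counts[:, ref_sample]
    nr = lib[ref_sample]
    for j in range(n_samples):
        if j == ref_sample:
            continue
        y = counts[:, j]
        n = lib[j]
        ok = (y > 0) & (yr > 0)
        if not np.any(ok):
            warnings.warn(f"sample {j}: no usable features for TMM; factor set to 1")
            continue
        yj, yrj = y[ok], yr[ok]
        m = np.log2((yj / n) / (yrj / nr))
        a = 0.5 * np.log2((yj / n) * (yrj / nr))
        w = (n - yj) / (n * yj) + (nr - yrj) / (nr * yrj)
        if np.max(np.abs(m)) < 1e-6:
            continue
        k = len(m)
        lo_l = np.floor(k * logratio_trim) + 1
        hi_l = k + 1 - lo_l
        lo_s = np.floor(k * sum_trim) + 1
        hi_s = k + 1 - lo_s
        rank_m = _rank(m)
        rank_a = _rank(a)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if not np.any(keep) or w[keep].sum() == 0:
            warnings.warn(f"sample {j}: all features trimmed; TMM factor set to 1")
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _rank(x: np.ndarray) -> np.ndarray:
    """Mid-ranks, 1-based."""
    from scipy.stats import rankdata

    return rankdata(x)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: np.ndarray,
    group_a_cols: Sequence[int],
    group_b_cols: Sequence[int],
    effective_lib: Optional[np.ndarray] = None,
) -> float:
    """Pooled method-of-moments common dispersion on normalized counts.

    Under var = mu + phi * mu^2, a ratio estimator pools (s^2 - m) over
    m^2 across features and both groups. Floored at 1e-6.
    """
    counts = np.asarray(counts, dtype=float)
    if effective_lib is None:
        effective_lib = counts.sum(axis=0)
    scale = np.exp(np.mean(np.log(effective_lib))) / effective_lib
    norm = counts * scale[None, :]
    num = 0.0
    den = 0.0
    for cols in (group_a_cols, group_b_cols):
        sub = norm[:, list(cols)]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += np.sum(v[ok] - m[ok])
        den += np.sum(m[ok] ** 2)
    if den == 0:
        return DISPERSION_FLOOR
    return float(max(DISPERSION_FLOOR, num / den))


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def nb_exact_test(ya: Sequence[float], yb: Sequence[float], phi: float) -> float:
    """Conditional two-sided exact NB test for equal means of two groups.

    ``ya``/``yb`` are counts pre-scaled to a common effective library size
    and rounded. Group sums are conditioned on the total; the conditional
    law (negative-hypergeometric, free of the mean) gives the two tails;
    p doubles the smaller tail, capped at 1. Zero total returns p = 1.
    In the phi -> 0 limit the law is binomial(total, n_a / (n_a + n_b)).
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    sa = int(round(ya.sum()))
    sb = int(round(yb.sum()))
    t = sa + sb
    if t == 0:
        return 1.0
    na, nb = len(ya), len(yb)
    a = np.arange(t + 1)
    if phi < _BINOMIAL_PHI:
        logp = (
            gammaln(t + 1)
            - gammaln(a + 1)
            - gammaln(t - a + 1)
            + a * np.log(na / (na + nb))
            + (t - a) * np.log(nb / (na + nb))
        )
    else:
        ra = na / phi
        rb = nb / phi
        logp = (
            gammaln(a + ra)
            - gammaln(a + 1)
            + gammaln(t - a + rb)
            - gammaln(t - a + 1)
        )
    logp = logp - logsumexp(logp)
    pmf = np.exp(logp)
    lower = pmf[: sa + 1].sum()
    upper = pmf[sa:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values:
    fdr_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def screen_de(
    counts: ExpressionMatrix,
    config: PipelineConfig,
    numerator_group: Optional[str] = None,
) -> List[DEResult]:
    """Full two-group screen: TMM -> common dispersion -> per-feature exact
    test -> BH -> fold-change/FDR call.

    log2fc is log2 of normalized group means (pseudocount 0.5) with
    ``numerator_group`` on top (defaults to the first group label in
    design order). Features with all-zero counts are excluded before
    testing and absent from the result.
    """
    if counts.unit != "count":
        raise ValueError("screen_de expects a count matrix")
    labels = list(dict.fromkeys(counts.design[s] for s in counts.sample_ids))
    if len(labels) != 2:
        raise ValueError(f"DE screen needs exactly 2 group labels, got {labels}")
    if numerator_group is None:
        numerator_group = labels[0]
    if numerator_group not in labels:
        raise ValueError(f"numerator group {numerator_group!r} not in design {labels}")
    denominator_group = labels[1] if numerator_group == labels[0] else labels[0]

    values = counts.values
    nonzero = values.sum(axis=1) > 0
    features = [f for f, ok in zip(counts.feature_ids, nonzero) if ok]
    values = values[nonzero]
    if not features:
        return []

    lib = counts.values.sum(axis=0)  # library sizes from the full matrix
    factors = tmm_factors(values)
    eff = lib * factors
    scale = np.exp(np.mean(np.log(eff))) / eff
    norm = values * scale[None, :]
    scaled = np.round(norm)

    cols_a = counts.group_columns(numerator_group)
    cols_b = counts.group_columns(denominator_group)
    phi = estimate_dispersion(values, cols_a, cols_b, effective_lib=eff)

    mean_a = norm[:, cols_a].mean(axis=1)
    mean_b = norm[:, cols_b].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    pvals = np.array(
        [nb_exact_test(scaled[i, cols_a], scaled[i, cols_b], phi) for i in range(len(features))]
    )
    fdrs = bh_fdr(pvals)

    lfc_cut = np.log2(config.abs_fc_threshold)
    results = []
    for f, lfc, p, q in zip(features, log2fc, pvals, fdrs):
        if q < config.fdr_threshold and lfc >= lfc_cut:
            call = "up"
        elif q < config.fdr_threshold and lfc <= -lfc_cut:
            call = "down"
        else:
            call = "ns"
        results.append(DEResult(f, float(lfc), float(p), float(q), call))
    return results


def de_sets(results: Sequence[DEResult]) -> Tuple[set, Dict[str, str]]:
    """Convenience: (set of DE feature ids, feature -> direction)."""
    directions = {r.feature_id: r.call for r in results if r.call != "ns"}
    return set(directions), directions
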