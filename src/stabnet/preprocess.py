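"""Expression filtering, TMM normalization and log-CPM transformation.

The preprocessing chain mirrors standard bulk RNA-seq practice for small
designs: a counts-per-million expression floor, trimmed-mean-of-M-values
(TMM) scaling factors computed against a reference sample, a log2-CPM
transform with a pseudo-count, and a variance prefilter applied before
network construction. Optional mean-variance precision weights in the style
of the voom transform are computed for completeness but are not consumed by
any downstream stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, ExpressionMatrix, ValidationError

log = logging.getLogger("stabnet")


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million on raw library sizes (no normalization factors)."""
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValidationError("library size must be positive for CPM")
    return cm.counts / lib * 1e6


def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Drop genes below ``min_cpm`` CPM in fewer than ``min_samples`` samples.

    CPM is computed on raw library sizes (pre-normalization); the threshold
    is inclusive on both counts (CPM >= min_cpm in >= min_samples samples).
    """
    keep = (cpm(cm) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError("expression filter removed all genes")
    return CountMatrix(cm.counts.loc[keep])


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
) -> float:
    """Doubly trimmed, precision-weighted mean of M-values for one sample.

    M = log2 relative expression ratio vs the reference, A = average log2
    abundance; the stated fractions are trimmed from each tail of M and A,
    and remaining M-values are averaged with inverse asymptotic-variance
    (delta-method binomial) weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return np.nan
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    ok = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[ok], a[ok], w[ok]
    if m.size == 0:
        return np.nan
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    return float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_normalize(
    cm: CountMatrix,
    ref: str = "auto",
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The "auto" reference is the sample whose upper-quartile CPM is closest
    to the mean upper-quartile across samples. Samples with zero gene
    overlap with the reference get factor 1 with a warning.
    """
    if cm.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if ref == "auto":
        uq = np.quantile(counts / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref not in cm.sample_ids:
            raise ValidationError(f"reference sample {ref!r} not found")
        ref_idx = int(cm.sample_ids.get_loc(ref))
    factors = np.ones(cm.shape[1])
    for s in range(cm.shape[1]):
        if s == ref_idx:
            continue
        f = _tmm_pair_factor(
            counts[:, s], counts[:, ref_idx], lib[s], lib[ref_idx],
            logratio_trim, sum_trim, a_cutoff,
        )
        if not np.isfinite(f) or f <= 0:
            log.warning(
                "sample %s has no usable overlap with the TMM reference; factor set to 1",
                cm.sample_ids[s],
            )
            f = 1.0
        factors[s] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="norm_factor")


def log_cpm(
    cm: CountMatrix, norm_factors: pd.Series | None = None, prior_count: float = 0.5
) -> ExpressionMatrix:
    """log2 counts-per-million with effective (TMM-scaled) library sizes.

    value = log2((count + p_s) / (lib_size * f + 2 * p_s) * 1e6) where the
    pseudo-count ``p_s = prior_count * lib_size * f / 1e6`` is specified in
    CPM units and scaled to each effective library size, which makes the
    transform exactly invariant to rescaling counts and library sizes
    together (a library of 1e6 reads gets pseudo-count ``prior_count``).
    """
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    prior = prior_count * lib / 1e6
    values = np.log2(
        (cm.counts.to_numpy(dtype=float) + prior)
        / (lib + 2.0 * prior)
        * 1e6
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=cm.gene_ids, columns=cm.sample_ids), prior_count
    )


def voom_weights(
    cm: CountMatrix, norm_factors: pd.Series | None = None, span: float = 0.5
) -> pd.DataFrame:
    """Inverse-variance precision weights from the mean-variance trend.

    A lowess curve of sqrt residual standard deviation against mean log2
    count is fitted across genes and evaluated at each observation's fitted
    log-count; weights are the predicted variance to the -1 power. Exposed
    for completeness; no downstream stage consumes these weights.
    """
    em = log_cpm(cm, norm_factors)
    x = em.values.to_numpy()
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    mean_logcount = x.mean(axis=1) + np.log2(lib).mean() - np.log2(1e6)
    sd = x.std(axis=1, ddof=1)
    fit = lowess(np.sqrt(sd), mean_logcount, frac=span, return_sorted=True)
    fx, fy = fit[:, 0], np.maximum(fit[:, 1], 1e-4)
    # per-observation fitted log2 count
    obs_logcount = x + np.log2(lib)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(obs_logcount, fx, fy)
    weights = pred_sqrt_sd ** -4.0
    return pd.DataFrame(weights, index=cm.gene_ids, columns=cm.sample_ids)


def variance_prefilter(em: ExpressionMatrix, drop_fraction: float = 0.40) -> ExpressionMatrix:
    """Drop the ``drop_fraction`` of genes with lowest variance across samples.

    Exactly floor(drop_fraction * n_genes) genes are removed; ties are broken
    by gene id order (earlier ids dropped first), making the filter stable.
    """
    if not 0 <= drop_fraction < 1:
        raise ValidationError("drop_fraction must be in [0, 1)")
    n_drop = int(np.floor(drop_fraction * em.shape[0]))
    if n_drop == 0:
        return ExpressionMatrix(em.values.copy(), em.prior_count)
    var = em.values.var(axis=1, ddof=1)
    order = np.lexsort((np.arange(em.shape[0]), var.to_numpy()))
    drop = set(em.gene_ids[order[:n_drop]])
    keep = [g for g in em.gene_ids if g not in drop]
    return ExpressionMatrix(em.values.loc[keep], em.prior_count)
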