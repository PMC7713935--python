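"""Negative-binomial differential expression with interaction contrasts.

Each gene is modelled as NB(mean mu_gs, dispersion phi_g) with a log link,
an offset of log effective library size, and a six-cell group-means design
(population x infestation). Contrasts are linear combinations of the six
cell means; each contrast is tested with a likelihood-ratio test against
chi-square(1). Dispersions come from a moment estimator shrunk toward the
across-gene median (see :func:`estimate_dispersions`): a deliberate,
validated simplification relative to empirical-Bayes machinery, since the
inference layer here only requires the NB variance function.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, DesignTable, ValidationError
from .preprocess import log_cpm

log = logging.getLogger("stabnet")

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-6

#: Order of design cells used by group-means contrast vectors.
CELL_ORDER = [
    ("kauai", "control"),
    ("kauai", "day4"),
    ("kauai", "day7"),
    ("mangaia", "control"),
    ("mangaia", "day4"),
    ("mangaia", "day7"),
]

#: Named contrasts over the six cell means (the four within-population
#: infested-vs-control comparisons and the two difference-of-differences
#: interaction contrasts).
NAMED_CONTRASTS = {
    "kauai_day4_vs_control": np.array([-1, 1, 0, 0, 0, 0], dtype=float),
    "kauai_day7_vs_control": np.array([-1, 0, 1, 0, 0, 0], dtype=float),
    "mangaia_day4_vs_control": np.array([0, 0, 0, -1, 1, 0], dtype=float),
    "mangaia_day7_vs_control": np.array([0, 0, 0, -1, 0, 1], dtype=float),
    "interaction_day4": np.array([-1, 1, 0, 1, -1, 0], dtype=float),
    "interaction_day7": np.array([-1, 0, 1, 1, 0, -1], dtype=float),
}


@dataclass
class Dispersions:
    """Per-gene NB dispersions with shrinkage bookkeeping."""

    tagwise: pd.Series
    per_gene: pd.Series
    common: float
    shrinkage_weight: float


def group_means_design(design: DesignTable, sample_ids) -> tuple[np.ndarray, list]:
    """Indicator design matrix (samples x cells) in :data:`CELL_ORDER`."""
    tab = design.table.loc[list(sample_ids)]
    cells = [
        (p, s)
        for (p, s) in itertools.product(design.populations, design.stages)
    ]
    # keep canonical ordering when using default vocabularies
    if set(cells) == set(CELL_ORDER):
        cells = list(CELL_ORDER)
    x = np.zeros((len(tab), len(cells)))
    for j, (pop, stage) in enumerate(cells):
        x[:, j] = ((tab["population"] == pop) & (tab["infestation"] == stage)).to_numpy()
    occupied = x.sum(axis=0) > 0
    return x[:, occupied], [c for c, k in zip(cells, occupied) if k]


def estimate_dispersions(
    cm: CountMatrix,
    design: DesignTable,
    prior_df: float = 10.0,
    norm_factors: pd.Series | None = None,
) -> Dispersions:
    """Moment dispersion estimates shrunk toward the across-gene median.

    Counts are scaled to a common library size; for each design cell the
    within-cell sample variance in excess of the (Poisson) mean contributes
    a moment estimate of phi, pooled across cells with df weights and
    floored at 1e-6. Tagwise values are a convex combination of the gene
    estimate and the common (median) value with weight
    prior_df / (prior_df + residual df) on the common value.
    """
    design = design.reindex(cm.sample_ids)
    y = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    scale = lib.mean() / lib
    ys = y * scale[None, :]

    groups = design.group_labels()
    num = np.zeros(cm.shape[0])
    df_total = 0
    for g in groups.unique():
        idx = np.flatnonzero((groups == g).to_numpy())
        if idx.size < 2:
            continue
        sub = ys[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        cbar = scale[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - cbar * m) / np.where(m > 0, m**2, np.nan)
        phi_g = np.where(np.isfinite(phi_g), phi_g, 0.0)
        num += (idx.size - 1) * phi_g
        df_total += idx.size - 1
    if df_total == 0:
        raise ValidationError("design has zero residual degrees of freedom")
    per_gene = np.maximum(num / df_total, DISPERSION_FLOOR)
    common = float(np.median(per_gene))
    w = prior_df / (prior_df + df_total)
    tagwise = np.maximum(w * common + (1.0 - w) * per_gene, DISPERSION_FLOOR)
    return Dispersions(
        tagwise=pd.Series(tagwise, index=cm.gene_ids, name="dispersion"),
        per_gene=pd.Series(per_gene, index=cm.gene_ids, name="dispersion_raw"),
        common=common,
        shrinkage_weight=float(w),
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB log-likelihood per gene (summed over samples); phi is (G,)."""
    r = 1.0 / phi[:, None]
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + y * np.log(phi[:, None] * mu / (1.0 + phi[:, None] * mu))
        - r * np.log1p(phi[:, None] * mu)
    ).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Fisher-scoring fit of NB GLMs across genes.

    Parameters
    ----------
    y : (G, S) counts; x : (S, P) design; offset : (S,) log effective
    library sizes; phi : (G,) dispersions.

    Returns (beta (G, P), loglik (G,), converged (G,) bool).
    """
    g, s = y.shape
    p = x.shape[1]
    pinv = np.linalg.pinv(x)
    eta0 = np.log(y + 0.5) - offset[None, :]
    beta = eta0 @ pinv.T
    converged = np.zeros(g, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(beta @ x.T + offset[None, :], -60.0, 60.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-300)
        a = np.einsum("sp,gs,sq->gpq", x, w, x, optimize=True) + ridge
        b = np.einsum("sp,gs,gs->gp", x, w, z, optimize=True)
        # cap coefficients so cells with no counts park at the boundary
        new = np.clip(np.linalg.solve(a, b[..., None])[..., 0], -50.0, 50.0)
        step = np.abs(new - beta).max(axis=1)
        beta = new
        newly = step < tol * (1.0 + np.abs(beta).max(axis=1))
        converged |= newly
        if converged.all():
            break
    eta = np.clip(beta @ x.T + offset[None, :], -60.0, 60.0)
    ll = _nb_loglik(y, np.exp(eta), phi)
    return beta, ll, converged


def fit_and_test(
    cm: CountMatrix,
    norm_factors: pd.Series | None,
    design: DesignTable,
    dispersions: Dispersions,
    contrast: np.ndarray,
    contrast_name: str = "contrast",
) -> pd.DataFrame:
    """Likelihood-ratio test of a single group-means contrast per gene.

    The reduced model restricts the fit to the null space of the contrast
    vector. Genes with zero counts in every sample of the cells involved in
    the contrast receive log2FC 0 and p 1; genes whose IRLS fails to
    converge get missing p-values and are excluded from the BH denominator.
    """
    contrast = np.asarray(contrast, dtype=float)
    design = design.reindex(cm.sample_ids)
    x, cells = group_means_design(design, cm.sample_ids)
    if contrast.shape != (x.shape[1],):
        raise ValidationError(
            f"contrast length {contrast.size} != number of design cells {x.shape[1]}"
        )
    if not np.any(contrast):
        raise ValidationError("contrast vector is all zero")

    y = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    offset = np.log(lib)
    phi = dispersions.tagwise.reindex(cm.gene_ids).to_numpy(dtype=float)

    beta_full, ll_full, conv_full = fit_nb_glm(y, x, offset, phi)
    z = scipy.linalg.null_space(contrast[None, :])
    beta_red, ll_red, conv_red = fit_nb_glm(y, x @ z, offset, phi)

    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p_raw = chi2.sf(lrt, df=1)
    log2fc = beta_full @ contrast / LN2

    involved = np.abs(x @ contrast) > 0  # samples in cells touched by the contrast
    degenerate = (y[:, involved].sum(axis=1) == 0)
    log2fc = np.where(degenerate, 0.0, log2fc)
    p_raw = np.where(degenerate, 1.0, p_raw)

    nonconv = ~(conv_full & conv_red) & ~degenerate
    if nonconv.any():
        log.warning("%d gene(s) failed to converge for %s", nonconv.sum(), contrast_name)
    p_raw = np.where(nonconv, np.nan, p_raw)

    out = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "contrast": contrast_name,
            "log2FC": log2fc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(pd.Series(p_raw)).to_numpy(),
            "mean_logcpm": log_cpm(cm, norm_factors).values.mean(axis=1).to_numpy(),
            "converged": ~nonconv,
        }
    ).set_index("gene_id")
    return out


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; missing values propagate."""
    p = pd.Series(np.asarray(p, dtype=float))
    ok = p.notna()
    vals = p[ok].to_numpy()
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = np.full(len(p), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(vals, method="fdr_bh")[1]
    return pd.Series(adj, index=p.index)


def run_contrasts(
    cm: CountMatrix,
    norm_factors: pd.Series | None,
    design: DesignTable,
    dispersions: Dispersions | None = None,
    contrasts: dict | None = None,
    prior_df: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Fit and test every named contrast; returns {name: result table}."""
    if dispersions is None:
        dispersions = estimate_dispersions(cm, design, prior_df, norm_factors)
    if contrasts is None:
        contrasts = NAMED_CONTRASTS
    return {
        name: fit_and_test(cm, norm_factors, design, dispersions, vec, name)
        for name, vec in contrasts.items()
    }


def venn_partition(de_a: pd.DataFrame, de_b: pd.DataFrame, fdr: float = 0.05) -> dict:
    """Two-way DE overlap with the same-direction fraction among shared genes.

    Returns counts unique to each list, the shared count, and the percent of
    shared genes whose fold changes agree in sign (one decimal place, or
    None when nothing is shared).
    """
    if set(de_a.index) != set(de_b.index):
        raise ValidationError("DE tables must share one gene universe")
    sig_a = de_a.index[(de_a["p_adj"] < fdr).fillna(False)]
    sig_b = de_b.index[(de_b["p_adj"] < fdr).fillna(False)]
    shared = sig_a.intersection(sig_b)
    same = int(
        (
            np.sign(de_a.loc[shared, "log2FC"]) == np.sign(de_b.loc[shared, "log2FC"])
        ).sum()
    )
    return {
        "unique_to_a": int(len(sig_a.difference(sig_b))),
        "unique_to_b": int(len(sig_b.difference(sig_a))),
        "shared": int(len(shared)),
        "same_direction": same,
        "same_direction_pct": proportion_percent(same, len(shared), 1)
        if len(shared)
        else None,
    }


def proportion_percent(k: int, n: int, digits: int = 0) -> float:
    """k/n as a percentage rounded to ``digits`` decimal places."""
    if n == 0:
        raise ValidationError("cannot form a percentage with n = 0")
    return round(100.0 * k / n, digits)
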