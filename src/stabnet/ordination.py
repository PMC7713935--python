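"""Bray-Curtis ordination (nMDS) and permutational ANOVA.

Sample-level structure is summarized by Bray-Curtis dissimilarities on
normalized abundance values, embedded by nonmetric multidimensional
scaling (Kruskal stress-1 minimized by iterative majorization with
isotonic regression, multiple restarts), and tested with a sequential
(type-I) PERMANOVA with population, infestation time, and their
interaction, p-values by free permutation of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .containers import DesignTable, ValidationError

log = logging.getLogger("stabnet")


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample rows.

    d_ij = sum_g |x_ig - x_jg| / sum_g (x_ig + x_jg); a pair of all-zero
    samples is defined as distance 0 with a warning.
    """
    x = abundance.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        log.warning("all-zero sample pair(s): Bray-Curtis distance set to 0")
        d = np.nan_to_num(d)
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    stress_history: list = field(default_factory=list)  # best start's trajectory


def _kruskal_stress(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((dhat - dist) ** 2) / denom))


def _smacof_single(
    d_cond: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, list]:
    """One nonmetric majorization run from a given start configuration."""
    n = x0.shape[0]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = x0.copy()
    order = np.argsort(d_cond, kind="stable")
    history: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        dist = np.maximum(dist, 1e-12)
        # monotone regression of configuration distances on dissimilarity ranks
        dhat = np.empty_like(dist)
        dhat[order] = iso.fit_transform(np.arange(d_cond.size), dist[order])
        stress = _kruskal_stress(dhat, dist)
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with weights 1
        ratio = squareform(dhat / dist)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, history[-1] if history else 1.0, converged, history


def nmds(
    dissim: pd.DataFrame,
    k: int = 4,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric MDS in ``k`` dimensions; best of seeded restarts.

    One start is the classical (metric) scaling configuration; the rest are
    random. Coordinates of the best run are centered and rotated onto their
    principal axes.
    """
    n = dissim.shape[0]
    if n <= k:
        raise ValidationError("nMDS requires more samples than dimensions")
    d = dissim.to_numpy(dtype=float)
    d_cond = squareform(d, checks=False)
    rng = np.random.default_rng(seed)

    # classical-scaling start
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(g)
    idx = np.argsort(evals)[::-1][:k]
    metric_start = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 1e-12))

    best = None
    for start in range(max(1, n_starts)):
        x0 = metric_start if start == 0 else rng.normal(size=(n, k))
        x, stress, conv, hist = _smacof_single(d_cond, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, hist)
    x, stress, conv, hist = best
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T  # principal-axis rotation
    coords = pd.DataFrame(
        x, index=dissim.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, float(stress), max(1, n_starts), conv, hist)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design_matrices(design: DesignTable) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Cumulative model matrices for the sequential PERMANOVA terms."""
    tab = design.table
    pop = pd.get_dummies(tab["population"], drop_first=True).to_numpy(dtype=float)
    stage = pd.get_dummies(tab["infestation"], drop_first=True).to_numpy(dtype=float)
    inter = np.einsum("ij,ik->ijk", pop, stage).reshape(len(tab), -1)
    n = len(tab)
    ones = np.ones((n, 1))
    x0 = ones
    x1 = np.hstack([ones, pop])
    x2 = np.hstack([ones, pop, stage])
    x3 = np.hstack([ones, pop, stage, inter])
    terms = ["population", "infestation", "population:infestation"]
    dfs = [pop.shape[1], stage.shape[1], inter.shape[1]]
    return [x0, x1, x2, x3], terms, dfs


def permanova(
    dissim: pd.DataFrame,
    design: DesignTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential PERMANOVA of a dissimilarity matrix on the factorial design.

    The Gower-centered inner-product matrix of squared dissimilarities is
    partitioned by projecting onto the nested model matrices in order
    (population, infestation, interaction). Pseudo-F uses the residual of
    the full model; p-values count permuted F >= observed with the +1
    correction under free permutation of samples.
    """
    if n_perm < 1:
        raise ValidationError("PERMANOVA requires n_perm >= 1")
    design = design.reindex(dissim.index)
    d = dissim.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j

    xs, terms, dfs = _design_matrices(design)
    hats = [_hat(x) for x in xs]
    df_resid = n - xs[-1].shape[1]

    def term_ss(gm: np.ndarray) -> tuple[np.ndarray, float, float]:
        tr = [float(np.sum(h * gm)) for h in hats]  # tr(H G), H symmetric
        ss_terms = np.array([tr[i + 1] - tr[i] for i in range(len(terms))])
        ss_total = float(np.trace(gm))
        ss_resid = ss_total - tr[-1]
        return ss_terms, ss_resid, ss_total

    ss_terms, ss_resid, ss_total = term_ss(g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_p, resid_p, _ = term_ss(gp)
        f_p = (ss_p / np.array(dfs)) / (resid_p / df_resid)
        exceed += f_p >= f_obs - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_terms[i],
                "pseudo_F": f_obs[i],
                "R2": ss_terms[i] / ss_total,
                "p_perm": pvals[i],
            }
        )
    rows.append(
        {"term": "Residual", "df": df_resid, "SS": ss_resid,
         "pseudo_F": np.nan, "R2": ss_resid / ss_total, "p_perm": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total,
         "pseudo_F": np.nan, "R2": 1.0, "p_perm": np.nan}
    )
    return pd.DataFrame(rows).set_index("term")
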