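"""Module eigengenes, factorial ANOVA, and response-category classification.

The eigengene of a module is the first principal component of its
standardized expression submatrix: a single per-sample profile summarizing
the module. Each eigengene is tested with a two-way fixed-effects ANOVA
(population, infestation stage, interaction), and modules with
population-dependent responses are sorted into the four qualitative
response categories:

I    same direction in both populations, much stronger in one;
II   response confined to a single population;
III  opposing directions in the two populations;
IV   both populations respond but with different timing across day 4/day 7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import (
    DesignTable,
    ExpressionMatrix,
    ModuleAssignment,
    UNASSIGNED,
    ValidationError,
)
from .diffexpr import bh_adjust

log = logging.getLogger("stabnet")

CATEGORIES = ("shared", "I", "II", "III", "IV", "none")


@dataclass
class Eigengene:
    module_id: str
    scores: pd.Series  # per-sample, unit norm
    variance_explained: float
    loadings: pd.Series  # per-gene


def module_eigengene(em: ExpressionMatrix, genes, module_id: str = "module") -> Eigengene:
    """First principal component of the standardized module submatrix.

    Genes are standardized to mean 0 / SD 1 across samples (zero-variance
    genes are excluded with a warning); the unit-norm first right singular
    vector is the eigengene, sign-fixed so the gene loadings sum positive.
    variance_explained is the first squared singular value over the total.
    """
    genes = [g for g in genes if g in em.gene_ids]
    if len(genes) < 2:
        raise ValidationError("eigengene requires at least 2 genes present")
    x = em.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning(
            "module %s: excluding %d zero-variance gene(s) from the eigengene",
            module_id, int((~keep).sum()),
        )
        x, genes = x[keep], [g for g, k in zip(genes, keep) if k]
        sd = sd[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = u[:, 0]
    scores = vt[0]
    if loadings.sum() < 0:
        loadings, scores = -loadings, -scores
    return Eigengene(
        module_id=module_id,
        scores=pd.Series(scores, index=em.sample_ids, name=module_id),
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
        loadings=pd.Series(loadings, index=genes, name=module_id),
    )


def all_eigengenes(em: ExpressionMatrix, assignment: ModuleAssignment) -> dict[str, Eigengene]:
    return {
        m: module_eigengene(em, assignment.members(m), m)
        for m in sorted(assignment.module_names())
    }


def eigengene_anova(eg: Eigengene, design: DesignTable) -> pd.Series:
    """Two-way fixed-effects ANOVA with interaction on eigengene scores.

    With a balanced design the sequential (type I) decomposition equals the
    type III one, so sequential sums of squares are used.
    """
    design = design.reindex(eg.scores.index)
    df = design.table.copy()
    df["score"] = eg.scores
    counts = df.groupby(["population", "infestation"], observed=True).size()
    if (counts == 0).any() or counts.size < len(design.populations) * len(design.stages):
        raise ValidationError("eigengene ANOVA requires every design cell occupied")
    fit = smf.ols("score ~ C(population) * C(infestation)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    return pd.Series(
        {
            "module_id": eg.module_id,
            "F_population": tab.loc["C(population)", "F"],
            "p_population": tab.loc["C(population)", "PR(>F)"],
            "F_infestation": tab.loc["C(infestation)", "F"],
            "p_infestation": tab.loc["C(infestation)", "PR(>F)"],
            "F_interaction": tab.loc["C(population):C(infestation)", "F"],
            "p_interaction": tab.loc["C(population):C(infestation)", "PR(>F)"],
            "df_residual": tab.loc["Residual", "df"],
        }
    )


def anova_table(eigengenes: dict[str, Eigengene], design: DesignTable) -> pd.DataFrame:
    """Per-module ANOVA with BH adjustment across modules for each term."""
    rows = [eigengene_anova(eg, design) for eg in eigengenes.values()]
    tab = pd.DataFrame(rows).set_index("module_id")
    for term in ("population", "infestation", "interaction"):
        tab[f"p_adj_{term}"] = bh_adjust(tab[f"p_{term}"]).to_numpy()
    return tab


def _deltas(eg: Eigengene, design: DesignTable) -> tuple[dict, float]:
    """Group-mean eigengene shifts from control, in pooled within-group SD units."""
    design = design.reindex(eg.scores.index)
    df = design.table.copy()
    df["score"] = eg.scores
    grouped = df.groupby(["population", "infestation"], observed=True)["score"]
    means = grouped.mean()
    # pooled within-cell SD
    ss = ((df["score"] - grouped.transform("mean")) ** 2).sum()
    dof = len(df) - means.size
    pooled_sd = float(np.sqrt(ss / dof)) if dof > 0 else np.nan
    if not np.isfinite(pooled_sd) or pooled_sd == 0:
        pooled_sd = float(df["score"].std(ddof=1)) or 1.0
    deltas = {}
    for pop in design.populations:
        for stage in design.stages:
            if stage == "control":
                continue
            deltas[(pop, stage)] = (means[(pop, stage)] - means[(pop, "control")]) / pooled_sd
    return deltas, pooled_sd


def classify_response(
    eg: Eigengene,
    design: DesignTable,
    eps: float = 0.6,
    ratio: float = 2.0,
) -> str:
    """Assign a population-by-infestation response category.

    Day-7 and day-4 shifts from control are computed per population in
    pooled-SD units. With both day-7 shifts exceeding ``eps``: opposite
    signs give III, a magnitude ratio of at least ``ratio`` gives I, and a
    smaller ratio gives "shared". Otherwise a population counts as
    responding if either day's |shift| exceeds ``eps``: exactly one
    responding population gives II; two responding populations whose
    thresholded sign patterns across days differ give IV (timing); equal
    patterns give "shared"; no responders give "none".
    """
    deltas, _ = _deltas(eg, design)
    pops = list(design.populations)
    d7 = {p: deltas[(p, "day7")] for p in pops}
    d4 = {p: deltas[(p, "day4")] for p in pops}
    a, b = pops
    big7 = {p: abs(d7[p]) > eps for p in pops}
    if big7[a] and big7[b]:
        if np.sign(d7[a]) != np.sign(d7[b]):
            return "III"
        hi, lo = max(abs(d7[a]), abs(d7[b])), min(abs(d7[a]), abs(d7[b]))
        return "I" if hi / lo >= ratio else "shared"
    responding = {p: max(abs(d4[p]), abs(d7[p])) > eps for p in pops}
    if responding[a] != responding[b]:
        return "II"
    if responding[a] and responding[b]:
        pattern = {
            p: (
                int(np.sign(d4[p])) if abs(d4[p]) > eps else 0,
                int(np.sign(d7[p])) if abs(d7[p]) > eps else 0,
            )
            for p in pops
        }
        return "IV" if pattern[a] != pattern[b] else "shared"
    return "none"


def categorize_modules(
    em: ExpressionMatrix,
    assignment: ModuleAssignment,
    design: DesignTable,
    eps: float = 0.6,
    ratio: float = 2.0,
) -> pd.DataFrame:
    """Eigengenes, ANOVA and categories for every named module."""
    egs = all_eigengenes(em, assignment)
    tab = anova_table(egs, design)
    tab["variance_explained"] = [egs[m].variance_explained for m in tab.index]
    tab["category"] = [classify_response(egs[m], design, eps, ratio) for m in tab.index]
    tab["n_genes"] = [len(assignment.members(m)) for m in tab.index]
    return tab
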