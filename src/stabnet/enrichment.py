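"""Gene-set over-representation tests ("classic" per-term Fisher scoring).

Each annotation term is tested independently with a one-sided upper-tail
hypergeometric (Fisher exact) test of the overlap between a selected gene
list and the term's annotated genes within a declared universe. Term
hierarchy is not modelled: annotation tables are taken as given,
pre-propagated. BH-adjusted p-values are reported alongside raw ones; the
significance flag uses raw p by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetMap, ValidationError
from .diffexpr import bh_adjust


def fisher_enrichment(
    selected,
    gene_sets: GeneSetMap,
    universe,
    min_term_size: int = 3,
    sig_mode: str = "raw",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation test for every term.

    Parameters
    ----------
    selected : iterable of gene ids, a subset of ``universe``.
    gene_sets : annotation term -> gene set mapping; intersected with the
        universe, terms smaller than ``min_term_size`` skipped.
    sig_mode : "raw" or "adjusted"; which p-value column drives the
        ``significant`` flag at level ``alpha``.
    """
    universe = frozenset(universe)
    selected = frozenset(selected)
    if not universe:
        raise ValidationError("empty gene universe")
    if not selected:
        raise ValidationError("empty selection")
    if not selected <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    if sig_mode not in ("raw", "adjusted"):
        raise ValidationError("sig_mode must be 'raw' or 'adjusted'")

    m = len(universe)
    n_sel = len(selected)
    rows = []
    for gs in sorted(gene_sets, key=lambda s: s.term_id):
        annotated = gs.gene_ids & universe
        if len(annotated) < min_term_size:
            continue
        k = len(annotated & selected)
        p = float(hypergeom.sf(k - 1, m, len(annotated), n_sel))
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "n_universe": m,
                "n_annotated": len(annotated),
                "n_selected": n_sel,
                "n_overlap": k,
                "p_raw": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "n_universe", "n_annotated",
                     "n_selected", "n_overlap", "p_raw", "p_adj", "significant"]
        ).set_index("term_id")
    tab = pd.DataFrame(rows).set_index("term_id")
    tab["p_adj"] = bh_adjust(tab["p_raw"]).to_numpy()
    col = "p_raw" if sig_mode == "raw" else "p_adj"
    tab["significant"] = tab[col] < alpha
    return tab.sort_values("p_raw")
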