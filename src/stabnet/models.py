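"""Model/Results front-ends over the pipeline stages.

Each analysis stage is exposed as a model object built from data whose
``fit()`` returns a results object carrying estimates, diagnostics and a
``summary()`` table, in the spirit of statsmodels. The functional stage
modules (:mod:`preprocess`, :mod:`diffexpr`, :mod:`network`,
:mod:`consensus`, :mod:`eigengenes`, :mod:`ordination`,
:mod:`enrichment`) remain the computational layer; these classes wrap them
for interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import consensus as cns
from . import diffexpr as de
from . import eigengenes as eg
from . import network as net
from . import ordination as ordn
from . import preprocess as pre
from .containers import CountMatrix, DesignTable, ExpressionMatrix, ModuleAssignment


def _fmt(df: pd.DataFrame, title: str) -> str:
    return f"{title}\n{'=' * len(title)}\n{df.to_string()}\n"


class DifferentialExpression:
    """Per-gene NB-GLM differential expression on a count matrix.

    Parameters
    ----------
    counts : CountMatrix of raw counts (already expression-filtered or not;
        ``fit`` applies the CPM filter when ``filter_counts`` is true).
    design : DesignTable with population and infestation factors.
    """

    def __init__(self, counts: CountMatrix, design: DesignTable):
        design.check_matches(counts.sample_ids)
        self.counts = counts
        self.design = design

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, design: pd.DataFrame):
        return cls(CountMatrix(counts), DesignTable(design))

    def fit(
        self,
        contrasts: dict | None = None,
        filter_counts: bool = True,
        min_cpm: float = 1.0,
        min_samples: int = 2,
        prior_df: float = 10.0,
        fdr: float = 0.05,
    ) -> "DifferentialExpressionResults":
        cm = (
            pre.filter_low_expression(self.counts, min_cpm, min_samples)
            if filter_counts
            else self.counts
        )
        nf = pre.tmm_normalize(cm)
        disp = de.estimate_dispersions(cm, self.design, prior_df, nf)
        tables = de.run_contrasts(cm, nf, self.design, disp, contrasts)
        return DifferentialExpressionResults(tables, disp, nf, fdr)


@dataclass
class DifferentialExpressionResults:
    tables: dict
    dispersions: de.Dispersions
    norm_factors: pd.Series
    fdr: float = 0.05

    def n_significant(self) -> pd.Series:
        return pd.Series(
            {k: int((t["p_adj"] < self.fdr).sum()) for k, t in self.tables.items()}
        )

    def venn(self, contrast_a: str, contrast_b: str) -> dict:
        return de.venn_partition(
            self.tables[contrast_a], self.tables[contrast_b], self.fdr
        )

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "n_genes": {k: len(t) for k, t in self.tables.items()},
                "n_significant": self.n_significant(),
            }
        )
        head = (
            f"NB-GLM differential expression (LRT, chi2(1); BH FDR < {self.fdr})\n"
            f"common dispersion {self.dispersions.common:.4f}, "
            f"shrinkage weight {self.dispersions.shrinkage_weight:.2f}\n"
        )
        return head + _fmt(tab, "Contrasts")


class CoexpressionNetwork:
    """Signed-hybrid weighted coexpression network on log-CPM expression."""

    def __init__(self, expression: ExpressionMatrix):
        self.expression = expression

    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        drop_fraction: float = 0.40,
        min_cpm: float = 1.0,
        min_samples: int = 2,
    ):
        cm = pre.filter_low_expression(counts, min_cpm, min_samples)
        nf = pre.tmm_normalize(cm)
        em = pre.log_cpm(cm, nf)
        return cls(pre.variance_prefilter(em, drop_fraction))

    def fit(self, params: net.NetworkParams | None = None, seed: int = 0) -> "NetworkResults":
        params = params or net.NetworkParams()
        assignment, info = net.blockwise_modules(self.expression, params, seed)
        return NetworkResults(self.expression, assignment, params, info)


@dataclass
class NetworkResults:
    expression: ExpressionMatrix
    assignment: ModuleAssignment
    params: net.NetworkParams
    info: dict

    def summary(self) -> str:
        sizes = self.assignment.sizes()
        head = (
            f"Signed-hybrid network: power {self.info.get('power')}, "
            f"{self.info.get('n_blocks')} block(s), "
            f"{len(sizes)} modules, "
            f"{self.assignment.n_assigned()}/{len(self.assignment.gene_ids)} genes assigned\n"
        )
        return head + _fmt(sizes.to_frame("n_genes"), "Module sizes")

    def consensus(
        self,
        n_boot: int = 250,
        overlap_frac: float = 0.10,
        reliability: float = 0.70,
        merge_r: float = 0.85,
        min_size: int = 30,
        seed: int = 0,
    ) -> "ConsensusResults":
        params = net.NetworkParams(
            power=self.info.get("power", self.params.power),
            min_module_size=self.params.min_module_size,
            deep_split=self.params.deep_split,
            merge_cut_height=self.params.merge_cut_height,
        )
        cr = cns.run_consensus(
            self.expression, self.assignment, params,
            n_boot=n_boot, overlap_frac=overlap_frac, reliability=reliability,
            merge_r=merge_r, min_size=min_size, seed=seed,
        )
        return ConsensusResults(self.expression, cr)


@dataclass
class ConsensusResults:
    expression: ExpressionMatrix
    result: cns.ConsensusResult

    @property
    def assignment(self) -> ModuleAssignment:
        return self.result.assignment

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "original_label": self.result.original,
                "final_label": self.result.final,
                "reliability": self.result.reliability,
            }
        )

    def summary(self) -> str:
        sizes = self.assignment.sizes()
        head = (
            f"Bootstrap consensus over {self.result.n_boot} replicates: "
            f"{len(sizes)} stable modules, "
            f"{int((self.result.final != 'unassigned').sum())} genes retained\n"
        )
        return head + _fmt(sizes.to_frame("n_genes"), "Stable module sizes")


class EigengeneAnalysis:
    """Module-eigengene factorial analysis and response classification."""

    def __init__(
        self,
        expression: ExpressionMatrix,
        assignment: ModuleAssignment,
        design: DesignTable,
    ):
        self.expression = expression
        self.assignment = assignment
        self.design = design

    def fit(self, eps: float = 0.6, ratio: float = 2.0) -> "EigengeneResults":
        egs = eg.all_eigengenes(self.expression, self.assignment)
        table = eg.categorize_modules(
            self.expression, self.assignment, self.design, eps, ratio
        )
        scores = pd.DataFrame({m: e.scores for m, e in egs.items()}).T
        return EigengeneResults(egs, scores, table)


@dataclass
class EigengeneResults:
    eigengenes: dict
    scores: pd.DataFrame  # modules x samples
    table: pd.DataFrame  # ANOVA + categories

    def summary(self) -> str:
        cols = [
            "n_genes", "variance_explained", "F_population", "F_infestation",
            "F_interaction", "p_adj_interaction", "category",
        ]
        return _fmt(self.table[cols].round(4), "Module eigengene ANOVA and categories")


class Ordination:
    """Bray-Curtis nMDS and PERMANOVA on sample-level abundances."""

    def __init__(self, abundance: pd.DataFrame, design: DesignTable):
        """``abundance``: samples x genes non-negative values (TMM-scaled CPM)."""
        design.check_matches(abundance.index)
        self.abundance = abundance
        self.design = design

    @classmethod
    def from_counts(
        cls, counts: CountMatrix, design: DesignTable,
        min_cpm: float = 1.0, min_samples: int = 2,
    ):
        cm = pre.filter_low_expression(counts, min_cpm, min_samples)
        nf = pre.tmm_normalize(cm)
        lib = cm.lib_sizes * nf
        cpm_tmm = (cm.counts / lib.to_numpy() * 1e6).T
        return cls(cpm_tmm, design)

    def fit(
        self, k: int = 4, n_starts: int = 20, n_perm: int = 1000, seed: int = 0
    ) -> "OrdinationResults":
        d = ordn.bray_curtis(self.abundance)
        mds = ordn.nmds(d, k=k, n_starts=n_starts, seed=seed)
        ptab = ordn.permanova(d, self.design, n_perm=n_perm, seed=seed)
        return OrdinationResults(d, mds, ptab)


@dataclass
class OrdinationResults:
    dissimilarity: pd.DataFrame
    nmds: ordn.OrdinationResult
    permanova: pd.DataFrame

    def summary(self) -> str:
        head = (
            f"nMDS in k={self.nmds.coordinates.shape[1]}: "
            f"stress-1 {self.nmds.stress:.4f} "
            f"({'converged' if self.nmds.converged else 'not converged'})\n"
        )
        return head + _fmt(self.permanova.round(4), "PERMANOVA (sequential SS)")
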