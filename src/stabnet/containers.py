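"""Core data containers shared by every pipeline stage.

The pipeline operates on three primary objects: a :class:`CountMatrix` of raw
read counts (genes x samples), a :class:`DesignTable` assigning each sample to
a population and an infestation stage, and a :class:`GeneSetMap` carrying
gene-ontology-style annotation sets. All of them validate their invariants at
construction time so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved module label for genes not belonging to any named module.
UNASSIGNED = "unassigned"

#: Default factor vocabularies of the two-population infestation design.
POPULATIONS = ("kauai", "mangaia")
STAGES = ("control", "day4", "day7")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dups[:10]}")


@dataclass
class CountMatrix:
    """Integer read counts for genes (rows) by samples (columns).

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = gene ids, columns = sample ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValidationError("no genes parsed")
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise ValidationError(f"non-numeric count at {bad[:5].tolist()}")
        if np.any(values != np.floor(values)):
            g, s = np.argwhere(values != np.floor(values))[0]
            raise ValidationError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample library sizes (exact column sums)."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass
class DesignTable:
    """Sample-level factors: population and infestation stage.

    ``table`` is indexed by sample id with columns ``population`` and
    ``infestation``. Factor levels are restricted to declared vocabularies
    unless alternatives are supplied.
    """

    table: pd.DataFrame
    populations: tuple = POPULATIONS
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        required = {"population", "infestation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing column(s): {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        bad_pop = set(self.table["population"]) - set(self.populations)
        if bad_pop:
            raise ValidationError(f"unknown population level(s): {sorted(bad_pop)}")
        bad_stage = set(self.table["infestation"]) - set(self.stages)
        if bad_stage:
            raise ValidationError(f"unknown infestation level(s): {sorted(bad_stage)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def group_labels(self) -> pd.Series:
        """Combined population x infestation cell label per sample."""
        return self.table["population"].str.cat(self.table["infestation"], sep=":")

    def check_matches(self, sample_ids) -> None:
        """Require exact sample agreement with a count matrix."""
        mine = set(self.table.index)
        theirs = set(sample_ids)
        if mine != theirs:
            only_design = sorted(mine - theirs)
            only_counts = sorted(theirs - mine)
            raise ValidationError(
                "design/count sample mismatch: "
                f"only in design {only_design}; only in counts {only_counts}"
            )

    def reindex(self, sample_ids) -> "DesignTable":
        self.check_matches(sample_ids)
        return DesignTable(self.table.loc[list(sample_ids)], self.populations, self.stages)


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    gene_ids: frozenset

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"gene set {self.term_id!r} is empty")
        self.gene_ids = frozenset(self.gene_ids)


@dataclass
class GeneSetMap:
    """Collection of annotation term -> gene-set mappings."""

    sets: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "GeneSetMap":
        """Build from an iterable of (term_id, term_name, gene_id) triples."""
        names: dict[str, str] = {}
        genes: dict[str, set] = {}
        for term_id, term_name, gene_id in records:
            names.setdefault(term_id, term_name)
            genes.setdefault(term_id, set()).add(gene_id)
        return cls({t: GeneSet(t, names[t], frozenset(g)) for t, g in genes.items()})

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def restrict(self, universe) -> "GeneSetMap":
        """Intersect every set with a gene universe, dropping emptied terms."""
        universe = frozenset(universe)
        out = {}
        for gs in self:
            inter = gs.gene_ids & universe
            if inter:
                out[gs.term_id] = GeneSet(gs.term_id, gs.term_name, inter)
        return GeneSetMap(out)


@dataclass
class ExpressionMatrix:
    """log2 counts-per-million expression values (genes x samples)."""

    values: pd.DataFrame
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("non-finite expression value")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.prior_count)


@dataclass
class ModuleAssignment:
    """Gene -> module label map with dendrogram provenance.

    ``labels`` is a Series indexed by gene id; named modules are labelled
    ``"M1", "M2", ...`` in decreasing size order and genes outside any named
    module carry the reserved :data:`UNASSIGNED` label.
    """

    labels: pd.Series
    linkage: np.ndarray | None = None
    cut_height: float | None = None

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "gene")
        self.labels = self.labels.astype(str)

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        named = self.labels[self.labels != UNASSIGNED]
        return named.value_counts()

    def n_assigned(self) -> int:
        return int((self.labels != UNASSIGNED).sum())

    def relabel_by_size(self) -> "ModuleAssignment":
        """Rename modules M1..Mk by decreasing size (ties by first member)."""
        named = self.labels[self.labels != UNASSIGNED]
        if named.empty:
            return ModuleAssignment(self.labels.copy(), self.linkage, self.cut_height)
        order = sorted(
            named.unique(),
            key=lambda m: (-int((named == m).sum()), str(self.members(m).min())),
        )
        mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
        mapping[UNASSIGNED] = UNASSIGNED
        return ModuleAssignment(self.labels.map(mapping), self.linkage, self.cut_height)
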