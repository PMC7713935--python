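"""Bootstrap module-stability consensus filtering.

Networks are rebuilt on with-replacement resamples of the samples, each
resampled network's modules are matched back to the original modules by a
10% overlap rule, and a gene keeps its original module only when at least
70% of bootstrap replicates support that assignment. Surviving modules are
then merged at eigengene correlation strictly above 0.85 and modules
falling below the minimum size are dissolved. By construction the final
topology is a subset-relabelling of the original: no new module can appear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ModuleAssignment, UNASSIGNED, ValidationError
from .network import NetworkParams, merge_close_modules, single_block_modules

log = logging.getLogger("stabnet")


@dataclass
class BootstrapRun:
    replicate: int
    sample_indices: np.ndarray  # with multiplicity, length = n samples
    assignment: ModuleAssignment


@dataclass
class ConsensusResult:
    original: pd.Series  # gene -> original label
    final: pd.Series  # gene -> consensus label
    reliability: pd.Series  # gene -> supported fraction of replicates
    n_boot: int
    audit: dict = field(default_factory=dict)

    @property
    def assignment(self) -> ModuleAssignment:
        return ModuleAssignment(self.final)


def bootstrap_networks(
    em: ExpressionMatrix,
    params: NetworkParams,
    n_boot: int = 250,
    seed: int = 0,
    max_redraws: int = 20,
) -> list[BootstrapRun]:
    """Rebuild the network on ``n_boot`` with-replacement sample resamples.

    Network parameters (including the soft power) must match the original
    run; duplicated samples enter the correlations with their multiplicity.
    Replicates where more than half the genes lose all expression variance
    are redrawn (logged). Per-replicate seeds derive deterministically from
    ``seed``.
    """
    if n_boot < 1:
        raise ValidationError("bootstrap requires >=1 replicate")
    if params.power is None:
        raise ValidationError("bootstrap runs need the original network's power")
    values = em.values
    n_samples = values.shape[1]
    runs = []
    for b in range(n_boot):
        rng = np.random.default_rng([int(seed) % (2**31), b])
        for _ in range(max_redraws):
            idx = rng.integers(0, n_samples, size=n_samples)
            resampled = values.iloc[:, idx]
            frac_flat = (resampled.std(axis=1) == 0).mean()
            if frac_flat <= 0.5:
                break
            log.warning("replicate %d: %.0f%% flat genes, redrawing", b, 100 * frac_flat)
        boot_em = ExpressionMatrix(
            pd.DataFrame(
                resampled.to_numpy(),
                index=values.index,
                columns=[f"bs{j}" for j in range(n_samples)],
            ),
            em.prior_count,
        )
        ma, _ = single_block_modules(boot_em, params)
        runs.append(BootstrapRun(b, idx, ma))
    return runs


def match_modules(
    original: ModuleAssignment,
    resampled: ModuleAssignment,
    overlap_frac: float = 0.10,
) -> pd.Series:
    """Genes supported by one resampled network (boolean per gene).

    A resampled module corresponds to an original module when it contains
    at least ``overlap_frac`` of that module's genes (inclusive); the
    overlapping genes then support their original assignment. A resampled
    module may correspond to several original modules; unassigned labels on
    either side never match.
    """
    if set(original.gene_ids) != set(resampled.gene_ids):
        raise ValidationError("module assignments must share one gene universe")
    support = pd.Series(False, index=original.gene_ids)
    resampled_members = {
        m: set(resampled.members(m)) for m in resampled.module_names()
    }
    for orig_mod in original.module_names():
        orig_genes = set(original.members(orig_mod))
        needed = overlap_frac * len(orig_genes) - 1e-9
        for genes_r in resampled_members.values():
            overlap = orig_genes & genes_r
            if len(overlap) >= needed and overlap:
                support[list(overlap)] = True
    return support


def tally_support(
    original: ModuleAssignment,
    runs: list[BootstrapRun],
    overlap_frac: float = 0.10,
) -> pd.Series:
    """Count, per gene, the replicates supporting its original module.

    Support is binary per replicate: multiple matching resampled modules in
    one replicate still count once.
    """
    counts = pd.Series(0, index=original.gene_ids, dtype=int)
    for run in runs:
        counts += match_modules(original, run.assignment, overlap_frac).astype(int)
    return counts


def consensus_filter(
    original: ModuleAssignment,
    support_counts: pd.Series,
    n_boot: int,
    reliability: float = 0.70,
) -> ConsensusResult:
    """Demote genes supported in fewer than ``reliability`` of replicates.

    The threshold is inclusive: support_count / n_boot >= reliability keeps
    the gene. Originally unassigned genes stay unassigned regardless.
    """
    if n_boot < 1:
        raise ValidationError("bootstrap requires >=1 replicate")
    rel = support_counts.reindex(original.gene_ids).fillna(0) / n_boot
    keep = rel >= reliability - 1e-12
    final = original.labels.where(keep, UNASSIGNED)
    final[original.labels == UNASSIGNED] = UNASSIGNED
    audit = {}
    for m in original.module_names():
        members = original.members(m)
        retained = int((final[members] == m).sum())
        audit[m] = {"original": len(members), "retained": retained,
                    "demoted": len(members) - retained}
    return ConsensusResult(
        original=original.labels.copy(),
        final=final,
        reliability=rel.rename("reliability"),
        n_boot=n_boot,
        audit=audit,
    )


def finalize_consensus(
    em: ExpressionMatrix,
    cr: ConsensusResult,
    merge_r: float = 0.85,
    min_size: int = 30,
) -> ConsensusResult:
    """Strict-threshold eigengene merge, then minimum-size cleanup.

    Modules whose eigengenes correlate strictly above ``merge_r`` are
    merged; modules left with fewer than ``min_size`` genes (strictly fewer:
    a module of exactly ``min_size`` survives) are dissolved to unassigned.
    Final labels are renumbered by decreasing size.
    """
    assignment = ModuleAssignment(cr.final.copy())
    merged = merge_close_modules(em, assignment, cut_height=1.0 - merge_r, strict=True)
    labels = merged.labels.copy()
    sizes = labels[labels != UNASSIGNED].value_counts()
    for m, size in sizes.items():
        if size < min_size:
            labels[labels == m] = UNASSIGNED
    final = ModuleAssignment(labels).relabel_by_size()
    audit = dict(cr.audit)
    audit["final_modules"] = {
        m: int(len(final.members(m))) for m in final.module_names()
    }
    return ConsensusResult(
        original=cr.original,
        final=final.labels,
        reliability=cr.reliability,
        n_boot=cr.n_boot,
        audit=audit,
    )


def run_consensus(
    em: ExpressionMatrix,
    original: ModuleAssignment,
    params: NetworkParams,
    n_boot: int = 250,
    overlap_frac: float = 0.10,
    reliability: float = 0.70,
    merge_r: float = 0.85,
    min_size: int = 30,
    seed: int = 0,
) -> ConsensusResult:
    """Full bootstrap-consensus chain on an original module assignment."""
    runs = bootstrap_networks(em, params, n_boot=n_boot, seed=seed)
    counts = tally_support(original, runs, overlap_frac)
    cr = consensus_filter(original, counts, n_boot, reliability)
    return finalize_consensus(em, cr, merge_r, min_size)
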