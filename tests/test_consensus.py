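"""Bootstrap consensus: boundary semantics, determinism, stability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stabnet import consensus as cns
from stabnet import network as net
from stabnet.containers import ExpressionMatrix, ModuleAssignment, UNASSIGNED, ValidationError


def _assignment(mapping):
    labels = pd.Series(
        {g: lab for lab, genes in mapping.items() for g in genes}
    ).sort_index()
    return ModuleAssignment(labels)


def _genes(prefix, n, start=0):
    return [f"{prefix}{i:03d}" for i in range(start, start + n)]


class TestMatchModules:
    def test_ten_percent_overlap_inclusive(self):
        genes = _genes("g", 120)
        original = _assignment({"A": genes[:100], UNASSIGNED: genes[100:]})
        # resampled module shares exactly 10 of A's 100 genes
        resampled = _assignment(
            {"R": genes[:10] + genes[100:120], UNASSIGNED: genes[10:100]}
        )
        support = cns.match_modules(original, resampled, overlap_frac=0.10)
        assert support[genes[:10]].all()
        assert not support[genes[10:100]].any()

    def test_nine_of_hundred_below_threshold(self):
        genes = _genes("g", 120)
        original = _assignment({"A": genes[:100], UNASSIGNED: genes[100:]})
        resampled = _assignment(
            {"R": genes[:9] + genes[100:120], UNASSIGNED: genes[9:100]}
        )
        support = cns.match_modules(original, resampled, overlap_frac=0.10)
        assert not support.any()

    def test_resampled_module_split_between_two_originals(self):
        genes = _genes("g", 200)
        original = _assignment({"A": genes[:100], "B": genes[100:200]})
        resampled = _assignment(
            {"R": genes[80:120], UNASSIGNED: genes[:80] + genes[120:]}
        )
        support = cns.match_modules(original, resampled, overlap_frac=0.10)
        # R covers 20 of A and 20 of B: both matched, genes split by origin
        assert support[genes[80:120]].all()
        assert not support[genes[:80]].any() and not support[genes[120:]].any()

    def test_unassigned_never_matches(self):
        genes = _genes("g", 60)
        original = _assignment({UNASSIGNED: genes})
        resampled = _assignment({"R": genes[:40], UNASSIGNED: genes[40:]})
        support = cns.match_modules(original, resampled)
        assert not support.any()


class TestConsensusFilter:
    @staticmethod
    def _one_gene_result(count, n_boot=250, reliability=0.70):
        genes = _genes("g", 40)
        original = _assignment({"A": genes[:30], UNASSIGNED: genes[30:]})
        support = pd.Series(0, index=original.gene_ids)
        support[genes[0]] = count
        support[genes[1:30]] = n_boot
        return cns.consensus_filter(original, support, n_boot, reliability)

    def test_seventy_percent_boundary_inclusive(self):
        cr = self._one_gene_result(175)  # 175/250 = 0.70 exactly
        assert cr.final["g000"] == "A"

    def test_below_seventy_percent_demoted(self):
        cr = self._one_gene_result(174)
        assert cr.final["g000"] == UNASSIGNED
        assert cr.reliability["g000"] == pytest.approx(174 / 250)

    def test_fixed_point_when_all_replicates_agree(self):
        genes = _genes("g", 50)
        original = _assignment({"A": genes[:40], UNASSIGNED: genes[40:]})
        support = pd.Series(10, index=original.gene_ids)
        cr = cns.consensus_filter(original, support, n_boot=10)
        assert cr.final.equals(original.labels)

    def test_originally_unassigned_stay_unassigned(self):
        genes = _genes("g", 20)
        original = _assignment({"A": genes[:10], UNASSIGNED: genes[10:]})
        support = pd.Series(10, index=original.gene_ids)  # even with support
        cr = cns.consensus_filter(original, support, n_boot=10)
        assert (cr.final[genes[10:]] == UNASSIGNED).all()

    def test_raising_reliability_never_grows_modules(self):
        rng = np.random.default_rng(3)
        genes = _genes("g", 200)
        original = _assignment({"A": genes[:120], "B": genes[120:180],
                                UNASSIGNED: genes[180:]})
        support = pd.Series(rng.integers(0, 51, size=200), index=original.gene_ids)
        sizes = []
        for rel in (0.3, 0.5, 0.7, 0.9):
            cr = cns.consensus_filter(original, support, n_boot=50, reliability=rel)
            sizes.append(cr.final.value_counts().reindex(["A", "B"]).fillna(0))
        for lo, hi in zip(sizes[1:], sizes[:-1]):
            assert (lo <= hi).all()


class TestFinalize:
    @staticmethod
    def _correlated_em(n_genes_per=40, r_target=1.0, seed=0, n_samples=18):
        rng = np.random.default_rng(seed)
        f1 = rng.normal(size=n_samples)
        f2 = r_target * f1 + np.sqrt(max(1 - r_target**2, 0)) * rng.normal(size=n_samples)
        rows = [4 * f1 + 0.1 * rng.normal(size=n_samples) for _ in range(n_genes_per)]
        rows += [4 * f2 + 0.1 * rng.normal(size=n_samples) for _ in range(n_genes_per)]
        genes = _genes("a", n_genes_per) + _genes("b", n_genes_per)
        return ExpressionMatrix(
            pd.DataFrame(rows, index=genes,
                         columns=[f"s{j}" for j in range(n_samples)])
        )

    def test_highly_correlated_modules_merged(self):
        em = self._correlated_em(r_target=0.98, seed=1)
        cr = cns.ConsensusResult(
            original=pd.Series("A", index=em.gene_ids),
            final=pd.Series(["A"] * 40 + ["B"] * 40, index=em.gene_ids),
            reliability=pd.Series(1.0, index=em.gene_ids),
            n_boot=10,
        )
        out = cns.finalize_consensus(em, cr, merge_r=0.85, min_size=30)
        assert len(set(out.final) - {UNASSIGNED}) == 1

    def test_uncorrelated_modules_kept(self):
        em = self._correlated_em(r_target=0.0, seed=2)
        cr = cns.ConsensusResult(
            original=pd.Series("A", index=em.gene_ids),
            final=pd.Series(["A"] * 40 + ["B"] * 40, index=em.gene_ids),
            reliability=pd.Series(1.0, index=em.gene_ids),
            n_boot=10,
        )
        out = cns.finalize_consensus(em, cr, merge_r=0.85, min_size=30)
        assert len(set(out.final) - {UNASSIGNED}) == 2

    @pytest.mark.parametrize("size,kept", [(30, True), (29, False)])
    def test_min_size_boundary_strictly_fewer_than(self, size, kept):
        em = self._correlated_em(r_target=0.0, seed=3)
        labels = pd.Series(UNASSIGNED, index=em.gene_ids)
        labels.iloc[:size] = "A"
        cr = cns.ConsensusResult(
            original=labels.copy(), final=labels.copy(),
            reliability=pd.Series(1.0, index=em.gene_ids), n_boot=10,
        )
        out = cns.finalize_consensus(em, cr, min_size=30)
        has_module = (out.final != UNASSIGNED).any()
        assert has_module is np.bool_(kept) or has_module == kept

    def test_merge_strictly_greater_than_r(self):
        """Eigengene correlation exactly at the threshold does not merge."""
        em = self._correlated_em(r_target=0.9, seed=4)
        from stabnet.eigengenes import module_eigengene

        e1 = module_eigengene(em, _genes("a", 40)).scores
        e2 = module_eigengene(em, _genes("b", 40)).scores
        r = float(np.corrcoef(e1, e2)[0, 1])
        cr = cns.ConsensusResult(
            original=pd.Series("A", index=em.gene_ids),
            final=pd.Series(["A"] * 40 + ["B"] * 40, index=em.gene_ids),
            reliability=pd.Series(1.0, index=em.gene_ids),
            n_boot=10,
        )
        # threshold exactly at the realized correlation: strict rule keeps both
        out_eq = cns.finalize_consensus(em, cr, merge_r=r, min_size=30)
        assert len(set(out_eq.final) - {UNASSIGNED}) == 2
        # threshold just below: merged
        out_lt = cns.finalize_consensus(em, cr, merge_r=r - 1e-6, min_size=30)
        assert len(set(out_lt.final) - {UNASSIGNED}) == 1


class TestBootstrapRuns:
    def test_zero_replicates_rejected(self, preprocessed):
        _, _, _, em_net = preprocessed
        with pytest.raises(ValidationError, match="requires >=1"):
            cns.bootstrap_networks(em_net, net.NetworkParams(power=6), n_boot=0)

    def test_deterministic_resample_indices(self, preprocessed):
        _, _, _, em_net = preprocessed
        small = ExpressionMatrix(em_net.values.iloc[:150])
        params = net.NetworkParams(power=6, min_module_size=10)
        a = cns.bootstrap_networks(small, params, n_boot=3, seed=5)
        b = cns.bootstrap_networks(small, params, n_boot=3, seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.sample_indices, rb.sample_indices)
            assert ra.assignment.labels.equals(rb.assignment.labels)

    def test_resample_size_matches_design(self, bootstrap_runs, preprocessed):
        _, _, _, em_net = preprocessed
        for run in bootstrap_runs[:5]:
            assert run.sample_indices.shape == (em_net.shape[1],)

    def test_replicates_recover_planted_modules(
        self, bootstrap_runs, network_run, truth_labels
    ):
        """Most replicates find a module overlapping each truth module >=50%."""
        truth_modules = {
            m: set(truth_labels.index[truth_labels == m])
            for m in truth_labels.unique() if m != UNASSIGNED
        }
        hit_counts = {m: 0 for m in truth_modules}
        for run in bootstrap_runs:
            for m, genes in truth_modules.items():
                best = max(
                    (
                        len(genes & set(run.assignment.members(r))) / len(genes)
                        for r in run.assignment.module_names()
                    ),
                    default=0.0,
                )
                if best >= 0.5:
                    hit_counts[m] += 1
        for m, hits in hit_counts.items():
            assert hits / len(bootstrap_runs) >= 0.8, (m, hits)


class TestEndToEndConsensus:
    def test_final_labels_subset_of_original(
        self, preprocessed, network_run, bootstrap_runs
    ):
        """No new module appears: the topology is biased toward the original."""
        _, _, _, em_net = preprocessed
        ma, _ = network_run
        counts = cns.tally_support(ma, bootstrap_runs)
        cr = cns.consensus_filter(ma, counts, len(bootstrap_runs))
        final = cns.finalize_consensus(em_net, cr)
        for m in set(final.final) - {UNASSIGNED}:
            members = final.final.index[final.final == m]
            origins = set(cr.original[members])
            assert UNASSIGNED not in origins

    def test_planted_genes_reliable_impostors_demoted(
        self, preprocessed, network_run, bootstrap_runs, truth_labels
    ):
        """Genuine module genes keep reliability >= 0.7; injected random
        impostors lose it (scaled bootstrap)."""
        _, _, _, em_net = preprocessed
        ma, _ = network_run
        rng = np.random.default_rng(2)
        noise_pool = [
            g for g in em_net.gene_ids
            if truth_labels[g] == UNASSIGNED and ma.labels[g] == UNASSIGNED
        ]
        impostors = rng.choice(noise_pool, size=60, replace=False)
        modules = ma.module_names()
        injected = ma.labels.copy()
        injected[impostors] = rng.choice(modules, size=len(impostors))
        injected_ma = ModuleAssignment(injected)
        counts = cns.tally_support(injected_ma, bootstrap_runs)
        cr = cns.consensus_filter(injected_ma, counts, len(bootstrap_runs))
        # impostors demoted
        demoted = (cr.final[impostors] == UNASSIGNED).mean()
        assert demoted >= 0.9
        # genuine planted genes that the network named keep their label
        genuine = [
            g for g in ma.labels.index
            if ma.labels[g] != UNASSIGNED and truth_labels[g] != UNASSIGNED
        ]
        retained = (cr.final[genuine] != UNASSIGNED).mean()
        assert retained >= 0.9
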