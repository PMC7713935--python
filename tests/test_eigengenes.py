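"""Eigengene definition, factorial ANOVA and category classification."""

import numpy as np
import pandas as pd
import pytest

from stabnet import eigengenes as eg
from stabnet import preprocess as pre
from stabnet import simulate as sim
from stabnet.containers import DesignTable, ExpressionMatrix, ValidationError
from conftest import make_design


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestModuleEigengene:
    def test_rank_one_module(self):
        """Exact copies of one profile: variance explained 1, scores match."""
        rng = np.random.default_rng(0)
        profile = rng.normal(size=12)
        em = _em([profile, 2 * profile + 3, 0.5 * profile - 1])
        e = eg.module_eigengene(em, em.gene_ids)
        assert e.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        expected = z / np.linalg.norm(z)
        assert np.allclose(np.abs(e.scores), np.abs(expected), atol=1e-10)

    def test_sign_convention_loadings_sum_positive(self):
        rng = np.random.default_rng(1)
        em = _em(rng.normal(size=(30, 10)))
        e = eg.module_eigengene(em, em.gene_ids)
        assert e.loadings.sum() > 0

    def test_variance_explained_matches_spectral_oracle(self):
        """Full eigendecomposition of the standardized covariance agrees."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=(50, 18))
            em = _em(x)
            e = eg.module_eigengene(em, em.gene_ids)
            z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1)[:, None]
            evals = np.linalg.eigvalsh(z @ z.T)
            assert e.variance_explained == pytest.approx(
                evals[-1] / evals.sum(), abs=1e-8
            )

    def test_zero_variance_gene_excluded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 8))
        x[2] = 7.0
        em = _em(x)
        e = eg.module_eigengene(em, em.gene_ids)
        assert "g2" not in e.loadings.index

    def test_invariant_to_gene_reordering(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 12))
        em = _em(x)
        e1 = eg.module_eigengene(em, em.gene_ids)
        perm = rng.permutation(40)
        e2 = eg.module_eigengene(em, em.gene_ids[perm])
        assert np.allclose(e1.scores, e2.scores, atol=1e-10)

    def test_too_few_genes_rejected(self):
        em = _em(np.random.default_rng(0).normal(size=(3, 6)))
        with pytest.raises(ValidationError):
            eg.module_eigengene(em, ["g0"])

    def test_variance_floor_on_well_formed_modules(self, experiment):
        """Modules whose realized within-correlation reaches 0.7 explain
        at least 70.5% of their standardized variance."""
        cm, design, truths, _ = experiment
        cm = pre.filter_low_expression(cm)
        em = pre.log_cpm(cm, pre.tmm_normalize(cm))
        checked = 0
        for mt in truths:
            genes = [g for g in mt.gene_ids if g in em.gene_ids]
            x = em.values.loc[genes].to_numpy()
            c = np.corrcoef(x)
            mean_cor = c[np.triu_indices_from(c, 1)].mean()
            if mean_cor < 0.7:
                continue
            e = eg.module_eigengene(em, genes, mt.module_id)
            assert e.variance_explained >= 0.705, (mt.module_id, mean_cor)
            checked += 1
        assert checked >= 3  # the floor is exercised on most planted modules


def _anova_oracle(scores, design):
    """Hand-computed balanced two-way sums-of-squares decomposition."""
    df = design.table.copy()
    df["y"] = scores
    grand = df["y"].mean()
    n = len(df)
    cell = df.groupby(["population", "infestation"], observed=True)["y"].mean()
    pop = df.groupby("population", observed=True)["y"].mean()
    stage = df.groupby("infestation", observed=True)["y"].mean()
    n_pop = df.groupby("population", observed=True).size()
    n_stage = df.groupby("infestation", observed=True).size()
    n_cell = df.groupby(["population", "infestation"], observed=True).size()
    ss_pop = float((n_pop * (pop - grand) ** 2).sum())
    ss_stage = float((n_stage * (stage - grand) ** 2).sum())
    ss_cells = float((n_cell * (cell - grand) ** 2).sum())
    ss_int = ss_cells - ss_pop - ss_stage
    fitted = df.set_index(["population", "infestation"]).index.map(cell)
    ss_res = float(((df["y"].to_numpy() - fitted.to_numpy()) ** 2).sum())
    df_pop, df_stage = len(pop) - 1, len(stage) - 1
    df_int = df_pop * df_stage
    df_res = n - len(cell)
    f = lambda ss, d: (ss / d) / (ss_res / df_res)
    return {
        "F_population": f(ss_pop, df_pop),
        "F_infestation": f(ss_stage, df_stage),
        "F_interaction": f(ss_int, df_int),
        "df_residual": df_res,
    }


class TestEigengeneAnova:
    def test_degrees_of_freedom_accounting(self):
        design = make_design()
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=18), index=design.sample_ids)
        e = eg.Eigengene("m", scores, 0.8, pd.Series(dtype=float))
        row = eg.eigengene_anova(e, design)
        assert row["df_residual"] == 12

    def test_matches_hand_computed_decomposition(self):
        design = make_design()
        rng = np.random.default_rng(6)
        # planted cell means + noise over the 2x3x3 grid
        base = {"control": 0.0, "day4": 0.5, "day7": 1.2}
        scores = pd.Series(
            [
                base[s] + (0.8 if p == "kauai" and s == "day7" else 0.0)
                + 0.3 * rng.normal()
                for p, s in zip(design.table["population"], design.table["infestation"])
            ],
            index=design.sample_ids,
        )
        e = eg.Eigengene("m", scores, 0.8, pd.Series(dtype=float))
        row = eg.eigengene_anova(e, design)
        oracle = _anova_oracle(scores, design)
        for key in ("F_population", "F_infestation", "F_interaction"):
            assert row[key] == pytest.approx(oracle[key], abs=1e-8)

    def test_null_eigengene_small_f(self):
        design = make_design()
        rng = np.random.default_rng(7)
        fs = []
        for rep in range(30):
            scores = pd.Series(1.0 + 1e-3 * rng.normal(size=18),
                               index=design.sample_ids)
            e = eg.Eigengene("m", scores, 0.8, pd.Series(dtype=float))
            row = eg.eigengene_anova(e, design)
            fs.append(row["p_interaction"])
        # null p-values roughly uniform: mean near 0.5, few small
        assert 0.3 < np.mean(fs) < 0.7

    def test_empty_cell_rejected(self):
        design = make_design()
        sub = DesignTable(design.table.iloc[3:])  # drops kauai controls
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=15), index=sub.sample_ids)
        e = eg.Eigengene("m", scores, 0.8, pd.Series(dtype=float))
        with pytest.raises(ValidationError, match="cell"):
            eg.eigengene_anova(e, sub)

    def test_planted_interaction_module_detected(self):
        """Category-III modules show interaction p < 0.01 in >=90% of reps."""
        hits = 0
        for seed in range(10):
            cfg = sim.SimConfig(
                n_genes=300, module_sizes={"III_opposed": 80},
                lib_size_target=2e6, low_expression_frac=0.0,
                n_immune=0, n_stress=0, n_random_terms=0, seed=400 + seed,
            )
            cm, design, truths, _ = sim.simulate_experiment(cfg)
            em = pre.log_cpm(cm, pre.tmm_normalize(cm))
            genes = [g for g in truths[0].gene_ids if g in em.gene_ids]
            e = eg.module_eigengene(em, genes)
            row = eg.eigengene_anova(e, design)
            hits += row["p_interaction"] < 0.01
        assert hits >= 9


class TestClassifyResponse:
    @staticmethod
    def _eigengene_from_deltas(d4k, d7k, d4m, d7m, noise=0.02, seed=0):
        """Synthetic eigengene with prescribed shifts in pooled-SD units."""
        design = make_design()
        rng = np.random.default_rng(seed)
        shift = {
            ("kauai", "control"): 0.0, ("kauai", "day4"): d4k, ("kauai", "day7"): d7k,
            ("mangaia", "control"): 0.0, ("mangaia", "day4"): d4m,
            ("mangaia", "day7"): d7m,
        }
        # noise centered within each cell: group means are exactly the
        # prescribed shifts and the pooled within-group SD is ~1, so the
        # deltas are in pooled-SD units up to a small ddof factor
        noise_vals = rng.normal(size=18).reshape(6, 3)
        noise_vals -= noise_vals.mean(axis=1, keepdims=True)
        noise_vals /= noise_vals.std()
        scores = pd.Series(
            [
                shift[(p, s)] + noise * noise_vals.flat[i]
                for i, (p, s) in enumerate(
                    zip(design.table["population"], design.table["infestation"])
                )
            ],
            index=design.sample_ids,
        )
        return eg.Eigengene("m", scores, 0.9, pd.Series(dtype=float)), design

    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ((1.0, 8.0, 0.5, 3.2), "I"),      # same sign, ratio 2.5
            ((4.0, 8.0, 0.0, 0.0), "II"),     # single-population response
            ((3.0, 6.0, -3.0, -6.0), "III"),  # opposed
            ((8.0, 0.0, 0.0, 8.0), "IV"),     # timing swap
            ((4.0, 8.0, 4.0, 7.0), "shared"),
            ((0.0, 0.0, 0.0, 0.0), "none"),
        ],
    )
    def test_rule_table(self, deltas, expected):
        e, design = self._eigengene_from_deltas(*deltas, seed=3)
        assert eg.classify_response(e, design) == expected

    def test_planted_categories_recovered_across_seeds(self):
        """Every planted category classified to truth in >=80% of seeds."""
        per_category = {}
        n_seeds = 12
        for seed in range(n_seeds):
            cm, design, truths, _ = sim.simulate_experiment(sim.fixture_config(seed))
            cm = pre.filter_low_expression(cm)
            em = pre.log_cpm(cm, pre.tmm_normalize(cm))
            for mt in truths:
                genes = [g for g in mt.gene_ids if g in em.gene_ids]
                e = eg.module_eigengene(em, genes, mt.module_id)
                got = eg.classify_response(e, design)
                want = sim.EXPECTED_CLASS[mt.category]
                per_category.setdefault(mt.category, []).append(got == want)
        for cat, hits in per_category.items():
            assert np.mean(hits) >= 0.8, (cat, hits)
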