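"""Synthetic two-population infestation experiments with planted structure.

The generator emulates the study design the pipeline targets: 18 pooled
RNA-seq libraries = 2 populations (kauai, mangaia) x 3 infestation stages
(control, day4, day7) x 3 replicates, negative-binomial counts, planted
coexpression modules with population-by-infestation response profiles, and
labelled "immune" / "stress" annotation sets. Every planted feature is
returned as explicit ground truth so each downstream stage has a
recoverable target.

Counts are drawn as NB(mean = CPM * lib_size / 1e6, dispersion phi_g) with
log2 CPM = baseline + group shift + loading * latent factor. Each module
shares one Gaussian latent factor per sample, centered within design cells
(it models residual coexpression orthogonal to treatment) and scaled with
common-sign per-gene loadings so that the target within-module correlation
is achieved on the log-CPM scale - and so that planted modules are
recoverable by a signed-hybrid network, which zeroes negative correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    DesignTable,
    GeneSetMap,
    UNASSIGNED,
    ValidationError,
)
from .diffexpr import CELL_ORDER
from . import io as snio

log = logging.getLogger("stabnet")

LN2 = np.log(2.0)

#: Planted response categories and their expected classifier output.
EXPECTED_CLASS = {
    "shared_up": "shared",
    "shared_down": "shared",
    "I_amplified": "I",
    "II_one_population": "II",
    "III_opposed": "III",
    "IV_timing": "IV",
}

#: Mean log2 shifts per design cell (CELL_ORDER: kauai c/d4/d7, mangaia
#: c/d4/d7), scaled by ``effect_scale``. Chosen so day-7 responses span the
#: qualitative taxonomy: equal (shared), 2.5x amplified (I), single
#: population (II), opposed (III) and timing-swapped (IV).
CATEGORY_PROFILES = {
    "shared_up": np.array([0.0, 1.0, 1.8, 0.0, 1.0, 1.8]),
    "shared_down": np.array([0.0, -1.0, -1.8, 0.0, -1.0, -1.8]),
    "I_amplified": np.array([0.0, 1.0, 2.0, 0.0, 0.4, 0.8]),
    "II_one_population": np.array([0.0, 1.0, 2.0, 0.0, 0.0, 0.0]),
    "III_opposed": np.array([0.0, 0.7, 1.5, 0.0, -0.7, -1.5]),
    "IV_timing": np.array([0.0, 1.8, 0.0, 0.0, 0.0, 1.8]),
}


@dataclass
class ModuleTruth:
    module_id: str
    gene_ids: tuple
    category: str
    effect_profile: np.ndarray  # mean log2 shift per design cell
    within_module_cor: float


@dataclass
class AnnotationTruth:
    term_id: str
    term_name: str
    gene_ids: tuple


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults reflect the emulated design: ~10^4 genes, 18 libraries in six
    cells of three, lognormal per-gene NB dispersion around 0.1, library
    sizes varying +/-30% around the nominal depth (the simulated genes are
    a subset of the transcriptome, so realized column sums fall below the
    nominal depth in proportion to total simulated CPM), six planted
    modules (two shared
    plus one per response category) among a majority of unstructured noise
    genes, and module sizes spanning the tested range.
    """

    n_genes: int = 10000
    samples_per_group: int = 3
    module_sizes: dict = field(
        default_factory=lambda: {
            "shared_up": 400,
            "shared_down": 300,
            "I_amplified": 350,
            "II_one_population": 250,
            "III_opposed": 150,
            "IV_timing": 40,
        }
    )
    within_module_cor: float = 0.8
    effect_scale: float = 1.0
    baseline_logcpm_mean: float = 4.0
    baseline_logcpm_sd: float = 1.5
    low_expression_frac: float = 0.08  # noise genes from a near-silent tail
    low_expression_mean: float = -6.0
    dispersion: float = 0.1
    dispersion_sigma: float = 0.3
    lib_size_target: float = 5e6
    lib_size_spread: float = 0.30
    frac_de_noise: float = 0.05
    de_noise_scale: float = 1.2
    n_immune: int = 67
    n_stress: int = 309
    n_random_terms: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("NB dispersion must be > 0")
        if not 0 <= self.within_module_cor < 1:
            raise ValidationError("within_module_cor must be in [0, 1)")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValidationError("module sizes exceed n_genes")


def fixture_config(seed: int = 0) -> SimConfig:
    """Desk-scale fixture: 2,000 genes, same design, 40% module genes."""
    return SimConfig(
        n_genes=2000,
        module_sizes={
            "shared_up": 300,
            "shared_down": 150,
            "I_amplified": 120,
            "II_one_population": 90,
            "III_opposed": 80,
            "IV_timing": 60,
        },
        lib_size_target=2e6,
        seed=seed,
    )


def null_config(n_genes: int = 2000, seed: int = 0, dispersion: float = 0.1) -> SimConfig:
    """No planted effects and no coexpression: calibration conditions."""
    return SimConfig(
        n_genes=n_genes,
        module_sizes={},
        within_module_cor=0.0,
        effect_scale=0.0,
        frac_de_noise=0.0,
        dispersion=dispersion,
        lib_size_target=2e6,
        n_immune=0,
        n_stress=0,
        n_random_terms=0,
        seed=seed,
    )


def _design(cfg: SimConfig) -> DesignTable:
    rows = []
    for pop, stage in CELL_ORDER:
        for r in range(1, cfg.samples_per_group + 1):
            rows.append((f"{pop}_{stage}_{r}", pop, stage))
    df = pd.DataFrame(rows, columns=["sample_id", "population", "infestation"])
    return DesignTable(df.set_index("sample_id"))


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[CountMatrix, DesignTable, list[ModuleTruth], list[AnnotationTruth]]:
    """Draw one synthetic experiment with full ground truth."""
    rng = np.random.default_rng(cfg.seed)
    design = _design(cfg)
    n_samples = len(design.sample_ids)
    cell_index = np.array(
        [CELL_ORDER.index((p, s)) for p, s in
         zip(design.table["population"], design.table["infestation"])]
    )

    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    lib_sizes = cfg.lib_size_target * rng.uniform(
        1.0 - cfg.lib_size_spread, 1.0 + cfg.lib_size_spread, size=n_samples
    )
    baseline = rng.normal(cfg.baseline_logcpm_mean, cfg.baseline_logcpm_sd, cfg.n_genes)
    phi = np.exp(rng.normal(np.log(cfg.dispersion), cfg.dispersion_sigma, cfg.n_genes))

    # planted module membership: leading genes, in declaration order
    truth_label = np.full(cfg.n_genes, UNASSIGNED, dtype=object)
    module_truths: list[ModuleTruth] = []
    cursor = 0
    for mi, (category, size) in enumerate(cfg.module_sizes.items(), start=1):
        idx = np.arange(cursor, cursor + size)
        cursor += size
        truth_label[idx] = f"T{mi}"
        module_truths.append(
            ModuleTruth(
                module_id=f"T{mi}",
                gene_ids=tuple(gene_ids[idx]),
                category=category,
                effect_profile=CATEGORY_PROFILES[category] * cfg.effect_scale,
                within_module_cor=cfg.within_module_cor,
            )
        )

    # group shifts (genes x samples), on the log2-CPM scale
    shift = np.zeros((cfg.n_genes, n_samples))
    for mt in module_truths:
        idx = np.flatnonzero(np.isin(gene_ids, mt.gene_ids))
        gene_factor = np.clip(rng.normal(1.0, 0.15, idx.size), 0.5, 1.5)
        shift[idx] = gene_factor[:, None] * mt.effect_profile[cell_index][None, :]

    # a near-silent tail among noise genes exercises the CPM filter
    noise_idx = np.flatnonzero(truth_label == UNASSIGNED)
    n_low = int(round(cfg.low_expression_frac * noise_idx.size))
    if n_low:
        low_idx = rng.choice(noise_idx, size=n_low, replace=False)
        baseline[low_idx] = rng.normal(cfg.low_expression_mean, 1.5, n_low)

    # scattered DE noise genes: independent random stage responses
    n_de_noise = int(round(cfg.frac_de_noise * noise_idx.size))
    if n_de_noise and cfg.effect_scale > 0:
        de_idx = rng.choice(noise_idx, size=n_de_noise, replace=False)
        profiles = rng.normal(0.0, cfg.de_noise_scale, size=(n_de_noise, len(CELL_ORDER)))
        profiles[:, [0, 3]] = 0.0  # controls at baseline
        shift[de_idx] = profiles[:, cell_index]

    # per-module latent factors, centered within design cells. The target
    # within-module correlation counts BOTH correlation sources: the shared
    # treatment profile and the latent factor; the latent loading supplies
    # only the remainder, so strongly responding modules carry little extra
    # residual covariance (cor_ij ~ (a_i a_j + l_i l_j) / prod of total SDs
    # with a_g the gene's treatment-signal SD and l_g its latent loading).
    log2cpm = baseline[:, None] + shift
    if cfg.within_module_cor > 0:
        rho = cfg.within_module_cor
        mean_count = 2.0**baseline / 1e6 * lib_sizes.mean()
        noise_var = (1.0 / np.maximum(mean_count, 1e-8) + phi) / LN2**2
        for mt in module_truths:
            idx = np.flatnonzero(np.isin(gene_ids, mt.gene_ids))
            signal_var = shift[idx].var(axis=1)
            lam = np.sqrt(
                np.maximum(rho / (1.0 - rho) * noise_var[idx] - signal_var, 0.0)
            )
            f = rng.normal(size=n_samples)
            for c in np.unique(cell_index):
                cell = cell_index == c
                f[cell] -= f[cell].mean()
            sd = f.std()
            if sd > 0:
                f /= sd
            log2cpm[idx] += lam[:, None] * f[None, :]

    mu = 2.0**log2cpm / 1e6 * lib_sizes[None, :]
    lam = rng.gamma(shape=1.0 / phi[:, None], scale=mu * phi[:, None])
    counts = rng.poisson(lam).astype(np.int64)
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=design.sample_ids))

    annotations = _annotations(cfg, rng, gene_ids, module_truths)
    return cm, design, module_truths, annotations


def _annotations(
    cfg: SimConfig, rng, gene_ids: np.ndarray, module_truths: list[ModuleTruth]
) -> list[AnnotationTruth]:
    """Immune / stress / random annotation sets.

    The immune set is planted to coincide with the amplified-response
    module where possible (filled with random genes if that module is
    smaller), emulating an annotation concentrated in one module; stress
    and the random terms are uniform draws.
    """
    out: list[AnnotationTruth] = []
    if cfg.n_immune > 0:
        host = next(
            (mt for mt in module_truths if mt.category == "I_amplified"),
            module_truths[0] if module_truths else None,
        )
        immune: list[str] = []
        if host is not None:
            immune = list(host.gene_ids[: cfg.n_immune])
        if len(immune) < cfg.n_immune:
            pool = np.setdiff1d(gene_ids, np.array(immune, dtype=object))
            extra = rng.choice(pool, size=cfg.n_immune - len(immune), replace=False)
            immune.extend(extra.tolist())
        out.append(
            AnnotationTruth("immune_system_process", "immune system process", tuple(immune))
        )
    if cfg.n_stress > 0:
        stress = rng.choice(gene_ids, size=min(cfg.n_stress, len(gene_ids)), replace=False)
        out.append(
            AnnotationTruth("response_to_stress", "response to stress", tuple(stress))
        )
    for t in range(cfg.n_random_terms):
        size = int(rng.integers(30, 151))
        genes = rng.choice(gene_ids, size=size, replace=False)
        out.append(AnnotationTruth(f"random_{t}", f"random term {t}", tuple(genes)))
    return out


def truth_table(module_truths: list[ModuleTruth], gene_ids) -> pd.DataFrame:
    """Per-gene truth table (gene_id, module_id, category); noise unassigned."""
    label = pd.Series(UNASSIGNED, index=pd.Index(gene_ids, name="gene_id"))
    category = pd.Series(UNASSIGNED, index=label.index)
    for mt in module_truths:
        present = [g for g in mt.gene_ids if g in label.index]
        label[present] = mt.module_id
        category[present] = mt.category
    return pd.DataFrame({"module_id": label, "category": category})


def annotation_map(annotations: list[AnnotationTruth]) -> GeneSetMap:
    return GeneSetMap.from_records(
        (a.term_id, a.term_name, g) for a in annotations for g in a.gene_ids
    )


def write_fixture(outdir, cfg: SimConfig | None = None) -> dict:
    """Simulate one experiment and write it in the pipeline's file formats."""
    cfg = cfg or fixture_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, design, module_truths, annotations = simulate_experiment(cfg)
    snio.write_counts(cm, outdir / "counts.tsv")
    snio.write_design(design, outdir / "design.tsv")
    snio.write_gene_sets(annotation_map(annotations), outdir / "annotation.tsv")
    snio.write_table(
        truth_table(module_truths, cm.gene_ids), outdir / "truth.tsv", index_label="gene_id"
    )
    return {
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
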