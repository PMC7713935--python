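"""End-to-end pipeline runner with a reproducibility manifest.

Runs the eight stages (simulate, preprocess, de, network, consensus,
eigengene, ordinate, enrich) from one YAML-able configuration, writing
deterministic TSV/JSON outputs per stage plus a manifest with the master
seed, the full parameter set and per-file checksums. Stage seeds are
derived from the master seed by fixed offsets so stages can be re-run
independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import consensus as cns
from . import diffexpr as de
from . import eigengenes as eg
from . import enrichment as enr
from . import io as snio
from . import network as net
from . import ordination as ordn
from . import preprocess as pre
from . import simulate as sim
from .containers import ValidationError

log = logging.getLogger("stabnet")

STAGES = [
    "simulate", "preprocess", "de", "network",
    "consensus", "eigengene", "ordinate", "enrich",
]

#: Fixed per-stage seed offsets from the master seed.
STAGE_SEED_OFFSET = {name: 1000 + i for i, name in enumerate(STAGES)}

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"preset": "fixture"},  # or explicit SimConfig fields
    "preprocess": {"min_cpm": 1.0, "min_samples": 2, "prior_count": 0.5,
                   "drop_fraction": 0.40},
    "de": {"prior_df": 10.0, "fdr": 0.05},
    "network": {"power": None, "min_module_size": 30, "deep_split": 2,
                "merge_cut_height": 0.15, "max_block_size": 10000},
    "consensus": {"n_boot": 250, "overlap_frac": 0.10, "reliability": 0.70,
                  "merge_r": 0.85, "min_size": 30},
    "eigengene": {"eps": 0.6, "ratio": 2.0},
    "ordinate": {"k": 4, "n_starts": 20, "n_perm": 1000},
    "enrich": {"min_term_size": 3, "sig_mode": "raw", "alpha": 0.05},
}


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSET[stage]) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, outdir, counts_path=None, design_path=None,
                 gene_sets_path=None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    Without an input ``counts_path`` the simulate stage generates the
    synthetic experiment; with explicit inputs the simulate stage only
    records their provenance.
    """
    cfg = _merge_config(config)
    if cfg["consensus"]["n_boot"] < 1:
        raise ValidationError("bootstrap requires >=1 replicate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "files": {}}
    t0 = time.time()

    def done(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "elapsed_s": round(time.time() - t0, 3),
        }
        for f in files:
            manifest["files"][f.name] = _checksum(f)
        log.info("stage %s complete (%.1fs)", stage, time.time() - t0)

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # -- simulate ----------------------------------------------------------
    try:
        if counts_path is None:
            sim_cfg = dict(cfg["simulate"])
            preset = sim_cfg.pop("preset", "fixture")
            base = (
                sim.fixture_config(stage_seed(seed, "simulate"))
                if preset == "fixture"
                else sim.SimConfig(seed=stage_seed(seed, "simulate"))
            )
            for k, v in sim_cfg.items():
                setattr(base, k, v)
            files = sim.write_fixture(outdir, base)
            counts_path = files["counts"]
            design_path = files["design"]
            gene_sets_path = files["annotation"]
            done("simulate", [Path(p) for p in files.values()])
        else:
            manifest["stages"]["simulate"] = {
                "status": "complete", "note": "external inputs",
                "elapsed_s": round(time.time() - t0, 3),
            }
        cm = snio.read_counts(counts_path)
        design = snio.read_design(design_path).reindex(cm.sample_ids)
        gene_sets = snio.read_gene_sets(gene_sets_path) if gene_sets_path else None
    except RuntimeError:
        raise
    except Exception as e:
        fail("simulate", e)

    # -- preprocess --------------------------------------------------------
    try:
        p = cfg["preprocess"]
        cm_f = pre.filter_low_expression(cm, p["min_cpm"], p["min_samples"])
        nf = pre.tmm_normalize(cm_f)
        em = pre.log_cpm(cm_f, nf, p["prior_count"])
        em_net = pre.variance_prefilter(em, p["drop_fraction"])
        snio.write_counts(cm_f, outdir / "filtered_counts.tsv")
        nf.to_frame().to_csv(outdir / "norm_factors.tsv", sep="\t",
                             index_label="sample_id")
        snio.write_expression(em, outdir / "log_cpm.tsv")
        snio.write_expression(em_net, outdir / "log_cpm_prefiltered.tsv")
        done("preprocess", [outdir / "filtered_counts.tsv", outdir / "norm_factors.tsv",
                            outdir / "log_cpm.tsv", outdir / "log_cpm_prefiltered.tsv"])
    except Exception as e:
        fail("preprocess", e)

    # -- de ----------------------------------------------------------------
    try:
        disp = de.estimate_dispersions(cm_f, design, cfg["de"]["prior_df"], nf)
        tables = de.run_contrasts(cm_f, nf, design, disp)
        de_files = []
        for name, tab in tables.items():
            path = outdir / f"de_{name}.tsv"
            snio.write_table(tab.round(10), path, index_label="gene_id")
            de_files.append(path)
        venn = de.venn_partition(
            tables["kauai_day7_vs_control"], tables["mangaia_day7_vs_control"],
            cfg["de"]["fdr"],
        )
        snio.write_json(venn, outdir / "venn_summary.json")
        de_files.append(outdir / "venn_summary.json")
        done("de", de_files)
    except Exception as e:
        fail("de", e)

    # -- network -----------------------------------------------------------
    try:
        ncfg = cfg["network"]
        params = net.NetworkParams(
            power=ncfg["power"], min_module_size=ncfg["min_module_size"],
            deep_split=ncfg["deep_split"], merge_cut_height=ncfg["merge_cut_height"],
            max_block_size=ncfg["max_block_size"],
        )
        assignment, info = net.blockwise_modules(
            em_net, params, stage_seed(seed, "network")
        )
        assignment.labels.to_frame("module_label").to_csv(
            outdir / "modules.tsv", sep="\t", index_label="gene_id"
        )
        snio.write_json(info, outdir / "network_params.json")
        done("network", [outdir / "modules.tsv", outdir / "network_params.json"])
    except Exception as e:
        fail("network", e)

    # -- consensus ---------------------------------------------------------
    try:
        ccfg = cfg["consensus"]
        boot_params = net.NetworkParams(
            power=info["power"], min_module_size=ncfg["min_module_size"],
            deep_split=ncfg["deep_split"], merge_cut_height=ncfg["merge_cut_height"],
        )
        cres = cns.run_consensus(
            em_net, assignment, boot_params,
            n_boot=ccfg["n_boot"], overlap_frac=ccfg["overlap_frac"],
            reliability=ccfg["reliability"], merge_r=ccfg["merge_r"],
            min_size=ccfg["min_size"], seed=stage_seed(seed, "consensus"),
        )
        pd.DataFrame(
            {"original_label": cres.original, "final_label": cres.final,
             "reliability": cres.reliability}
        ).to_csv(outdir / "consensus_modules.tsv", sep="\t", index_label="gene_id")
        snio.write_json(cres.audit, outdir / "consensus_audit.json")
        done("consensus", [outdir / "consensus_modules.tsv",
                           outdir / "consensus_audit.json"])
    except Exception as e:
        fail("consensus", e)

    # -- eigengene ---------------------------------------------------------
    try:
        final_assignment = cres.assignment
        if final_assignment.module_names():
            table = eg.categorize_modules(
                em_net, final_assignment, design,
                cfg["eigengene"]["eps"], cfg["eigengene"]["ratio"],
            )
            egs = eg.all_eigengenes(em_net, final_assignment)
            pd.DataFrame({m: e.scores for m, e in egs.items()}).T.to_csv(
                outdir / "eigengenes.tsv", sep="\t", index_label="module_id"
            )
        else:
            table = pd.DataFrame()
            (outdir / "eigengenes.tsv").write_text("module_id\n")
        snio.write_table(table.round(10), outdir / "module_anova.tsv",
                         index_label="module_id")
        done("eigengene", [outdir / "eigengenes.tsv", outdir / "module_anova.tsv"])
    except Exception as e:
        fail("eigengene", e)

    # -- ordinate ----------------------------------------------------------
    try:
        ocfg = cfg["ordinate"]
        lib_eff = cm_f.lib_sizes * nf
        abundance = (cm_f.counts / lib_eff.to_numpy() * 1e6).T
        d = ordn.bray_curtis(abundance)
        mds = ordn.nmds(d, k=ocfg["k"], n_starts=ocfg["n_starts"],
                        seed=stage_seed(seed, "ordinate"))
        ptab = ordn.permanova(d, design, n_perm=ocfg["n_perm"],
                              seed=stage_seed(seed, "ordinate"))
        mds.coordinates.to_csv(outdir / "coordinates.tsv", sep="\t",
                               index_label="sample_id")
        snio.write_json(
            {"stress": mds.stress, "k": ocfg["k"], "converged": bool(mds.converged)},
            outdir / "stress.json",
        )
        snio.write_table(ptab.round(10), outdir / "permanova.tsv", index_label="term")
        done("ordinate", [outdir / "coordinates.tsv", outdir / "stress.json",
                          outdir / "permanova.tsv"])
    except Exception as e:
        fail("ordinate", e)

    # -- enrich ------------------------------------------------------------
    try:
        ecfg = cfg["enrich"]
        enrich_files = []
        if gene_sets is not None:
            universe = list(cm_f.gene_ids)
            for m in cres.assignment.module_names():
                selected = list(cres.assignment.members(m))
                tab = enr.fisher_enrichment(
                    selected, gene_sets, universe,
                    ecfg["min_term_size"], ecfg["sig_mode"], ecfg["alpha"],
                )
                path = outdir / f"enrichment_{m}.tsv"
                snio.write_table(tab.round(10), path, index_label="term_id")
                enrich_files.append(path)
        done("enrich", enrich_files)
    except Exception as e:
        fail("enrich", e)

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    snio.write_json(manifest, outdir / "manifest.json")
    return manifest
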