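"""Shared fixtures: one deterministic synthetic experiment per session.

The heavyweight objects (the 2,000-gene fixture experiment, its
preprocessed expression, the original network and the 50-replicate
bootstrap runs) are computed once and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stabnet import consensus as cns
from stabnet import network as net
from stabnet import preprocess as pre
from stabnet import simulate as sim
from stabnet.containers import DesignTable

FIXTURE_SEED = 1
BOOT_SEED = 11
N_BOOT = 50


@pytest.fixture(scope="session")
def experiment():
    """(CountMatrix, DesignTable, module truths, annotation truths)."""
    return sim.simulate_experiment(sim.fixture_config(FIXTURE_SEED))


@pytest.fixture(scope="session")
def preprocessed(experiment):
    """(filtered counts, norm factors, log-CPM, prefiltered log-CPM)."""
    cm, design, truths, anns = experiment
    cm_f = pre.filter_low_expression(cm)
    nf = pre.tmm_normalize(cm_f)
    em = pre.log_cpm(cm_f, nf)
    em_net = pre.variance_prefilter(em, 0.40)
    return cm_f, nf, em, em_net


@pytest.fixture(scope="session")
def network_run(preprocessed):
    """(ModuleAssignment, info dict) for the fixture's original network."""
    _, _, _, em_net = preprocessed
    return net.blockwise_modules(em_net, net.NetworkParams(), seed=7)


@pytest.fixture(scope="session")
def bootstrap_runs(preprocessed, network_run):
    """50 bootstrap networks at the original parameters (shared, slow)."""
    _, _, _, em_net = preprocessed
    _, info = network_run
    params = net.NetworkParams(power=info["power"])
    return cns.bootstrap_networks(em_net, params, n_boot=N_BOOT, seed=BOOT_SEED)


@pytest.fixture(scope="session")
def truth_labels(experiment):
    cm, _, truths, _ = experiment
    return sim.truth_table(truths, cm.gene_ids)["module_id"]


def make_design(n_per_group: int = 3) -> DesignTable:
    """Balanced 2 x 3 design with ``n_per_group`` samples per cell."""
    rows = []
    for pop in ("kauai", "mangaia"):
        for stage in ("control", "day4", "day7"):
            for r in range(1, n_per_group + 1):
                rows.append((f"{pop}_{stage}_{r}", pop, stage))
    df = pd.DataFrame(rows, columns=["sample_id", "population", "infestation"])
    return DesignTable(df.set_index("sample_id"))
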