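"""Shared fixtures: the reference synthetic study and cheap derived products.

Heavy objects (the default two-tissue simulation, normalized layers,
marker tables, clustering) are session-scoped so the acceptance-style
tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gutniche import markers as mk
from gutniche import preprocess as pp
from gutniche.io import CellLabels
from gutniche.simulate import SimConfig, simulate_two_tissue


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions: 8 shared + 3/2 specific types,
    300 cells/type, 30 markers at 8-fold, seed 1."""
    cfg = SimConfig(seed=1)
    cm_a, cm_b, truth = simulate_two_tissue(cfg)
    return cfg, cm_a, cm_b, truth


@pytest.fixture(scope="session")
def processed(default_sim):
    """QC-filtered log-CPM layers plus true-type labels per tissue."""
    _, cm_a, cm_b, truth = default_sim
    out = {}
    for cm, tissue in ((cm_a, "stomach"), (cm_b, "intestine")):
        params = pp.QCParams.for_tissue(tissue)
        filt = pp.filter_counts(cm, params)
        expr = pp.normalize_cpm_log(filt)["log_cpm"]
        keep = [cm.cell_ids.index(c) for c in filt.cell_ids]
        tl = truth.cell_type[tissue][keep]
        out[tissue] = {
            "filtered": filt,
            "expr": expr,
            "truth": tl,
            "labels": CellLabels(cell_ids=filt.cell_ids, cluster=tl),
            "params": params,
        }
    return out


@pytest.fixture(scope="session")
def marker_tables(processed):
    """Bimodal-LRT marker tables per tissue on true-type labels."""
    return {
        t: mk.marker_table(processed[t]["expr"], processed[t]["labels"])
        for t in ("stomach", "intestine")
    }


@pytest.fixture(scope="session")
def small_sim():
    """A fast, low-dimensional simulation for structural unit tests."""
    cfg = SimConfig(
        n_genes=300,
        shared_types=3,
        specific_types_per_tissue=(1, 1),
        cells_per_type=60,
        markers_per_type=10,
        seed=7,
    )
    cm_a, cm_b, truth = simulate_two_tissue(cfg)
    return cfg, cm_a, cm_b, truth


@pytest.fixture(scope="session")
def small_processed(small_sim):
    _, cm_a, cm_b, truth = small_sim
    out = {}
    for cm, tissue in ((cm_a, "stomach"), (cm_b, "intestine")):
        params = pp.QCParams.for_tissue(tissue, min_genes_per_cell=20)
        filt = pp.filter_counts(cm, params)
        expr = pp.normalize_cpm_log(filt)["log_cpm"]
        keep = [cm.cell_ids.index(c) for c in filt.cell_ids]
        tl = truth.cell_type[tissue][keep]
        out[tissue] = {
            "filtered": filt,
            "expr": expr,
            "truth": tl,
            "labels": CellLabels(cell_ids=filt.cell_ids, cluster=tl),
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
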