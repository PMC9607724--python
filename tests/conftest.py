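"""Shared fixtures: small seeded simulations and hand-built references."""

import numpy as np
import pytest

from bcrcoherence.repio import CellRecord, ChainAnnotation
from bcrcoherence.synthetic import PublicPlan, SimulationConfig, simulate_repertoire


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_donors=4,
        naive_per_donor=150,
        memory_per_donor=150,
        public=PublicPlan(n_keys=12, donors_per_key=4, copies_per_donor=2,
                          p_coherent=0.8),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_repertoire(small_config)


@pytest.fixture(scope="session")
def tiny_reference():
    """A deterministic 2-donor-scale germline set for fixture construction."""
    config = SimulationConfig(seed=7, n_v_heavy=6, n_d_heavy=4, n_j_heavy=3,
                              n_v_light=8, n_j_light=3)
    from bcrcoherence.synthetic import simulate_germline_set

    return simulate_germline_set(config, np.random.default_rng(7))


def make_cell(
    cell_id="c1",
    donor="d1",
    heavy_v="IGHV1-1",
    heavy_j="IGHJ1",
    light_v="IGKV1-1",
    light_j="IGKJ1",
    cdrh3_aa="CARDYW",
    cdrl3_aa="CQQYW",
    heavy_junction_nt=None,
    light_junction_nt=None,
    cell_class="memory",
    dataset="ds1",
    clonotype=None,
):
    """Minimal cell for pair/grouping logic tests (no full-length sequences)."""
    h_nt = heavy_junction_nt or "".join("GCA" for _ in cdrh3_aa)
    l_nt = light_junction_nt or "".join("GCA" for _ in cdrl3_aa)
    return CellRecord(
        cell_id=cell_id,
        donor_id=donor,
        dataset_id=dataset,
        heavy=ChainAnnotation(
            locus="IGH", v_gene=heavy_v, j_gene=heavy_j,
            junction_nt=h_nt, junction_aa=cdrh3_aa,
        ),
        light=ChainAnnotation(
            locus="IGK", v_gene=light_v, j_gene=light_j,
            junction_nt=l_nt, junction_aa=cdrl3_aa,
        ),
        cell_class=cell_class,
        clonotype_id=clonotype,
    )
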