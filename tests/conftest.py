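import numpy as np
import pandas as pd
import pytest

import mrmediate as mm
from mrmediate.instruments import HARMONIZED_COLUMNS, HarmonizedSet


def make_harmonized(beta_exp, beta_out, se_out, se_exp=None, snp_ids=None,
                    name="exposure", outcome="outcome") -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.asarray(se_exp, dtype=float)
    n = len(beta_exp)
    if snp_ids is None:
        snp_ids = [f"rs{i:04d}" for i in range(n)]
    table = pd.DataFrame({
        "snp_id": snp_ids, "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "eaf_exp": np.full(n, 0.3), "eaf_out": np.full(n, 0.3),
        "flipped": np.zeros(n, dtype=bool),
    }, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(name, outcome, table)


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture(scope="session")
def clean_panel():
    """Pleiotropy-free seeded panel at large n with the study-scale chain."""
    cfg = mm.SimulationConfig(
        seed=1, n_exposure=100_000, n_mediator=100_000, n_outcome=100_000,
        true_beta_exp_med=0.115, true_beta_med_out=0.0225 / 0.115,
        true_direct_exp_out=0.225 - 0.0225,
    )
    return mm.simulate_panel(cfg)


@pytest.fixture(scope="session")
def clean_harmonized(clean_panel):
    inst = mm.select_instruments(clean_panel.exposure, clean_panel.ld)
    return mm.harmonize(inst, clean_panel.outcome)


def make_variant(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.1, se=0.01, pval=1e-8, n=10_000) -> mm.VariantAssociation:
    return mm.VariantAssociation(snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


@pytest.fixture
def variant_factory():
    return make_variant
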