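import numpy as np
import pandas as pd
import pytest

from tardilfq.simulate import SimConfig, simulate_proteome


@pytest.fixture(scope="session")
def null_world():
    """Default-design simulation with no spiked effects (seed 11)."""
    return simulate_proteome(SimConfig(n_proteins=200, seed=11))


@pytest.fixture(scope="session")
def spiked_world():
    """Small world with treatment-only and confounded spike-ins (seed 5)."""
    cfg = SimConfig(
        n_proteins=200,
        frac_treatment_up=0.05,
        frac_treatment_down=0.05,
        frac_confounded=0.05,
        dropout_on_spiked=False,
        seed=5,
    )
    return simulate_proteome(cfg)


@pytest.fixture(scope="session")
def noise_free_world():
    """Deterministic limit: no noise, no dropout, unit loading, no effects."""
    cfg = SimConfig(
        n_proteins=60,
        cv_biological=0.0,
        dropout=0.0,
        scale_range=(1.0, 1.0),
        seed=3,
    )
    return simulate_proteome(cfg)


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def tiny_evidence(tmp_path):
    """Three-record long evidence file."""
    return write_tsv(
        tmp_path / "evidence.tsv",
        pd.DataFrame(
            {
                "peptide": ["PEPTIDEK", "PEPTIDEK", "ACDEFGHK"],
                "run": ["run1", "run2", "run1"],
                "area": [100.0, 300.0, 50.0],
            }
        ),
    )


@pytest.fixture()
def manifest_3x3(tmp_path):
    rows = [
        {"run": f"{g}_{j}", "group": g, "replicate": j}
        for g in ("untreated", "vehicle", "treatment")
        for j in (1, 2, 3)
    ]
    return write_tsv(tmp_path / "manifest.tsv", pd.DataFrame(rows))
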