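import numpy as np
import pytest

from muscleomics import (
    IdentificationRecord,
    MetaboSimConfig,
    ProteomeSimConfig,
    simulate_metabolite_panel,
    simulate_spectral_counts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_proteome():
    """Seeded pooled proteome with strong planted effects (study conditions)."""
    cfg = ProteomeSimConfig(
        n_proteins=500, frac_up=0.1, frac_down=0.1, planted_log2fc=3.0,
        total_spectra_per_group=20_000, seed=1,
    )
    entries, truth = simulate_spectral_counts(cfg)
    return cfg, entries, truth


@pytest.fixture(scope="session")
def planted_panel():
    """Seeded 50-metabolite panel, n=9/group, three planted effects."""
    cfg = MetaboSimConfig(
        planted_effects={"Orn": 1.0, "Cit": -1.0, "C16": -1.0},
        cv_noise=0.2, n_per_group=9, seed=1,
    )
    panel, truth = simulate_metabolite_panel(cfg)
    return panel, truth


def make_record(accession="P1", group="VPG", n_peptides=3, score=50.0, spc=10):
    return IdentificationRecord(
        accession=accession, description=f"protein {accession}", gene=f"G_{accession}",
        group=group, n_peptides=n_peptides, min_peptide_score=score, spectral_count=spc,
    )
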