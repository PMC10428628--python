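import logging

import numpy as np
import pytest

import maizegp as mg

logging.getLogger("maizegp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel():
    """Complete homozygous panel: 80 lines, 400 markers, 4 chromosomes."""
    return mg.simulate_genotypes(
        n_lines=80, n_markers=400, n_chromosomes=4, fst=0.1, seed=101
    )


@pytest.fixture(scope="session")
def small_phenotypes(small_panel):
    cfg = mg.TraitConfig(replicate_sd=0.0, block_sd=0.0)
    records, truth = mg.simulate_phenotypes(
        small_panel, cfg, ("E1", "E2"), seed=102, n_replicates=1
    )
    return records, truth


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return mg.vanraden_grm(small_panel)


@pytest.fixture(scope="session")
def tiny_settings():
    return mg.MCMCSettings(n_iterations=1500, burn_in=400, thin=2, seed=7)


def make_tiny_panel(dosage, chrom=None, pos=None):
    """Hand-built panel from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return mg.GenotypePanel(
        line_ids=[f"L{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(m)],
        chromosome=np.asarray(chrom if chrom is not None else ["chr1"] * m, dtype=object),
        position_bp=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 100),
        dosage=dosage,
    )
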