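import dataclasses

import numpy as np
import pandas as pd
import pytest

from metaboage import kinship, preprocess
from metaboage.simulate import (
    DriftSpec,
    MediatorSpec,
    SimulationConfig,
    default_mediator_spec,
    simulate_genotypes,
    simulate_phenotypes,
)


def make_matrix(values: np.ndarray, **meta) -> preprocess.MetaboliteMatrix:
    """Tiny MetaboliteMatrix with defaultable technical metadata."""
    state = meta.pop("state", "raw")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id")
    defaults = {
        "batch": ["b0"] * n,
        "run": ["r0"] * n,
        "run_order": np.arange(1, n + 1),
        "hemolysis": np.zeros(n, dtype=int),
        "travel_time": np.full(n, 24.0),
        "arrival_temp": np.full(n, 18.0),
    }
    defaults.update(meta)
    cols = [f"m{j:02d}" for j in range(values.shape[1])]
    return preprocess.MetaboliteMatrix(
        pd.DataFrame(values, index=idx, columns=cols),
        pd.DataFrame(defaults, index=idx),
        state=state,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Shared small synthetic bundle: 250 dogs, 40 metabolites, 1500 SNPs."""
    cfg = SimulationConfig(
        n_dogs=250, n_metabolites=40, n_snps=1500, n_breed_blocks=4, seed=11
    )
    cfg = dataclasses.replace(
        cfg, mediator_spec=default_mediator_spec(cfg, np.random.default_rng(11))
    )
    genotypes, ancestry = simulate_genotypes(cfg)
    kin = kinship.compute_grm(kinship.filter_snps(genotypes))
    matrix, cohort, truth = simulate_phenotypes(cfg, genotypes, kin)
    return {
        "config": cfg,
        "genotypes": genotypes,
        "ancestry": ancestry,
        "kin": kin,
        "matrix": matrix,
        "cohort": cohort,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def clean_sim():
    """No drift, no missingness, no sample shifts: latent equals log(raw)."""
    cfg = SimulationConfig(
        n_dogs=300,
        n_metabolites=25,
        n_snps=1500,
        n_breed_blocks=4,
        seed=7,
        missing_rate=0.0,
        drift_spec=DriftSpec(0.0, 0.0),
        sample_shift_sd=0.0,
        mediator_spec=MediatorSpec(a=1.0, sigma_m=1.0, targets={0: (1.0, 1.0), 1: (0.0, 0.5), 2: (0.6, 0.0)}),
    )
    genotypes, _ = simulate_genotypes(cfg)
    kin = kinship.compute_grm(kinship.filter_snps(genotypes))
    matrix, cohort, truth = simulate_phenotypes(cfg, genotypes, kin)
    return {
        "config": cfg,
        "kin": kin,
        "matrix": matrix,
        "cohort": cohort,
        "truth": truth,
    }
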