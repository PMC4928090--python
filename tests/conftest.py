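"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xdiverge.countdata import CountMatrix, SampleInfo
from xdiverge.divergence import OrthologMap
from xdiverge.simulate import SimulationConfig, simulate_counts


def two_group_design(n_per_group: int = 3) -> np.ndarray:
    n = 2 * n_per_group
    return np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n_per_group)])


def nb_draws(rng, mu, phi, size=None):
    """NB(mu, phi) variates (Poisson when phi == 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


@pytest.fixture(scope="session")
def small_bundle():
    """A 400-pair synthetic study with 10% planted divergence."""
    cfg = SimulationConfig(seed=3, n_pairs=400, fraction_divergent=0.10)
    counts_a, counts_b, samples, truth = simulate_counts(cfg)
    omap = OrthologMap(
        pd.DataFrame({"gene_a": list(counts_a.gene_ids), "gene_b": list(counts_b.gene_ids)})
    )
    return {"cfg": cfg, "counts_a": counts_a, "counts_b": counts_b,
            "samples": samples, "truth": truth, "orthologs": omap}


@pytest.fixture(scope="session")
def fitted_divergence(small_bundle):
    from xdiverge.divergence import DivergenceModel

    model = DivergenceModel.from_counts(
        small_bundle["counts_a"], small_bundle["counts_b"],
        small_bundle["orthologs"], control="28C",
    )
    return model.fit()


def toy_count_matrix(counts: np.ndarray, conditions: list[str], species: str = "A"):
    reps: dict[str, int] = {}
    samples = []
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        samples.append(SampleInfo(f"{species}_{c}_r{reps[c]}", species, c, reps[c]))
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(counts, samples, genes)
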