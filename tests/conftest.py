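import numpy as np
import pandas as pd
import pytest

from thermomethyl import simulate as sim

SIX = list("abcdef")
DESIGN6 = {s: ("control" if i < 3 else "treatment") for i, s in enumerate(SIX)}


@pytest.fixture(scope="session")
def study_sim():
    """Default-sized synthetic study (2k genes, ~22k sites, n=3/group).

    Session-scoped: the planted-truth recovery checks all read from the
    same realisation.
    """
    cfg = sim.SimulationConfig(seed=11)
    genes, chrom_sizes = sim.simulate_annotation(cfg)
    meth, truth = sim.simulate_methylrad_counts(cfg, genes, chrom_sizes)
    em, truth = sim.simulate_rnaseq_counts(cfg, genes, truth)
    return {
        "cfg": cfg,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "meth": meth,
        "expression": em,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down config for fast structural/end-to-end checks."""
    return sim.SimulationConfig(
        seed=5,
        n_chroms=4,
        chrom_size=1_200_000,
        n_genes=200,
        n_cg_sites=2000,
        n_cwg_sites=200,
        n_coupled_pos=3,
        n_coupled_neg=2,
    )


def nb_matrix(rng, n_features, mean, dispersion, n_per_group=3, lfc=None):
    """Direct NB count matrix helper for null/planted simulations."""
    samples = [f"c{i}" for i in range(n_per_group)] + [
        f"t{i}" for i in range(n_per_group)
    ]
    design = {s: ("control" if s.startswith("c") else "treatment") for s in samples}
    mu = np.full(n_features, float(mean))
    counts = np.empty((n_features, 2 * n_per_group), dtype=int)
    for j, s in enumerate(samples):
        m = mu * (2.0 ** lfc if (lfc is not None and design[s] == "treatment") else 1.0)
        if dispersion <= 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + m))
    df = pd.DataFrame(
        counts, columns=samples, index=[f"f{i}" for i in range(n_features)]
    )
    return df, design
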