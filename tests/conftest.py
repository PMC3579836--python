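"""Shared fixtures: one small synthetic colony reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from kinface import (
    ResponseSimConfig,
    SimConfig,
    simulate_genotypes,
    simulate_inventory,
    simulate_pedigree,
    simulate_responses,
)
from kinface import triads as tr


@pytest.fixture(scope="session")
def colony():
    config = SimConfig(seed=1)
    pedigree, census = simulate_pedigree(config)
    return config, pedigree, census


@pytest.fixture(scope="session")
def colony_genotypes(colony):
    config, pedigree, _ = colony
    return simulate_genotypes(pedigree, config)


@pytest.fixture(scope="session")
def colony_inventory(colony):
    config, pedigree, census = colony
    return simulate_inventory(
        pedigree, census, photo_year=config.n_years + 1.0, seed=1
    )


@pytest.fixture(scope="session")
def kd_triads(colony, colony_inventory):
    _, pedigree, _ = colony
    return tr.build_kd_triads(pedigree, colony_inventory, seed=1)


@pytest.fixture(scope="session")
def id_triads(colony, colony_inventory, kd_triads):
    _, pedigree, _ = colony
    used = {i for t in kd_triads for i in (t.target, t.match, t.decoy)}
    return tr.build_id_triads(
        pedigree, colony_inventory, seed=1, exclude=sorted(used)
    )


@pytest.fixture(scope="session")
def schedules(kd_triads, id_triads):
    return {
        f"P{i:03d}": tr.randomize_session(kd_triads, id_triads, f"P{i:03d}", 100 + i)
        for i in range(30)
    }


@pytest.fixture(scope="session")
def responses_df(kd_triads, id_triads, schedules):
    return simulate_responses(
        kd_triads + id_triads, schedules, ResponseSimConfig(seed=2)
    )


def gene_drop_relatedness(
    pedigree, a: str, b: str, n_drops: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo gene-dropping estimate of r(a, b) with its standard error.

    Founders receive unique allele labels; each replicate drops one
    allele per parent down the pedigree.  The per-replicate statistic is
    half the number of matching allele pairs between the two genotypes,
    whose expectation is 2f = r for non-inbred pairs.
    """
    rng = np.random.default_rng(seed)
    order = sorted(pedigree.ids, key=pedigree.depth)
    genomes: dict[str, np.ndarray] = {}
    next_allele = 0
    for ind in order:
        g = np.empty((n_drops, 2), dtype=np.int64)
        for k, parent in enumerate(pedigree.parents(ind)):
            if parent is None:
                g[:, k] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(2, size=n_drops)
                g[:, k] = genomes[parent][np.arange(n_drops), pick]
        genomes[ind] = g
    ga, gb = genomes[a], genomes[b]
    share = (
        (ga[:, 0] == gb[:, 0]).astype(float)
        + (ga[:, 0] == gb[:, 1])
        + (ga[:, 1] == gb[:, 0])
        + (ga[:, 1] == gb[:, 1])
    ) / 2.0
    return float(share.mean()), float(share.std(ddof=1) / np.sqrt(n_drops))


def toy_pedigree(rows):
    """Build a Pedigree from (id, sex, birth, dam, sire) tuples."""
    from kinface import Pedigree

    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sex", "birth", "dam", "sire"])
    )
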