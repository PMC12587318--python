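"""Shared fixtures: hand-built toy pedigrees and clustered pair tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinconfound import Pedigree, TransmissionParams, simulate_pedigree, simulate_wealth


def build_pedigree(rows, generations, params=None, measures=("status",)):
    """Build a Pedigree from (id, father, mother, sex, birth_year, surname,
    generation, status) tuples; latent columns are filled with the status
    value (T = status, E = 0) unless given."""
    df = pd.DataFrame(
        rows,
        columns=[
            "id", "father_id", "mother_id", "sex", "birth_year",
            "surname", "generation", "status",
        ],
    )
    df["T"] = df["status"]
    df["G"] = df["T"] / 2.0
    df["C"] = df["T"] - df["G"]
    df["E"] = 0.0
    return Pedigree(
        individuals=df,
        generations=generations,
        params=params or TransmissionParams(),
        seed=None,
        measures=tuple(measures),
    )


@pytest.fixture
def toy_pedigree():
    """Three generations: two founder couples, each with two children,
    cross-married, two grandchildren per young couple."""
    rows = [
        # id, father, mother, sex, year, surname, gen, status
        ("A1", None, None, "M", 1700, "A", 0, 1.0),
        ("A2", None, None, "F", 1701, "A", 0, 2.0),
        ("B1", None, None, "M", 1700, "B", 0, 3.0),
        ("B2", None, None, "F", 1702, "B", 0, 4.0),
        ("a1", "A1", "A2", "M", 1730, "A", 1, 1.5),
        ("a2", "A1", "A2", "F", 1731, "A", 1, 2.5),
        ("b1", "B1", "B2", "M", 1730, "B", 1, 3.5),
        ("b2", "B1", "B2", "F", 1732, "B", 1, 0.5),
        # cross-marriages: a1 x b2, b1 x a2
        ("g1", "a1", "b2", "M", 1760, "A", 2, 1.1),
        ("g2", "a1", "b2", "F", 1761, "A", 2, 2.2),
        ("g3", "b1", "a2", "M", 1760, "B", 2, 3.3),
        ("g4", "b1", "a2", "F", 1762, "B", 2, 0.4),
    ]
    return build_pedigree(rows, generations=3)


@pytest.fixture
def nuclear_family():
    """One couple with four children."""
    rows = [
        ("F", None, None, "M", 1700, "S", 0, 0.0),
        ("M", None, None, "F", 1700, "S", 0, 1.0),
    ] + [
        (f"c{i}", "F", "M", "M" if i % 2 else "F", 1730 + i, "S", 1, float(i))
        for i in range(4)
    ]
    return build_pedigree(rows, generations=2)


@pytest.fixture(scope="session")
def medium_pedigree():
    """A mid-sized simulated pedigree with wealth, reused across tests."""
    params = TransmissionParams(t2=0.6, m=0.6, h2_share=0.5)
    ped = simulate_pedigree(
        params, n_founder_couples=1500, n_generations=4, seed=20260
    )
    return simulate_wealth(ped, status_loading=0.9, seed=20260)


def clustered_pair_table(rng, n_clusters, cluster_size, rho, relationship="siblings"):
    """Pair table where each surname cluster is a sibship of
    ``cluster_size`` members contributing all within-sibship pairs; the
    true pair correlation is ``rho``."""
    shared = rng.normal(0.0, np.sqrt(rho), n_clusters)
    vals = shared[:, None] + rng.normal(
        0.0, np.sqrt(1.0 - rho), (n_clusters, cluster_size)
    )
    ii, jj = np.triu_indices(cluster_size, 1)
    recs = []
    for k in range(n_clusters):
        for i, j in zip(ii, jj):
            recs.append(
                (f"s{k}_{i}", f"s{k}_{j}", relationship, f"S{k}",
                 vals[k, i], vals[k, j], 0)
            )
    return pd.DataFrame(
        recs,
        columns=["id_a", "id_b", "relationship", "surname",
                 "values_a", "values_b", "cohort"],
    )
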