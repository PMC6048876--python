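"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import random

import pytest

from pandorapan import generate_pangenome
from pandorapan.cluster import cluster_proteins

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


@pytest.fixture(scope="session")
def small_pangenome():
    """6 genomes, 10 core + 6 shell + 4 cloud/genome families at identity 0.8."""
    genomes, truth = generate_pangenome(
        n_genomes=6,
        n_core=10,
        n_shell=6,
        shell_p=0.5,
        n_cloud_per_genome=4,
        identity=0.8,
        paralog_prob=0.0,
        seed=42,
    )
    return genomes, truth


@pytest.fixture(scope="session")
def small_clusters(small_pangenome):
    genomes, _truth = small_pangenome
    genes = [g for gs in genomes.values() for g in gs]
    return cluster_proteins(genes)
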