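"""Core/pangenome delineation, accumulation curves, and summary statistics.

The *pangenome* is the full set of clusters; the *strict core* is the subset
of clusters with at least one member in every genome. A gene is a core gene
iff its cluster is core; a gene is a paralog iff it shares a cluster with at
least one other gene of the same genome (paralogs are counted as genes, not
pairs: a cluster with three same-genome members contributes three paralog
genes).

Accumulation ("extinction") curves add genomes one at a time: at step k the
pangenome is every cluster seen among the first k genomes and the core is
every cluster covering all k. The endpoints are order-invariant; the path is
not, so random-permutation mode reports the spread across orderings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from pandorapan.cluster import Cluster, cluster_size_distribution
from pandorapan.utils import pct, round_half_up, truncate_to


@dataclass
class PerGenomeStats:
    n_genes: int
    n_core_genes: int
    core_fraction: float
    n_paralog_genes: int
    coding_capacity: float | None = None


@dataclass
class PangenomeSummary:
    n_pan_clusters: int
    n_core_clusters: int
    n_core_proteins: int
    core_over_pan: float
    per_genome: dict[str, PerGenomeStats]
    size_distribution: dict

    @property
    def core_over_pan_pct(self) -> float:
        return pct(self.n_core_clusters, self.n_pan_clusters, ndigits=1)


@dataclass
class AccumulationCurve:
    ordering: list[str]
    pan_k: list[int]
    core_k: list[int]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.pan_k, self.pan_k[1:])):
            raise AssertionError("pangenome curve must be non-decreasing")
        if any(b > a for a, b in zip(self.core_k, self.core_k[1:])):
            raise AssertionError("core curve must be non-increasing")
        if self.pan_k and self.pan_k[0] != self.core_k[0]:
            raise AssertionError("pan and core must coincide at the first genome")

    @property
    def relative_increases(self) -> list[float]:
        """Percent pangenome growth at each addition step k >= 2."""
        return [
            100.0 * (b - a) / a for a, b in zip(self.pan_k, self.pan_k[1:])
        ]

    @property
    def mean_relative_increase(self) -> float:
        incs = self.relative_increases
        return float(np.mean(incs)) if incs else 0.0


def delineate(
    clusters: list[Cluster],
    genomes: set[str],
    genome_lengths: dict[str, int] | None = None,
) -> PangenomeSummary:
    """Delineate the pangenome and strict core from a clustering.

    ``genomes`` is the full genome set; every genome must have contributed
    at least one gene. ``genome_lengths`` (bp) enables the genes/kbp coding
    capacity column.
    """
    genomes = set(genomes)
    seen = {g for c in clusters for g in c.genome_count}
    missing = sorted(genomes - seen)
    if missing:
        raise ValueError(f"genome(s) with zero genes: {', '.join(missing)}")

    core = [c for c in clusters if c.covers(genomes)]
    n_core_proteins = sum(c.size for c in core)

    per_genome: dict[str, PerGenomeStats] = {}
    for g in sorted(genomes):
        n_genes = sum(c.genome_count.get(g, 0) for c in clusters)
        n_core_genes = sum(c.genome_count.get(g, 0) for c in core)
        n_paralogs = sum(
            c.genome_count.get(g, 0) for c in clusters if c.genome_count.get(g, 0) >= 2
        )
        capacity = None
        if genome_lengths and g in genome_lengths:
            capacity = coding_capacity(n_genes, genome_lengths[g])
        per_genome[g] = PerGenomeStats(
            n_genes=n_genes,
            n_core_genes=n_core_genes,
            core_fraction=n_core_genes / n_genes if n_genes else 0.0,
            n_paralog_genes=n_paralogs,
            coding_capacity=capacity,
        )

    return PangenomeSummary(
        n_pan_clusters=len(clusters),
        n_core_clusters=len(core),
        n_core_proteins=n_core_proteins,
        core_over_pan=len(core) / len(clusters) if clusters else 0.0,
        per_genome=per_genome,
        size_distribution=cluster_size_distribution(clusters),
    )


def coding_capacity(n_genes: int, genome_length: int, mode: str = "round") -> float:
    """Predicted genes per kilobase pair, reported to two decimals.

    ``mode="truncate"`` is a compatibility switch for tables that truncate
    instead of rounding the second decimal.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    value = n_genes / (genome_length / 1000.0)
    if mode == "truncate":
        return truncate_to(value, 2)
    return round_half_up(value, 2)


def _curve_for_ordering(
    ordering: list[str], cluster_genomes: list[set[str]]
) -> AccumulationCurve:
    pan_k: list[int] = []
    core_k: list[int] = []
    for k in range(1, len(ordering) + 1):
        prefix = set(ordering[:k])
        pan = sum(1 for gs in cluster_genomes if gs & prefix)
        core = sum(1 for gs in cluster_genomes if prefix <= gs)
        pan_k.append(pan)
        core_k.append(core)
    return AccumulationCurve(list(ordering), pan_k, core_k)


def accumulation(
    clusters: list[Cluster],
    genomes: list[str],
    orderings: str | int | list[list[str]] = "given",
    seed: int = 0,
) -> list[AccumulationCurve]:
    """Pangenome/core accumulation curves over genome-addition orderings.

    ``orderings`` is "given" (the supplied genome order), "all" (every
    permutation — only sensible for a handful of genomes), an integer
    (that many random permutations, seeded), or an explicit list of
    orderings.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes for an accumulation curve")
    known = set(genomes)
    cluster_genomes = [set(c.genome_count) for c in clusters]
    if orderings == "given":
        orders = [list(genomes)]
    elif orderings == "all":
        orders = [list(p) for p in itertools.permutations(genomes)]
    elif isinstance(orderings, int):
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(genomes)) for _ in range(orderings)]
    else:
        orders = [list(o) for o in orderings]
        for o in orders:
            unknown = set(o) - known
            if unknown:
                raise ValueError(f"unknown genome(s) in ordering: {sorted(unknown)}")
            if sorted(o) != sorted(genomes):
                raise ValueError("each ordering must be a permutation of the genomes")
    return [_curve_for_ordering(o, cluster_genomes) for o in orders]


def openness(curves: list[AccumulationCurve], threshold_pct: float = 5.0) -> dict:
    """Open/closed verdict from the pangenome growth at the final addition.

    The pangenome is called open when the mean relative increase of the
    pangenome at the last genome added exceeds ``threshold_pct`` percent.
    """
    if not curves:
        raise ValueError("no curves")
    if len(curves[0].pan_k) < 3:
        raise ValueError("openness needs curves over at least 3 genomes")
    final_increases = [c.relative_increases[-1] for c in curves]
    mean_final = float(np.mean(final_increases))
    mean_overall = float(np.mean([c.mean_relative_increase for c in curves]))
    return {
        "mean_final_increase_pct": mean_final,
        "mean_increase_pct": mean_overall,
        "verdict": "open" if mean_final > threshold_pct else "closed",
        "threshold_pct": threshold_pct,
    }
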