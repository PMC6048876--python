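"""Greedy incremental protein clustering (CD-HIT-style).

All proteins from all genomes are sorted by decreasing length (ties broken
lexicographically by gene id, so the result is independent of input file
order), then processed once: each sequence joins the cluster of the
*best-matching* existing representative that meets both the identity and
the coverage threshold, or founds a new cluster with itself as
representative. Identity is counted over the shorter sequence (identical
columns / length of the shorter sequence) and coverage, by default, is the
aligned span of the shorter sequence over its length; ``cov_mode="both"``
additionally requires the span on the longer sequence to qualify.

Joining the best-identity representative (rather than the first qualifying
one, as CD-HIT does) removes residual input-order sensitivity at the cost
of comparing each sequence against every current representative. At the
30% identity floor used here no k-mer screen can prove a pair is below
threshold, so every comparison runs the full dynamic program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pandorapan.align import PROTEIN_MATRIX, _sw_kernel, encode_protein
from pandorapan.records import GeneRecord
from pandorapan.utils import pct

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """One pangenome cluster: members, representative, per-genome counts."""

    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)
    genome_count: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def covers(self, genomes: set[str]) -> bool:
        """True if the cluster has at least one member from every genome."""
        return genomes <= set(self.genome_count)


def cluster_proteins(
    genes: list[GeneRecord],
    id_thresh: float = 0.30,
    cov_thresh: float = 0.50,
    cov_mode: str = "shorter",
    gap_open: int = 11,
    gap_ext: int = 1,
) -> list[Cluster]:
    """Partition proteins into clusters at identity/coverage thresholds.

    Defaults mirror the comparative-genomics convention for delineating a
    giant-virus pangenome: 30% identity and 50% coverage.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    if not 0.0 < id_thresh <= 1.0 or not 0.0 < cov_thresh <= 1.0:
        raise ValueError("thresholds must be in (0, 1]")
    if cov_mode not in ("shorter", "both"):
        raise ValueError("cov_mode must be 'shorter' or 'both'")

    order = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    encoded = [encode_protein(g.sequence) for g in order]

    clusters: list[Cluster] = []
    rep_encoded: list = []  # parallel to clusters; representatives are encoded once

    for gene, eq in zip(order, encoded):
        best_cluster = -1
        best_identity = 0.0
        lq = gene.length
        for ci, er in enumerate(rep_encoded):
            lr = er.shape[0]
            score, n_id, _cols, q0, q1, s0, s1 = _sw_kernel(
                eq, er, PROTEIN_MATRIX, gap_open, gap_ext
            )
            if score <= 0:
                continue
            lmin = min(lq, lr)
            identity = n_id / lmin
            if identity < id_thresh:
                continue
            # query (the new sequence) is never longer than the representative
            cov_short = (q1 - q0) / lq if lq <= lr else (s1 - s0) / lr
            if cov_short < cov_thresh:
                continue
            if cov_mode == "both":
                cov_long = (s1 - s0) / lr if lq <= lr else (q1 - q0) / lq
                if cov_long < cov_thresh:
                    continue
            if identity > best_identity:
                best_identity = identity
                best_cluster = ci
        if best_cluster >= 0:
            c = clusters[best_cluster]
            c.members.append(gene.gene_id)
            c.genome_count[gene.genome_id] = c.genome_count.get(gene.genome_id, 0) + 1
        else:
            c = Cluster(len(clusters), gene.gene_id, [gene.gene_id], {gene.genome_id: 1})
            clusters.append(c)
            rep_encoded.append(eq)
    logger.info(
        "clustered %d proteins into %d clusters (id >= %.2f, cov >= %.2f)",
        len(genes),
        len(clusters),
        id_thresh,
        cov_thresh,
    )
    return clusters


def cluster_size_distribution(clusters: list[Cluster]) -> dict:
    """Cluster-size histogram with fractions as one-decimal percentages."""
    if not clusters:
        raise ValueError("no clusters")
    counts: dict[int, int] = {}
    for c in clusters:
        counts[c.size] = counts.get(c.size, 0) + 1
    total = len(clusters)
    return {
        "counts": dict(sorted(counts.items())),
        "fractions_pct": {
            size: pct(n, total, ndigits=1) for size, n in sorted(counts.items())
        },
        "n_clusters": total,
    }
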