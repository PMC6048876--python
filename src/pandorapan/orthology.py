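"""Best-reciprocal-hit (BRH) orthology between genome pairs.

A BRH pair is two genes, one per genome, that are each other's best homology
hit and meet identity/coverage thresholds (the orthology convention here is
identity > 30% and coverage ≥ 70%). Hits can come from the built-in aligner
(synthetic scale) or from a tabular homology file. Ortholog groups are the
connected components of the graph whose edges are all pairwise BRH pairs;
the headline statistic is how many groups contain at least one gene from
every genome.

Coverage is required on *both* sequences by default (the behaviour of
standard reciprocal-hit tools); ``cov_mode="query"`` relaxes this to the
query side only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from pandorapan.align import PROTEIN_MATRIX, _sw_kernel, encode_protein
from pandorapan.records import GeneRecord, HitRecord


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    identity_pct: float
    coverage_query: float
    coverage_subject: float
    score: float


@dataclass(frozen=True)
class BrhPair:
    """An unordered reciprocal-best pair; (a, b) is stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    identity_pct: float
    coverage_a: float
    coverage_b: float


def best_hits(
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    hits: list[HitRecord] | None = None,
    identity_def: str = "shorter",
    gap_open: int = 11,
    gap_ext: int = 1,
) -> dict[str, BestHit]:
    """Best hit in genome B for every gene of genome A.

    With ``hits`` (a tabular source) the best hit is the highest bitscore;
    with the built-in aligner it is the highest raw alignment score. Ties are
    broken by higher identity, then lexicographic subject id. Genes with no
    positive-scoring hit are absent from the map.

    ``identity_def`` selects the identity denominator for the built-in
    source: "shorter" (identical columns over the shorter sequence) or
    "columns" (over alignment columns, the BLAST-style convention).
    """
    if not genes_a or not genes_b:
        raise ValueError("both genomes must be non-empty")
    if identity_def not in ("shorter", "columns"):
        raise ValueError("identity_def must be 'shorter' or 'columns'")
    if hits is not None:
        ids_a = {g.gene_id for g in genes_a}
        ids_b = {g.gene_id: g.length for g in genes_b}
        len_a = {g.gene_id: g.length for g in genes_a}
        best: dict[str, tuple] = {}
        for h in hits:
            if h.query_id not in ids_a or h.subject_id not in ids_b:
                continue
            cov_q = (h.qend - h.qstart + 1) / len_a[h.query_id]
            slo, shi = h.s_interval()
            cov_s = (shi - slo) / ids_b[h.subject_id]
            key = (h.bitscore, h.pct_identity, _NegLex(h.subject_id))
            cand = (key, BestHit(h.subject_id, h.pct_identity, cov_q, cov_s, h.bitscore))
            prev = best.get(h.query_id)
            if prev is None or cand[0] > prev[0]:
                best[h.query_id] = cand
        return {q: bh for q, (_k, bh) in best.items()}

    encoded_b = [(g, encode_protein(g.sequence)) for g in sorted(genes_b, key=lambda g: g.gene_id)]
    out: dict[str, BestHit] = {}
    for ga in genes_a:
        ea = encode_protein(ga.sequence)
        best_key = None
        best_hit = None
        for gb, eb in encoded_b:
            score, n_id, cols, q0, q1, s0, s1 = _sw_kernel(
                ea, eb, PROTEIN_MATRIX, gap_open, gap_ext
            )
            if score <= 0:
                continue
            if identity_def == "shorter":
                ident = 100.0 * n_id / min(ga.length, gb.length)
            else:
                ident = 100.0 * n_id / cols if cols else 0.0
            key = (score, ident, _NegLex(gb.gene_id))
            if best_key is None or key > best_key:
                best_key = key
                best_hit = BestHit(
                    gb.gene_id,
                    ident,
                    (q1 - q0) / ga.length,
                    (s1 - s0) / gb.length,
                    float(score),
                )
        if best_hit is not None:
            out[ga.gene_id] = best_hit
    return out


class _NegLex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal(
    best_ab: dict[str, BestHit],
    best_ba: dict[str, BestHit],
    genome_a: str,
    genome_b: str,
    id_thresh_pct: float = 30.0,
    cov_thresh: float = 0.70,
    cov_mode: str = "both",
) -> list[BrhPair]:
    """Keep pairs that are mutual best hits and pass both thresholds."""
    if cov_mode not in ("both", "query"):
        raise ValueError("cov_mode must be 'both' or 'query'")
    pairs: list[BrhPair] = []
    for a, hit_ab in sorted(best_ab.items()):
        b = hit_ab.subject_id
        back = best_ba.get(b)
        if back is None or back.subject_id != a:
            continue
        if hit_ab.identity_pct <= id_thresh_pct:
            continue
        cov_a = hit_ab.coverage_query
        cov_b = back.coverage_query
        if cov_a < cov_thresh:
            continue
        if cov_mode == "both" and cov_b < cov_thresh:
            continue
        ga, gb = (a, b) if a <= b else (b, a)
        gna, gnb = (genome_a, genome_b) if a <= b else (genome_b, genome_a)
        cov_ga, cov_gb = (cov_a, cov_b) if a <= b else (cov_b, cov_a)
        pairs.append(
            BrhPair(ga, gb, gna, gnb, hit_ab.identity_pct, cov_ga, cov_gb)
        )
    return pairs


def brh_groups(
    pairs: list[BrhPair], genomes: set[str]
) -> tuple[list[set[str]], int]:
    """Ortholog groups as connected components of the BRH graph.

    Returns the list of groups (sets of gene ids) and the number of groups
    containing at least one gene from every genome.
    """
    graph = nx.Graph()
    gene_genome: dict[str, str] = {}
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
        gene_genome[p.gene_a] = p.genome_a
        gene_genome[p.gene_b] = p.genome_b
    groups = [set(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda s: sorted(s)[0])
    genomes = set(genomes)
    n_all = sum(
        1 for grp in groups if {gene_genome[g] for g in grp} >= genomes
    )
    return groups, n_all
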