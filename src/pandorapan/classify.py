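"""Homology-based gene classification: ORFans, NCVOG presence, taxon tallies.

An *ORFan* is a predicted ORF with no qualifying homolog in the reference
database: the qualifying thresholds are e-value ≤ 1e−3 and query coverage
≥ 30%. Coverage can be judged on the single best (highest-bitscore) hit, on
any individual hit, or on the union of qualifying hit intervals; the default
follows the best-hit reading, with the alternatives behind ``cov_source``.

NCVOG presence builds the binary NCVOG × genome matrix from qualifying hits
(the marker families for nucleocytoplasmic large DNA viruses), and the
taxon tally counts genes by the database label of their best hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pandorapan.records import GeneRecord, HitRecord
from pandorapan.utils import pct


@dataclass
class GeneAnnotation:
    gene_id: str
    genome_id: str
    is_orfan: bool
    best_hit_subject: str | None = None
    best_hit_label: str | None = None
    ncvog_id: str | None = None
    in_core: bool | None = None


def _best_hit(hits: list[HitRecord]) -> HitRecord:
    """Highest bitscore; ties go to lower e-value then lexicographic subject."""
    return max(hits, key=lambda h: (h.bitscore, -h.evalue, _neg(h.subject_id)))


class _neg(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _union_coverage(hits: list[HitRecord], query_length: int) -> float:
    ivals = sorted(h.q_interval() for h in hits)
    covered = 0
    cur_lo, cur_hi = None, None
    for lo, hi in ivals:
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        covered += cur_hi - cur_lo
    return covered / query_length


def classify_orfans(
    genes: list[GeneRecord],
    hits: list[HitRecord],
    e_max: float = 1e-3,
    q_cov_min: float = 0.30,
    cov_source: str = "best",
) -> dict[str, GeneAnnotation]:
    """Mark every gene as ORFan or not from its reference-database hits.

    ``cov_source``: "best" judges the single highest-bitscore hit against
    both thresholds; "any" rescues a gene if any one hit passes both;
    "union" pools the spans of all hits with e ≤ e_max and requires their
    union to cover ≥ q_cov_min of the query.
    """
    if cov_source not in ("best", "any", "union"):
        raise ValueError("cov_source must be 'best', 'any' or 'union'")
    lengths = {g.gene_id: g.length for g in genes}
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.query_id not in lengths:
            raise KeyError(f"hit references unknown gene {h.query_id!r}")
        by_query.setdefault(h.query_id, []).append(h)

    out: dict[str, GeneAnnotation] = {}
    for g in genes:
        ghits = by_query.get(g.gene_id, [])
        best = _best_hit(ghits) if ghits else None
        if not ghits:
            orfan = True
        elif cov_source == "best":
            cov = (best.qend - best.qstart + 1) / g.length
            orfan = not (best.evalue <= e_max and cov >= q_cov_min)
        elif cov_source == "any":
            orfan = not any(
                h.evalue <= e_max
                and (h.qend - h.qstart + 1) / g.length >= q_cov_min
                for h in ghits
            )
        else:
            qualifying = [h for h in ghits if h.evalue <= e_max]
            orfan = (
                not qualifying
                or _union_coverage(qualifying, g.length) < q_cov_min
            )
        out[g.gene_id] = GeneAnnotation(
            gene_id=g.gene_id,
            genome_id=g.genome_id,
            is_orfan=orfan,
            best_hit_subject=best.subject_id if best else None,
        )
    return out


def ncvog_presence(
    hits_by_genome: dict[str, list[HitRecord]],
    e_max: float = 1e-3,
) -> tuple[pd.DataFrame, int]:
    """Binary NCVOG × genome presence matrix and the all-genome count.

    ``hits_by_genome`` maps each genome to its NCVOG hit table (subject ids
    are NCVOG ids); a hit qualifies at e ≤ e_max. Returns the matrix
    (rows = NCVOGs, columns = genomes, cells ∈ {0, 1}) and the number of
    NCVOGs present in every genome.
    """
    genomes = sorted(hits_by_genome)
    present: dict[str, set[str]] = {}
    for genome, hits in hits_by_genome.items():
        for h in hits:
            if h.evalue <= e_max:
                present.setdefault(h.subject_id, set()).add(genome)
    rows = sorted(present)
    matrix = pd.DataFrame(
        [[int(g in present[n]) for g in genomes] for n in rows],
        index=rows,
        columns=genomes,
        dtype=int,
    )
    n_all = int((matrix.sum(axis=1) == len(genomes)).sum()) if rows else 0
    return matrix, n_all


def best_hit_taxon_tally(
    annotations: dict[str, GeneAnnotation],
    taxon_labels: dict[str, str],
) -> pd.DataFrame:
    """Counts and integer percentages of non-ORFan genes per best-hit label.

    ``taxon_labels`` maps subject ids to labels (e.g. "pandoravirus").
    Percentages are integer-rounded over genes with a best hit, the usual
    convention for "N (x%) of best hits are within the same genus" summaries.
    """
    labels = []
    for ann in annotations.values():
        if ann.is_orfan or ann.best_hit_subject is None:
            continue
        labels.append(taxon_labels.get(ann.best_hit_subject, "unlabeled"))
    total = len(labels)
    counted = pd.Series(labels, dtype=object).value_counts().sort_index()
    return pd.DataFrame(
        {
            "count": counted,
            "pct": [pct(n, total, ndigits=0) for n in counted],
        }
    )
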