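"""MITE detection in nucleotide genomes.

MITEs (miniature inverted-repeat transposable elements) are short
(100–600 bp) non-autonomous DNA transposons bounded by terminal inverted
repeats (TIRs) and flanked by identical target-site duplications (TSDs)
created on insertion. The scanner finds local-alignment hits of known MITE
queries in a genome on both strands (e-value ≤ 1e−3), calls hits full-length
when they cover ≥ 90% of the query and fall in the 100–600 bp size range,
and verifies the TIR/TSD structure directly on the genome sequence.

Multiple hits per scaffold are found by iterative masking: the best local
alignment is recorded, its genomic span is masked with N (which cannot
align), and the scan repeats until no hit passes the e-value threshold.
Hits overlapping by more than 50% of the shorter hit are merged, keeping
the higher-scoring one.
"""

from __future__ import annotations

from dataclasses import dataclass

from pandorapan.align import align_nucleotide, evalue
from pandorapan.utils import reverse_complement


@dataclass
class MiteHit:
    """One MITE-like match; coordinates are 0-based half-open on the scaffold."""

    genome_id: str
    query_id: str
    start: int
    end: int
    strand: str
    pct_identity: float
    score: int
    evalue: float
    q_span: tuple[int, int]
    query_length: int
    full_length: bool = False
    tir_length: int | None = None
    tir_mismatches: int | None = None
    tsd: str | None = None
    tsd_reason: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def query_coverage(self) -> float:
        return (self.q_span[1] - self.q_span[0]) / self.query_length


def _iter_hits(
    scaffold_id: str,
    scaffold: str,
    query_id: str,
    query: str,
    strand: str,
    e_max: float,
    max_hits: int = 200,
) -> list[MiteHit]:
    qseq = query if strand == "+" else reverse_complement(query)
    masked = list(scaffold)
    hits: list[MiteHit] = []
    for _ in range(max_hits):
        res = align_nucleotide(qseq, "".join(masked))
        if res.score <= 0:
            break
        e = evalue(res.score, len(query), len(scaffold), kind="nucleotide")
        if e > e_max:
            break
        s0, s1 = res.s_span
        q0, q1 = res.q_span
        if strand == "-":
            q0, q1 = len(query) - q1, len(query) - q0
        hits.append(
            MiteHit(
                genome_id=scaffold_id,
                query_id=query_id,
                start=s0,
                end=s1,
                strand=strand,
                pct_identity=100.0 * res.identity_columns,
                score=res.score,
                evalue=e,
                q_span=(q0, q1),
                query_length=len(query),
            )
        )
        for i in range(s0, s1):
            masked[i] = "N"
    return hits


def _overlap_fraction(a: MiteHit, b: MiteHit) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.length, b.length)


def _merge(hits: list[MiteHit]) -> list[MiteHit]:
    kept: list[MiteHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.query_id, h.strand)):
        if all(_overlap_fraction(h, k) <= 0.5 for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.genome_id, h.start, h.end))
    return kept


def scan(
    genome: dict[str, str],
    queries: dict[str, str],
    e_max: float = 1e-3,
) -> list[MiteHit]:
    """Find MITE-query matches in a genome, both strands, e-value filtered.

    ``genome`` and ``queries`` map sequence ids to nucleotide strings.
    """
    if not genome or not queries:
        raise ValueError("genome and queries must be non-empty")
    hits: list[MiteHit] = []
    for scaffold_id in sorted(genome):
        scaffold = genome[scaffold_id].upper()
        for query_id in sorted(queries):
            query = queries[query_id].upper()
            for strand in ("+", "-"):
                hits.extend(
                    _iter_hits(scaffold_id, scaffold, query_id, query, strand, e_max)
                )
    return _merge(hits)


def call_full_length(
    hit: MiteHit, query_length: int | None = None, min_query_cov: float = 0.90
) -> bool:
    """Full-length call: query coverage ≥ threshold and size within 100–600 bp."""
    qlen = hit.query_length if query_length is None else query_length
    coverage = (hit.q_span[1] - hit.q_span[0]) / qlen
    full = coverage >= min_query_cov and 100 <= hit.length <= 600
    hit.full_length = full
    return full


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def verify_tir_tsd(
    scaffold: str,
    hit: MiteHit,
    tir_min: int = 10,
    tsd_range: tuple[int, int] = (2, 10),
    max_mismatch: int = 2,
) -> MiteHit:
    """Annotate a hit with its TIR arm length and flanking TSD, if present.

    The TIR is the longest element prefix whose reverse complement matches
    the element suffix with at most ``max_mismatch`` mismatches; arms shorter
    than ``tir_min`` leave the hit flagged (tir_length still reported). The
    TSD is the longest identical direct repeat immediately flanking both
    ends, searched from the top of ``tsd_range`` down; matching is exact.
    A hit at a contig edge gets ``tsd=None`` with reason "contig_edge".
    """
    element = scaffold[hit.start : hit.end]
    best_len = 0
    best_mm = 0
    for ln in range(len(element) // 2, 0, -1):
        mm = _hamming(element[:ln], reverse_complement(element[-ln:]))
        if mm <= max_mismatch:
            best_len = ln
            best_mm = mm
            break
    hit.tir_length = best_len
    hit.tir_mismatches = best_mm if best_len else None

    lo, hi = tsd_range
    if hit.start == 0 or hit.end == len(scaffold):
        hit.tsd = None
        hit.tsd_reason = "contig_edge"
        return hit
    hit.tsd = None
    hit.tsd_reason = "no_exact_duplication"
    for ln in range(hi, lo - 1, -1):
        if hit.start - ln < 0 or hit.end + ln > len(scaffold):
            continue
        left = scaffold[hit.start - ln : hit.start]
        right = scaffold[hit.end : hit.end + ln]
        if left == right:
            hit.tsd = left
            hit.tsd_reason = None
            break
    return hit
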