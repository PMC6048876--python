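"""Average amino-acid identity (AAI) between two proteomes.

AAI is the unweighted mean percent identity over homologous protein pairs
between two genomes — a whole-proteome relatedness measure. Pairs come
either from one-way best hits ("best" mode, asymmetric: aai(A,B) need not
equal aai(B,A) and the two are never silently averaged) or from best
reciprocal hits ("brh" mode, symmetric by construction). Per-pair identity
follows the BLAST-style convention (identical columns over alignment
columns) when computed by the built-in aligner, or the table's own
pct_identity for a tabular source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pandorapan.orthology import best_hits, reciprocal
from pandorapan.records import GeneRecord, HitRecord


@dataclass
class AaiResult:
    genome_a: str
    genome_b: str
    mode: str
    mean_identity_pct: float | None
    n_pairs_used: int
    histogram: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_pairs_used == 0


def _histogram(identities: list[float], width: int = 5) -> dict[tuple[int, int], int]:
    bins: dict[tuple[int, int], int] = {}
    for ident in identities:
        lo = min(int(ident // width) * width, 100 - width)
        bins[(lo, lo + width)] = bins.get((lo, lo + width), 0) + 1
    return dict(sorted(bins.items()))


def aai(
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    mode: str = "brh",
    hits_ab: list[HitRecord] | None = None,
    hits_ba: list[HitRecord] | None = None,
    id_thresh_pct: float = 30.0,
    cov_thresh: float = 0.70,
) -> AaiResult:
    """AAI between two proteomes from best hits or reciprocal best hits.

    In "best" mode every gene of A with a best hit in B contributes its
    best-hit identity; in "brh" mode only reciprocal pairs passing the
    orthology thresholds contribute. Zero qualifying pairs yields an
    explicit empty result (mean None), never an AAI of 0.
    """
    if mode not in ("best", "brh"):
        raise ValueError("mode must be 'best' or 'brh'")
    genome_a = genes_a[0].genome_id if genes_a else "A"
    genome_b = genes_b[0].genome_id if genes_b else "B"
    ident_def = "columns"
    fwd = best_hits(genes_a, genes_b, hits=hits_ab, identity_def=ident_def)
    if mode == "best":
        identities = [bh.identity_pct for bh in fwd.values()]
    else:
        rev = best_hits(genes_b, genes_a, hits=hits_ba, identity_def=ident_def)
        pairs = reciprocal(
            fwd, rev, genome_a, genome_b, id_thresh_pct=id_thresh_pct, cov_thresh=cov_thresh
        )
        identities = [p.identity_pct for p in pairs]
    if not identities:
        return AaiResult(genome_a, genome_b, mode, None, 0, {})
    return AaiResult(
        genome_a,
        genome_b,
        mode,
        float(np.mean(identities)),
        len(identities),
        _histogram(identities),
    )
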