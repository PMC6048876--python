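"""Hierarchical clustering of genomes from marker presence/absence profiles.

Genomes are column vectors of a binary NCVOG × genome matrix; pairwise
distances (Jaccard by default, Hamming available) feed agglomerative
clustering (average linkage by default). Columns are sorted lexicographically
before clustering so ties resolve deterministically and the dendrogram never
depends on row or column input order. The result is an ultrametric Newick
string plus the SciPy linkage (merge) table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist

from pandorapan.seqio import linkage_to_newick

_DISTANCES = ("jaccard", "hamming")
_LINKAGES = ("single", "complete", "average")


def cluster_profiles(
    matrix: pd.DataFrame,
    distance: str = "jaccard",
    linkage: str = "average",
) -> tuple[str, np.ndarray, list[str]]:
    """Cluster genomes on presence/absence profiles; returns Newick + linkage.

    ``matrix`` has marker families as rows and genomes as columns, cells in
    {0, 1}. Non-binary cells and all-zero genome columns are errors.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 genomes")
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary")
    zero_cols = [c for c in matrix.columns if matrix[c].sum() == 0]
    if zero_cols:
        raise ValueError(f"all-zero genome column(s): {zero_cols}")

    ordered = matrix[sorted(matrix.columns)]
    labels = list(ordered.columns)
    profiles = ordered.to_numpy().T.astype(bool)
    dists = pdist(profiles, metric=distance)
    lk = scipy_linkage(dists, method=linkage)
    return linkage_to_newick(lk, labels), lk, labels
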