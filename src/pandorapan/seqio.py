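"""Readers and writers for every format the pipeline touches.

Formats: protein/nucleotide FASTA (via Bio.SeqIO), 12-column tabular homology
hits (BLAST outfmt-6 dialect, via pandas), cluster TSV, presence/absence
matrix TSV, and Newick dendrograms. All writers are deterministic: records
are emitted in lexicographic order of their identifiers, so the same input
always produces byte-identical output.

Genome identity is carried in the FASTA header prefix before ``|``
(``>G1|orf001`` → genome ``G1``, gene ``orf001``); when no ``|`` is present
the file stem is used as the genome id.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pandorapan.records import AMBIGUOUS_AA, GeneRecord, HitRecord

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_COERCE_X = str.maketrans({c: "X" for c in AMBIGUOUS_AA})


class FastaParseError(ValueError):
    pass


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: malformed FASTA, line {lineno} is not a header"
                    )
                return


def read_proteomes(
    paths: list[str | Path],
    min_length: int | None = None,
    id_from: str = "header",
) -> dict[str, list[GeneRecord]]:
    """Read per-genome protein FASTA files into GeneRecords grouped by genome.

    ``min_length`` drops proteins shorter than the given number of residues
    (the annotation convention is 50 aa) and logs each exclusion. Duplicate
    gene ids across files are an error. ``id_from`` selects where the genome
    id comes from: the header prefix before ``|`` ("header", with file-stem
    fallback) or always the file stem ("filename").
    """
    if id_from not in ("header", "filename"):
        raise ValueError("id_from must be 'header' or 'filename'")
    genomes: dict[str, list[GeneRecord]] = {}
    seen: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        if path.stat().st_size == 0 or not path.read_text().strip():
            logger.warning("empty FASTA file %s: empty genome", path)
            genomes.setdefault(path.stem, [])
            continue
        _check_fasta_header(path)
        n_read = 0
        n_dropped = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if id_from == "header" and "|" in header:
                genome_id, gene_id = header.split("|", 1)
            else:
                genome_id, gene_id = path.stem, header
            if gene_id in seen:
                raise ValueError(
                    f"duplicate gene id {gene_id!r} in {path} "
                    f"(first seen in {seen[gene_id]})"
                )
            seen[gene_id] = str(path)
            seq = str(rec.seq).upper().translate(_COERCE_X)
            n_read += 1
            if min_length is not None and len(seq) < min_length:
                n_dropped += 1
                logger.info(
                    "excluded %s (%d aa < %d aa minimum)", gene_id, len(seq), min_length
                )
                continue
            genomes.setdefault(genome_id, []).append(GeneRecord(genome_id, gene_id, seq))
        logger.info("%s: read %d proteins, excluded %d short", path, n_read, n_dropped)
    return genomes


def write_proteome_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as FASTA with ``>genome|gene`` headers, sorted by id."""
    records = [
        SeqRecord(Seq(g.sequence), id=f"{g.genome_id}|{g.gene_id}", description="")
        for g in sorted(genes, key=lambda g: g.gene_id)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an id → sequence map."""
    _check_fasta_header(Path(path))
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_nucleotide_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# --- tabular hits -------------------------------------------------------------


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated homology table (outfmt-6 dialect).

    Rows are preserved in file order; coordinates stay 1-based inclusive.
    A row whose query start exceeds its query end is rejected with an error
    naming the row.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 12:
        raise ValueError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = OUTFMT6_COLUMNS
    hits: list[HitRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hits.append(
                HitRecord(
                    query_id=row.query_id,
                    subject_id=row.subject_id,
                    pct_identity=float(row.pct_identity),
                    aln_length=int(row.aln_length),
                    mismatches=int(row.mismatches),
                    gap_opens=int(row.gap_opens),
                    qstart=int(row.qstart),
                    qend=int(row.qend),
                    sstart=int(row.sstart),
                    send=int(row.send),
                    evalue=float(row.evalue),
                    bitscore=float(row.bitscore),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return hits


def write_hits(hits: list[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:g}\t{h.aln_length}"
                f"\t{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}"
                f"\t{h.sstart}\t{h.send}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def join_lengths(hits: list[HitRecord], genes: list[GeneRecord]) -> list[HitRecord]:
    """Attach query lengths (and subject lengths where known) from gene records."""
    lengths = {g.gene_id: g.length for g in genes}
    out = []
    for h in hits:
        if h.query_id not in lengths:
            raise KeyError(f"hit references unknown gene {h.query_id!r}")
        out.append(
            HitRecord(
                **{
                    **h.__dict__,
                    "query_length": lengths[h.query_id],
                    "subject_length": lengths.get(h.subject_id),
                }
            )
        )
    return out


# --- clusters ------------------------------------------------------------------


def write_clusters(clusters: list, path: str | Path) -> None:
    """Cluster TSV: cluster_id, representative, members, per-genome counts."""
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmembers\tgenome_counts\n")
        for c in clusters:
            counts = ",".join(f"{g}:{n}" for g, n in sorted(c.genome_count.items()))
            fh.write(
                f"{c.cluster_id}\t{c.representative}\t{','.join(c.members)}\t{counts}\n"
            )


def read_clusters(path: str | Path) -> list:
    from pandorapan.cluster import Cluster

    clusters = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id\t"):
            raise ValueError(f"{path}: not a cluster TSV")
        for line in fh:
            cid, rep, members, counts = line.rstrip("\n").split("\t")
            genome_count = {}
            if counts:
                for item in counts.split(","):
                    g, n = item.rsplit(":", 1)
                    genome_count[g] = int(n)
            clusters.append(
                Cluster(int(cid), rep, members.split(","), genome_count)
            )
    return clusters


# --- matrices ------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Presence/absence (or count) matrix TSV with sorted rows and columns."""
    out = matrix.sort_index().sort_index(axis=1)
    out.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# --- dendrograms ---------------------------------------------------------------


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as an ultrametric Newick string.

    Each merge at height h places its children at depth h/2 from the root of
    the merged clade, so a two-leaf dendrogram merged at height 0.5 becomes
    ``(A:0.25,B:0.25);``.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _size) in enumerate(linkage):
        a, b = int(a), int(b)
        half = h / 2.0
        la = half - heights[a] / 2.0
        lb = half - heights[b] / 2.0
        node = n + k
        newick[node] = f"({newick[a]}:{la:g},{newick[b]}:{lb:g})"
        heights[node] = h
    return newick[n + len(linkage) - 1] + ";"


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")
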