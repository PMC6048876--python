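"""Core record types shared across pipeline stages.

A :class:`GeneRecord` is one predicted protein; a :class:`HitRecord` is one
row of a 12-column tabular homology-search result (BLAST "outfmt 6" dialect).
Tabular coordinates are kept 1-based inclusive, exactly as in the source
format; conversion to 0-based half-open intervals happens in one place
(:meth:`HitRecord.q_interval` / :meth:`HitRecord.s_interval`) so off-by-one
drift cannot accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = STANDARD_AA | {"X"}
#: residue codes outside the 20 standard + X that readers coerce to X
AMBIGUOUS_AA = set("BZJUO*")


@dataclass(frozen=True)
class GeneRecord:
    """One predicted protein of one genome."""

    genome_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r} contains non-standard residues "
                f"{sorted(bad)}; allowed are the 20 standard amino acids plus X"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One tabular homology hit (12-column outfmt-6 dialect).

    ``qstart``/``qend``/``sstart``/``send`` are 1-based inclusive as in the
    source file. ``query_length``/``subject_length`` are optional and joined
    from the protein FASTA when available (needed for coverage filters).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    query_length: int | None = field(default=None, compare=False)
    subject_length: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"hit {self.query_id!r} vs {self.subject_id!r}: "
                f"qstart {self.qstart} > qend {self.qend}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")

    def q_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return self.qstart - 1, self.qend

    def s_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi

    @property
    def query_coverage(self) -> float:
        """Fraction of the query covered by this hit's alignment span."""
        if self.query_length is None:
            raise ValueError(
                f"query_length not joined for hit {self.query_id!r}; "
                "call seqio.join_lengths first"
            )
        return (self.qend - self.qstart + 1) / self.query_length
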