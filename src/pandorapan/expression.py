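"""Transcriptome and proteome integration with pangenome status.

An ORF counts as *transcribed* when at least ``read_min`` (default 10) reads
mapped to it, summed over all timepoints; per-timepoint detection fractions
describe the kinetics (the denominator is all transcribed ORFs). Proteomics
input is a flat list of gene ids detected in virions. Cross-tabulation joins
these calls with core-genome and ORFan status and reports the standard
contingency summaries (transcribed∩core, detected among non-core, ORFans
transcribed, transcript∧protein concordance), with margins checked against
the input set sizes on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pandorapan.records import GeneRecord
from pandorapan.utils import pct


@dataclass
class ExpressionTable:
    """Per-gene counts, transcription calls, and proteomics detections."""

    table: pd.DataFrame  # index gene_id; timepoint columns + total_count + flags
    timepoints: list[str]
    read_min: int

    @property
    def transcribed(self) -> set[str]:
        return set(self.table.index[self.table["transcribed"]])

    @property
    def protein_detected(self) -> set[str]:
        return set(self.table.index[self.table["protein_detected"]])

    def mean_reads_per_orf(
        self, over: str = "transcribed", drop_top: int = 0
    ) -> float:
        """Mean total reads per ORF, over transcribed ORFs or all ORFs.

        ``drop_top`` removes the k highest-count ORFs first (outlier trim).
        """
        if over == "transcribed":
            totals = self.table.loc[self.table["transcribed"], "total_count"]
        elif over == "all":
            totals = self.table["total_count"]
        else:
            raise ValueError("over must be 'transcribed' or 'all'")
        totals = totals.sort_values(ascending=False)
        if drop_top:
            totals = totals.iloc[drop_top:]
        return float(totals.mean()) if len(totals) else 0.0

    def per_timepoint_fractions(self) -> dict[str, float]:
        """Percent of transcribed ORFs first exceeding detection per timepoint.

        For each timepoint, the fraction of transcribed ORFs with at least
        one read in that window, as a percent of all transcribed ORFs.
        """
        sub = self.table[self.table["transcribed"]]
        n = len(sub)
        return {
            tp: pct(int((sub[tp] > 0).sum()), n, ndigits=0) for tp in self.timepoints
        }


def call_transcribed(
    counts: dict[str, dict[str, int]] | pd.DataFrame,
    genes: list[GeneRecord],
    read_min: int = 10,
    protein_detected: set[str] | None = None,
) -> ExpressionTable:
    """Build the expression table from per-timepoint read counts.

    ``counts`` maps timepoint label → {gene_id: count} (or an equivalent
    DataFrame with genes as the index). Genes present in the counts but
    absent from the proteome are an error; genes with no counts get zeros.
    """
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    if isinstance(counts, pd.DataFrame):
        df = counts.copy()
    else:
        df = pd.DataFrame(counts).fillna(0)
    unknown = sorted(set(df.index) - known)
    if unknown:
        raise KeyError(
            f"count table references gene(s) absent from the proteome: {unknown[:5]}"
        )
    df = df.reindex(gene_ids, fill_value=0).astype(int)
    timepoints = list(df.columns)
    df["total_count"] = df[timepoints].sum(axis=1)
    df["transcribed"] = df["total_count"] >= read_min
    detected = protein_detected or set()
    missing = sorted(detected - known)
    if missing:
        raise KeyError(f"proteomics list references unknown gene(s): {missing[:5]}")
    df["protein_detected"] = df.index.isin(sorted(detected))
    return ExpressionTable(df, timepoints, read_min)


def cross_tabulate(
    expression: ExpressionTable,
    core_genes: set[str],
    orfan_genes: set[str] | None = None,
) -> dict:
    """Contingency summaries of expression calls against core/ORFan status.

    All percentages are integer-rounded except the ORFan fractions, which
    are reported to one decimal (they are small).
    """
    table = expression.table
    all_genes = set(table.index)
    core = core_genes & all_genes
    non_core = all_genes - core
    transcribed = expression.transcribed
    detected = expression.protein_detected
    concordant = transcribed & detected
    # margin conservation checks
    assert len(core) + len(non_core) == len(all_genes)
    assert concordant <= transcribed and concordant <= detected

    out = {
        "n_genes": len(all_genes),
        "n_core_genes": len(core),
        "n_transcribed": len(transcribed),
        "pct_transcribed": pct(len(transcribed), len(all_genes), ndigits=0),
        "n_transcribed_core": len(transcribed & core),
        "pct_transcribed_in_core": pct(
            len(transcribed & core), len(transcribed), ndigits=0
        ),
        "pct_core_transcribed": pct(len(transcribed & core), len(core), ndigits=0),
        "n_transcribed_noncore": len(transcribed & non_core),
        "pct_noncore_transcribed": pct(
            len(transcribed & non_core), len(non_core), ndigits=0
        ),
        "n_protein_detected": len(detected),
        "n_detected_core": len(detected & core),
        "pct_detected_in_core": pct(len(detected & core), len(detected), ndigits=0),
        "n_detected_noncore": len(detected & non_core),
        "pct_noncore_detected": pct(
            len(detected & non_core), len(non_core), ndigits=0
        ),
        "n_concordant": len(concordant),
    }
    if orfan_genes is not None:
        orfans = orfan_genes & all_genes
        out.update(
            {
                "n_orfans": len(orfans),
                "n_orfans_transcribed": len(orfans & transcribed),
                "pct_orfans_transcribed": pct(
                    len(orfans & transcribed), len(orfans), ndigits=1
                ),
                "n_orfans_detected": len(orfans & detected),
                "pct_orfans_detected": pct(
                    len(orfans & detected), len(orfans), ndigits=1
                ),
            }
        )
    return out
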