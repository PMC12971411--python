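"""Expression: TPM normalization, tissue/stress profiles, and the
gene-count versus expression-dosage relationship across genomes.

TPM (transcripts per million): per sample, each gene's count is divided
by its effective length in kilobases to give a rate, and rates are
scaled to sum to one million. Dosage analysis correlates the number of
family genes in a genome with log2(total family TPM + 1) in a tissue,
using the same Pearson kernel as the SV association test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from panfam._stats import CorrelationResult, pearson

TISSUES = ("bud", "young leaf", "old leaf", "flower", "stem", "root")
CONDITIONS = ("control", "drought", "salt")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convert a gene x sample count matrix to TPM.

    `lengths` gives effective gene lengths in bases. An all-zero sample
    stays all-zero, with a warning. Every other column sums to 1e6.
    """
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths: {missing}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive lengths: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"all-zero sample(s): {list(totals.index[zero])}", stacklevel=2
        )
        totals = totals.replace(0, np.nan)
    out = rates.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def gene_lengths_from_gff(genes: pd.DataFrame) -> pd.Series:
    """Gene lengths (bp) from the annotation table (span; for the
    single-exon models used here span == exon union)."""
    lengths = (genes["end"] - genes["start"] + 1).astype(float)
    lengths.index = genes["gene_id"]
    return lengths


def profile(matrix: pd.DataFrame, family_genes: list[str], meta: pd.DataFrame,
            group_by: str = "tissue", log2: bool = True) -> pd.DataFrame:
    """Per-gene mean expression across replicates per group.

    `meta` maps sample ids (index) to genome/tissue/condition labels;
    unknown tissue labels raise. Output optionally log2(TPM + 1) for
    heatmap export, genes restricted to `family_genes` order.
    """
    unknown = set(meta["tissue"]) - set(TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue label(s): {sorted(unknown)}")
    samples = [s for s in matrix.columns if s in meta.index]
    grouped = matrix[samples].T.groupby(meta.loc[samples, group_by]).mean().T
    grouped = grouped.reindex([g for g in family_genes if g in grouped.index])
    if log2:
        grouped = np.log2(grouped + 1.0)
    return grouped


def dosage_records(tpm_matrix: pd.DataFrame, meta: pd.DataFrame,
                   family_by_genome: dict[str, int], tissue: str) -> pd.DataFrame:
    """Per-genome family gene count and total family TPM in one tissue."""
    cols = meta.index[(meta["tissue"] == tissue)]
    cols = [c for c in cols if c in tpm_matrix.columns]
    totals = tpm_matrix[cols].T.groupby(meta.loc[cols, "genome"]).mean().sum(axis=1)
    rows = []
    for genome, total in totals.items():
        rows.append((genome, family_by_genome.get(genome, 0), float(total)))
    return pd.DataFrame(rows, columns=["genome", "gene_count", "total_tpm"])


def dosage_correlation(gene_counts, total_tpm, log2: bool = True,
                       pseudocount: float = 1.0) -> CorrelationResult:
    """Pearson correlation between per-genome family gene counts and
    (log2-transformed) total family expression."""
    dosage = np.asarray(total_tpm, dtype=float)
    if log2:
        dosage = np.log2(dosage + pseudocount)
    return pearson(np.asarray(gene_counts, dtype=float), dosage)
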