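"""Orthogroup occupancy backbone: membership matrix, category rule,
PAV/CNV matrices, per-genome tallies and pan/core saturation curves.

Occupancy categories follow the count-based rule used for the printed
ranges at n = 22 genomes: core = present in all genomes; soft-core =
present in at least ceil(0.9 n) but not all (20-21 of 22); private =
present in exactly one genome; dispensable = everything between
(2-19 of 22).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("core", "soft-core", "dispensable", "private")


def build_membership(og_table: pd.DataFrame, family_genes: set[str],
                     genomes: list[str] | None = None) -> pd.DataFrame:
    """Orthogroup x genome copy-count matrix restricted to family genes.

    `og_table` is the long (og, genome, gene_id) frame from
    :func:`panfam.io.read_orthogroups`. Every family gene must appear in
    the table; offenders are listed in the raised error. Orthogroups with
    no family gene are dropped (row sums stay positive).
    """
    present = set(og_table["gene_id"])
    missing = sorted(family_genes - present)
    if missing:
        raise ValueError(f"family genes absent from orthogroup table: {missing}")
    fam = og_table[og_table["gene_id"].isin(family_genes)]
    if genomes is None:
        genomes = sorted(og_table["genome"].unique())
    matrix = (
        fam.groupby(["og", "genome"]).size().unstack(fill_value=0)
        .reindex(columns=genomes, fill_value=0)
        .sort_index()
    )
    matrix.columns.name = "genome"
    matrix.index.name = "og"
    return matrix.astype(int)


def soft_core_floor(n_genomes: int) -> int:
    """Smallest occupancy classified soft-core: ceil(0.9 n)."""
    return math.ceil(0.9 * n_genomes)


def classify_og(occupancy: int, n_genomes: int) -> str:
    """Occupancy category of one orthogroup.

    core iff occupancy == n; soft-core iff ceil(0.9 n) <= occupancy <= n-1;
    private iff occupancy == 1 (for n > 1); dispensable otherwise.
    With n = 22: core 22, soft-core 20-21, dispensable 2-19, private 1.
    """
    if not 1 <= occupancy <= n_genomes:
        raise ValueError(f"occupancy {occupancy} out of range [1, {n_genomes}]")
    if occupancy == n_genomes:
        if n_genomes == 1:
            warnings.warn(
                "single-genome collection: every orthogroup is simultaneously "
                "core and private; reporting core", stacklevel=2,
            )
        return "core"
    if occupancy >= soft_core_floor(n_genomes):
        return "soft-core"
    if occupancy == 1:
        return "private"
    return "dispensable"


def categorize(membership: pd.DataFrame) -> pd.DataFrame:
    """Per-orthogroup occupancy and category table."""
    n = membership.shape[1]
    occ = (membership > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "occupancy": occ,
            "category": [classify_og(int(o), n) for o in occ],
        },
        index=membership.index,
    )


def pav_matrix(membership: pd.DataFrame, exclude_core: bool = False) -> pd.DataFrame:
    """Binary presence/absence matrix; core rows removed when asked
    (the usual display excludes them, as they are present everywhere)."""
    pav = (membership > 0).astype(int)
    if exclude_core:
        cats = categorize(membership)["category"]
        pav = pav.loc[cats != "core"]
    return pav


@dataclass(frozen=True)
class SaturationCurve:
    """Pan (union) and core (intersection) orthogroup counts as genomes
    are added in random order, summarized over permutations."""

    k: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_perms: int
    seed: int
    per_perm_pan: np.ndarray  # (n_perms, n_genomes)
    per_perm_core: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_mean": self.pan_mean,
                "pan_sd": self.pan_sd,
                "core_mean": self.core_mean,
                "core_sd": self.core_sd,
            }
        )


def saturation(membership: pd.DataFrame, n_perms: int = 100, seed: int = 0) -> SaturationCurve:
    """Pan/core saturation curve over sampled genome orders.

    For each sampled order, pan(k) is the number of orthogroups present
    in at least one of the first k genomes and core(k) the number present
    in all of them; means and standard deviations are taken over orders.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    presence = (membership.to_numpy() > 0)
    n_og, n_genomes = presence.shape
    rng = np.random.default_rng(seed)
    pan = np.empty((n_perms, n_genomes), dtype=int)
    core = np.empty((n_perms, n_genomes), dtype=int)
    for p in range(n_perms):
        order = rng.permutation(n_genomes)
        cum_any = np.logical_or.accumulate(presence[:, order], axis=1)
        cum_all = np.logical_and.accumulate(presence[:, order], axis=1)
        pan[p] = cum_any.sum(axis=0)
        core[p] = cum_all.sum(axis=0)
    return SaturationCurve(
        k=np.arange(1, n_genomes + 1),
        pan_mean=pan.mean(axis=0),
        pan_sd=pan.std(axis=0),
        core_mean=core.mean(axis=0),
        core_sd=core.std(axis=0),
        n_perms=n_perms,
        seed=seed,
        per_perm_pan=pan,
        per_perm_core=core,
    )


def per_genome_category_counts(membership: pd.DataFrame,
                               categories: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genome x category tally counting genes (copies), not orthogroups."""
    if categories is None:
        categories = categorize(membership)
    cat = categories["category"]
    out = pd.DataFrame(0, index=membership.columns, columns=list(CATEGORIES))
    for category in CATEGORIES:
        rows = membership.loc[cat == category]
        out[category] = rows.sum(axis=0)
    out.index.name = "genome"
    return out
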