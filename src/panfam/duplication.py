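"""Duplication-mode assignment under the priority cascade
WGD > TD > PD > TRD > DSD.

A pair of intra-genome homologs is called a whole-genome/segmental
duplicate (WGD) when it is an anchor of a collinear block; tandem (TD)
when the genes are adjacent on a chromosome (rank distance <=
td_max_gap, default 1); proximal (PD) when nearby (rank distance <=
pd_max_gap, default 10); transposed (TRD) when exactly one gene of the
pair sits at an ancestral locus, evidenced by membership in a collinear
block against an outgroup genome; dispersed (DSD) otherwise.

The collinearity chainer is a longest-chain dynamic program over anchor
rank pairs: within a chromosome pair, a block is a chain of anchors with
strictly monotone ranks on both sides (the second side may run in either
direction) and adjacent rank gaps of at most `max_gap` on both sides;
blocks shorter than `min_block_size` anchors are discarded. Blocks are
extracted greedily (best chain first, anchors removed, repeat), which is
deterministic for fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MODES = ("WGD", "TD", "PD", "TRD", "DSD")
MODE_PRIORITY = {m: i for i, m in enumerate(MODES)}


# ---------------------------------------------------------------- ranks


def rank_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Assign per-chromosome ordinal ranks by ascending start.

    Ties are broken by end, then gene id; ranks are contiguous from 1
    within each (genome, chromosome). Duplicate records (same id and
    identical coordinates appearing twice) raise.
    """
    if genes.duplicated(subset=["gene_id", "genome", "chrom", "start", "end"]).any():
        dups = genes[genes.duplicated(subset=["gene_id"], keep=False)]["gene_id"].tolist()
        raise ValueError(f"duplicate gene records: {sorted(set(dups))}")
    out = genes.copy()
    out = out.sort_values(["genome", "chrom", "start", "end", "gene_id"], kind="mergesort")
    out["rank"] = out.groupby(["genome", "chrom"]).cumcount() + 1
    return out.reset_index(drop=True)


# ---------------------------------------------------------------- blocks


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int

    @property
    def pair(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class CollinearBlock:
    anchors: list[Anchor]
    chrom_a: str
    chrom_b: str
    score: int = field(init=False)

    def __post_init__(self):
        self.score = len(self.anchors)

    @property
    def anchor_pairs(self) -> set[frozenset]:
        return {a.pair for a in self.anchors}

    @property
    def genes(self) -> set[str]:
        return {g for a in self.anchors for g in (a.gene_a, a.gene_b)}


def _canonical_anchor(gene_a, gene_b, pos: dict) -> Anchor:
    ca, ra = pos[gene_a]
    cb, rb = pos[gene_b]
    if (cb, rb, gene_b) < (ca, ra, gene_a):
        gene_a, gene_b = gene_b, gene_a
        (ca, ra), (cb, rb) = (cb, rb), (ca, ra)
    return Anchor(gene_a, gene_b, ca, cb, ra, rb)


def _best_chain(anchors: list[Anchor], max_gap: int, direction: int) -> list[int]:
    """Longest valid chain (indices into `anchors`) for one orientation.

    direction +1: rank_b strictly increasing; -1: strictly decreasing.
    rank_a strictly increasing in both. Deterministic: on ties the
    earliest predecessor in sort order wins.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    best_len = [1] * len(order)
    prev = [-1] * len(order)
    for oi in range(len(order)):
        ai = anchors[order[oi]]
        for oj in range(oi):
            aj = anchors[order[oj]]
            if not (aj.rank_a < ai.rank_a <= aj.rank_a + max_gap):
                continue
            db = (ai.rank_b - aj.rank_b) * direction
            if not (0 < db <= max_gap):
                continue
            if best_len[oj] + 1 > best_len[oi]:
                best_len[oi] = best_len[oj] + 1
                prev[oi] = oj
        # deterministic tie-break: first improving predecessor kept
    end = max(range(len(order)), key=lambda i: (best_len[i], -i), default=-1)
    if end < 0:
        return []
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def chain_collinear(pairs: list[tuple[str, str]], positions: pd.DataFrame,
                    min_block_size: int = 5, max_gap: int = 25) -> list[CollinearBlock]:
    """Chain anchor pairs into collinear blocks.

    `pairs` are homolog pairs (gene ids); `positions` is a ranked gene
    table (from :func:`rank_genes`). Anchors are grouped by chromosome
    pair; within a group, maximal chains are extracted greedily in both
    orientations until none reaches `min_block_size`.
    """
    pos = {r.gene_id: (r.chrom, r.rank) for r in positions.itertuples()}
    groups: dict[tuple[str, str], list[Anchor]] = {}
    seen: set[frozenset] = set()
    for ga, gb in pairs:
        if ga == gb or ga not in pos or gb not in pos:
            continue
        key = frozenset((ga, gb))
        if key in seen:
            continue
        seen.add(key)
        anchor = _canonical_anchor(ga, gb, pos)
        groups.setdefault((anchor.chrom_a, anchor.chrom_b), []).append(anchor)

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(groups):
        remaining = sorted(groups[(ca, cb)], key=lambda a: (a.rank_a, a.rank_b, a.gene_a))
        while True:
            best: list[int] = []
            for direction in (1, -1):
                chain = _best_chain(remaining, max_gap, direction)
                if len(chain) > len(best):
                    best = chain
            if len(best) < min_block_size:
                break
            chosen = sorted(best)
            blocks.append(CollinearBlock([remaining[i] for i in chosen], ca, cb))
            remaining = [a for i, a in enumerate(remaining) if i not in set(chosen)]
    return blocks


# --------------------------------------------------------------- cascade


@dataclass(frozen=True)
class DuplicationPair:
    gene_a: str
    gene_b: str
    mode: str
    evidence: str

    @property
    def pair(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


def classify_duplications(pairs: list[tuple[str, str]],
                          blocks: list[CollinearBlock],
                          outgroup_blocks: list[CollinearBlock],
                          positions: pd.DataFrame,
                          td_max_gap: int = 1,
                          pd_max_gap: int = 10) -> list[DuplicationPair]:
    """Assign exactly one duplication mode per candidate intra-genome pair.

    Cascade: WGD if the pair is an anchor of an intra-genome collinear
    block; else TD if same chromosome and rank distance <= td_max_gap;
    else PD if same chromosome and rank distance <= pd_max_gap; else TRD
    if exactly one gene lies in a collinear block against the outgroup;
    else DSD.
    """
    info = {r.gene_id: (r.genome, r.chrom, r.rank) for r in positions.itertuples()}
    wgd_anchors = {p for b in blocks for p in b.anchor_pairs}
    ancestral = {g for b in outgroup_blocks for a in b.anchors for g in (a.gene_a, a.gene_b)}

    out: list[DuplicationPair] = []
    seen: set[frozenset] = set()
    for ga, gb in pairs:
        if ga == gb:
            continue
        key = frozenset((ga, gb))
        if key in seen:
            continue
        seen.add(key)
        ga, gb = sorted((ga, gb))
        genome_a, chrom_a, rank_a = info[ga]
        genome_b, chrom_b, rank_b = info[gb]
        if genome_a != genome_b:
            raise ValueError(f"pair ({ga}, {gb}) spans genomes {genome_a}/{genome_b}")
        if key in wgd_anchors:
            out.append(DuplicationPair(ga, gb, "WGD", "collinear_block_anchor"))
            continue
        if chrom_a == chrom_b:
            dist = abs(rank_a - rank_b)
            if dist <= td_max_gap:
                out.append(DuplicationPair(ga, gb, "TD", f"rank_distance={dist}"))
                continue
            if dist <= pd_max_gap:
                out.append(DuplicationPair(ga, gb, "PD", f"rank_distance={dist}"))
                continue
        in_a, in_b = ga in ancestral, gb in ancestral
        if in_a != in_b:
            anchored = ga if in_a else gb
            out.append(DuplicationPair(ga, gb, "TRD", f"outgroup_anchor={anchored}"))
            continue
        out.append(DuplicationPair(ga, gb, "DSD", "no_evidence"))
    return out


def crosstab_mode_by_category(dup_pairs: list[DuplicationPair],
                              og_of_gene: dict[str, str],
                              og_category: dict[str, str]) -> tuple[pd.DataFrame, pd.Series]:
    """Mode x occupancy-category cross-tabulation and mode shares.

    A pair's category is that of its orthogroup (both genes share one).
    Shares are percentages of all pairs, half-up to one decimal.
    """
    from panfam._stats import percent

    rows = []
    for p in dup_pairs:
        og = og_of_gene.get(p.gene_a) or og_of_gene.get(p.gene_b)
        rows.append((p.mode, og_category.get(og, "unknown")))
    frame = pd.DataFrame(rows, columns=["mode", "category"])
    table = pd.crosstab(frame["mode"], frame["category"]).reindex(list(MODES), fill_value=0)
    counts = frame["mode"].value_counts().reindex(list(MODES), fill_value=0)
    total = int(counts.sum())
    shares = counts.map(lambda c: percent(int(c), total)) if total else counts.astype(float)
    shares.name = "percent"
    return table, shares


def per_gene_modes(dup_pairs: list[DuplicationPair]) -> dict[str, str]:
    """Highest-priority mode per gene over all pairs it participates in."""
    best: dict[str, str] = {}
    for p in dup_pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in best or MODE_PRIORITY[p.mode] < MODE_PRIORITY[best[g]]:
                best[g] = p.mode
    return best
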