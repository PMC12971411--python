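"""Structural-variant filtering, gene-window overlap, SV-presence vs
expression association, and promoter cis-element comparison.

Per-genome SV genotypes are retained only when the genome's read depth
(FORMAT/DP) is at least `min_depth` (default 20); SVs left with no
carrier are dropped. A gene "overlaps" an SV when the SV's affected
reference span intersects the gene body extended by a flank (default
2 kb) on both sides. The association statistic is the Pearson
correlation between the binary gene-level SV-presence vector and
expression across genomes (point-biserial; its two-sided t p-value is
identical to the equal-variance two-sample t-test comparing the two
presence groups).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam

from panfam._stats import CorrelationResult, pearson

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------ SVs


@dataclass
class StructuralVariant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_len: int
    alt_len: int
    presence: dict[str, bool]  # genome -> carries a non-reference genotype
    depth: dict[str, int]
    sv_id: str = ""
    sv_type: str = field(init=False)

    def __post_init__(self):
        self.sv_type = classify_sv_type(self.ref_len, self.alt_len)

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference span [pos, pos + max(ref_len - 1, 0)].

        An insertion (ref_len 1) affects only its anchor base.
        """
        return self.pos, self.pos + max(self.ref_len - 1, 0)

    @property
    def carriers(self) -> set[str]:
        return {g for g, p in self.presence.items() if p}


def classify_sv_type(ref_len: int, alt_len: int) -> str:
    """insertion / deletion / other by allele-length comparison."""
    if ref_len < 1 or alt_len < 1:
        raise ValueError("allele lengths must be >= 1")
    if alt_len > ref_len:
        return "insertion"
    if alt_len < ref_len:
        return "deletion"
    return "other"


def read_sv_vcf(path) -> list[StructuralVariant]:
    """Read SV records (with FORMAT/GT and DP) from a VCF via pysam."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            presence, depth = {}, {}
            for sample, data in rec.samples.items():
                dp = data.get("DP")
                if dp is None:
                    raise ValueError(f"record {rec.chrom}:{rec.pos} lacks DP for {sample}")
                depth[sample] = int(dp)
                gt = data.get("GT") or ()
                presence[sample] = any(a not in (0, None) for a in gt)
            records.append(
                StructuralVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_len=len(rec.ref),
                    alt_len=len(rec.alts[0]) if rec.alts else len(rec.ref),
                    presence=presence,
                    depth=depth,
                    sv_id=rec.id or f"sv{i + 1}",
                )
            )
    return records


def filter_svs(records: list[StructuralVariant], min_depth: int = 20) -> list[StructuralVariant]:
    """Depth-filter genotypes (DP >= min_depth, inclusive); drop SVs with
    no retained carrier."""
    kept = []
    for sv in records:
        presence = {
            g: (p and sv.depth.get(g, 0) >= min_depth) for g, p in sv.presence.items()
        }
        if any(presence.values()):
            kept.append(
                StructuralVariant(sv.chrom, sv.pos, sv.ref_len, sv.alt_len,
                                  presence, dict(sv.depth), sv.sv_id)
            )
    return kept


# -------------------------------------------------------------- windows


@dataclass(frozen=True)
class GeneWindow:
    gene_id: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_gene(cls, gene_id: str, chrom: str, start: int, end: int,
                  flank: int = 2000) -> "GeneWindow":
        if flank < 0:
            raise ValueError("flank must be >= 0")
        return cls(gene_id, chrom, max(1, start - flank), end + flank)


def overlaps(sv: StructuralVariant, window: GeneWindow) -> bool:
    """Closed-interval intersection of the SV's affected span with the
    gene window (same chromosome only)."""
    if sv.chrom != window.chrom:
        return False
    lo, hi = sv.span
    return lo <= window.end and hi >= window.start


def gene_sv_presence(svs: list[StructuralVariant], windows: list[GeneWindow],
                     genomes: list[str]) -> pd.DataFrame:
    """Gene x genome binary matrix: 1 iff >= 1 retained SV overlapping the
    gene's window is carried by that genome."""
    out = pd.DataFrame(0, index=[w.gene_id for w in windows], columns=genomes)
    for w in windows:
        for sv in svs:
            if overlaps(sv, w):
                for g in sv.carriers:
                    if g in out.columns:
                        out.loc[w.gene_id, g] = 1
    out.index.name = "gene_id"
    return out


# ----------------------------------------------------------- association


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    tissue: str
    correlation: CorrelationResult
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.correlation.defined and self.correlation.p < self.alpha


def associate(presence, expression, gene_id: str = "", tissue: str = "",
              alpha: float = 0.05) -> AssociationResult:
    """Pearson association between binary SV presence and expression
    across genomes; constant presence yields an NA result."""
    return AssociationResult(gene_id, tissue, pearson(presence, expression), alpha)


def associate_all(presence: pd.DataFrame, expression: pd.DataFrame,
                  tissue: str = "", alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`associate` for every gene shared by the presence and
    expression matrices (columns = genomes). Returns a tidy frame."""
    genomes = [g for g in presence.columns if g in expression.columns]
    rows = []
    for gene in presence.index:
        if gene not in expression.index:
            continue
        res = associate(
            presence.loc[gene, genomes].to_numpy(float),
            expression.loc[gene, genomes].to_numpy(float),
            gene_id=gene, tissue=tissue, alpha=alpha,
        )
        c = res.correlation
        rows.append((gene, tissue, c.r, c.p, res.significant, c.reason or ""))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "r", "p", "significant", "reason"])


# ------------------------------------------------------------- promoters


def extract_promoter(chrom_seq: str, start: int, end: int, strand: str,
                     length: int = 2000) -> str:
    """Promoter sequence of a gene on a chromosome sequence.

    Plus strand: the `length` bases immediately 5' of the gene start;
    minus strand: the `length` bases immediately 3' of the gene end,
    reverse-complemented. Truncated (with a warning) at contig edges.
    Coordinates are 1-based inclusive.
    """
    if strand == "+":
        lo = max(1, start - length)
        prom = chrom_seq[lo - 1: start - 1]
        if len(prom) < length:
            warnings.warn(f"promoter truncated to {len(prom)} bp at contig start", stacklevel=2)
        return prom.upper()
    if strand == "-":
        hi = min(len(chrom_seq), end + length)
        prom = chrom_seq[end: hi]
        if len(prom) < length:
            warnings.warn(f"promoter truncated to {len(prom)} bp at contig end", stacklevel=2)
        return reverse_complement(prom)
    raise ValueError(f"unknown strand {strand!r}")


def iupac_to_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in {pattern!r}") from None


def count_motif(seq: str, pattern: str) -> int:
    """Occurrences of an IUPAC motif on both strands, counted once per
    start position (palindromes are not double-counted)."""
    seq = seq.upper()
    fwd = re.compile(f"(?={iupac_to_regex(pattern)})")
    rev = re.compile(f"(?={iupac_to_regex(reverse_complement(pattern))})")
    starts = {m.start() for m in fwd.finditer(seq)}
    starts |= {m.start() for m in rev.finditer(seq)}
    return len(starts)


def compare_elements(promoters_a: dict[str, str], promoters_b: dict[str, str],
                     motifs: pd.DataFrame, top_k: int = 20,
                     label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    """Cis-element occurrence counts in two promoter sets.

    `motifs` needs columns name, pattern and optionally category (growth /
    hormone / stress). Elements are ranked by combined abundance and the
    top_k retained; the result carries per-set counts and the category.
    """
    if motifs.empty:
        raise ValueError("empty motif table")
    rows = []
    for m in motifs.itertuples():
        count_a = sum(count_motif(p, m.pattern) for p in promoters_a.values())
        count_b = sum(count_motif(p, m.pattern) for p in promoters_b.values())
        category = getattr(m, "category", "")
        rows.append((m.name, m.pattern, category, count_a, count_b))
    table = pd.DataFrame(rows, columns=["element", "pattern", "category", label_a, label_b])
    table["combined"] = table[label_a] + table[label_b]
    table = table[table["combined"] > 0]
    table = table.sort_values(["combined", "element"], ascending=[False, True]).head(top_k)
    return table.drop(columns="combined").reset_index(drop=True)


def category_rollup(element_table: pd.DataFrame, label_a: str = "A",
                    label_b: str = "B") -> pd.DataFrame:
    """Number of distinct top elements per functional category with a
    nonzero count in each promoter set."""
    present = element_table[element_table["category"] != ""]
    rows = []
    for category, sub in present.groupby("category"):
        rows.append((category, int((sub[label_a] > 0).sum()), int((sub[label_b] > 0).sum())))
    return pd.DataFrame(rows, columns=["category", label_a, label_b])
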